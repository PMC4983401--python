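"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import vasctomo as vt


def raysum_projection(vol: np.ndarray, angle_deg: float, voxel_size: float
                      ) -> np.ndarray:
    """Brute-force parallel-beam line integral about the z axis.

    Independent of the simulator's projector: marches every ray sample
    with hand-coded bilinear interpolation in the (y, x) plane. The
    geometry contract matches the package (rotation by ``angle`` about the
    voxel center (ny//2, nx//2), rays summed along y, detector column x).
    Returns a (z, x) frame in units of vol × µm.
    """
    nz, ny, nx = vol.shape
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    cy, cx = ny // 2, nx // 2
    out = np.zeros((nz, nx))
    for t in range(nx):            # detector column
        acc = np.zeros(nz)
        for k in range(ny):        # sample index along the ray
            y = c * (k - cy) - s * (t - cx) + cy
            x = s * (k - cy) + c * (t - cx) + cx
            y0, x0 = int(np.floor(y)), int(np.floor(x))
            fy, fx = y - y0, x - x0
            for (yy, xx, w) in ((y0, x0, (1 - fy) * (1 - fx)),
                                (y0, x0 + 1, (1 - fy) * fx),
                                (y0 + 1, x0, fy * (1 - fx)),
                                (y0 + 1, x0 + 1, fy * fx)):
                if 0 <= yy < ny and 0 <= xx < nx and w > 0:
                    acc += w * vol[:, yy, xx]
        out[:, t] = acc
    return out * voxel_size


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 1.0


@pytest.fixture(scope="session")
def small_phantom() -> vt.PhantomVolume:
    """A 32-cube phantom with one oblique vessel, for physics round trips."""
    spec = vt.TreeSpec(root_radius=8.0, min_radius=5.0, max_depth=1,
                       length_per_radius=5.0,
                       root_direction=(0.8, 0.35, 0.45))
    tree = vt.generate_vessel_tree(spec, seed=7)
    grid = vt.GridSpec((32, 32, 32), voxel_size=2.0)
    return vt.voxelize_tree(tree, grid)


@pytest.fixture(scope="session")
def tube_volume() -> tuple[np.ndarray, np.ndarray, float]:
    """A straight synthetic tube along z in a 48-cube: (volume, mask, voxel).

    Intensity mimics a reconstructed slice: dark lumen (low values) in
    brighter tissue, no noise.
    """
    n = 48
    voxel = 1.0
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
    r2 = (yy - n // 2) ** 2 + (xx - n // 2) ** 2
    mask = r2 < 5.0 ** 2
    vol = np.where(mask, 0.0, 1.0)
    return vol, mask, voxel
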