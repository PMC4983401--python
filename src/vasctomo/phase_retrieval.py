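"""Single-distance Paganin phase retrieval.

Assuming a homogeneous object with a fixed δ/β ratio, the projected
thickness follows from one near-field image by a low-pass Fourier filter
and a logarithm:

    T(x, y) = −(1/µ) · ln( F⁻¹[ F(I_p) / (1 + π λ z (δ/β) |f|²) ] )

with µ = 4πβ/λ and |f| the spatial frequency in cycles per µm. This is an
optional side branch of the pipeline: tomographic reconstruction operates
on the corrected (edge-enhanced) projections directly, where vessel
contrast is highest; retrieval trades that edge contrast for quantitative
thickness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .phantom import wavelength_um


@dataclass(frozen=True)
class PhaseRetrievalParams:
    delta: float = 1.0e-6
    beta: float = 1.0e-9            # delta/beta = 1000 for soft tissue at 16 keV
    energy_keV: float = 16.0
    distance_mm: float = 700.0
    pixel_size: float = 3.7         # µm

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.beta <= 0:
            raise ValueError("delta and beta must be positive")
        if self.distance_mm < 0:
            raise ValueError("distance_mm must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def wavelength_um(self) -> float:
        return wavelength_um(self.energy_keV)

    @property
    def mu_per_um(self) -> float:
        """Linear attenuation µ = 4πβ/λ in 1/µm."""
        return 4.0 * np.pi * self.beta / self.wavelength_um


def paganin_filter(frame: np.ndarray, params: PhaseRetrievalParams) -> np.ndarray:
    """The linear (pre-logarithm) stage: low-pass filter in frequency space."""
    frame = np.asarray(frame, dtype=np.float64)
    fy = np.fft.fftfreq(frame.shape[0], d=params.pixel_size)
    fx = np.fft.fftfreq(frame.shape[1], d=params.pixel_size)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    z_um = params.distance_mm * 1000.0
    denom = 1.0 + np.pi * params.wavelength_um * z_um * (params.delta / params.beta) * f2
    return np.real(np.fft.ifft2(np.fft.fft2(frame) / denom))


def paganin_retrieve(frame: np.ndarray, params: PhaseRetrievalParams,
                     epsilon: float = 1e-8) -> np.ndarray:
    """Retrieve the projected thickness map (µm) from one corrected frame.

    Non-positive input values are clipped to ``epsilon`` with a warning;
    non-positive filtered values (possible near strong fringes) are clipped
    the same way so the output stays finite.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if np.any(frame <= 0):
        if np.all(frame <= 0):
            raise ValueError("frame is non-positive everywhere")
        warnings.warn("clipping non-positive intensities before retrieval",
                      stacklevel=2)
        frame = np.clip(frame, epsilon, None)
    filtered = np.clip(paganin_filter(frame, params), epsilon, None)
    return -np.log(filtered) / params.mu_per_um
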