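"""Vessel-tree generation, voxelization and acquisition simulation."""

import numpy as np
import pytest

import vasctomo as vt
from vasctomo.phantom import (effective_pixel_um, min_resolvable_diameter_um,
                              wavelength_um)

from conftest import raysum_projection


class TestTreeGeneration:
    def test_single_segment_when_no_depth(self):
        tree = vt.generate_vessel_tree(
            vt.TreeSpec(root_radius=10.0, max_depth=1), seed=0)
        assert len(tree.segments) == 1
        assert len(tree.junctions) == 0

    def test_symmetric_bifurcation_radii_forced(self):
        spec = vt.TreeSpec(root_radius=10.0, radius_ratio_mean=0.7,
                           radius_ratio_sd=0.0, asymmetry=0.0, max_depth=2,
                           min_radius=1.0)
        tree = vt.generate_vessel_tree(spec, seed=0)
        assert len(tree.segments) == 3
        assert len(tree.junctions) == 1
        daughters = [tree.segments[c].radius for c in tree.junctions[0].child_segments]
        assert daughters == pytest.approx([7.0, 7.0])

    def test_mean_junction_ratio_matches_spec(self):
        spec = vt.TreeSpec(root_radius=12.0, radius_ratio_mean=0.794,
                           radius_ratio_sd=0.05, min_radius=1.0, max_depth=6)
        tree = vt.generate_vessel_tree(spec, seed=1)
        ratios = []
        for j in tree.junctions:
            parent = tree.segments[j.parent_segment].radius
            kids = [tree.segments[c].radius for c in j.child_segments]
            ratios.append(np.mean(kids) / parent)
        assert np.mean(ratios) == pytest.approx(0.794, abs=0.03)

    def test_determinism(self):
        spec = vt.TreeSpec(max_depth=5, min_radius=1.0)
        t1 = vt.generate_vessel_tree(spec, seed=42)
        t2 = vt.generate_vessel_tree(spec, seed=42)
        for a, b in zip(t1.segments, t2.segments):
            np.testing.assert_array_equal(a.start, b.start)
            np.testing.assert_array_equal(a.end, b.end)
            assert a.radius == b.radius

    def test_child_always_thinner_than_parent(self):
        spec = vt.TreeSpec(max_depth=6, radius_ratio_mean=0.9,
                           radius_ratio_sd=0.1, asymmetry=0.3, min_radius=0.5,
                           root_radius=20.0)
        tree = vt.generate_vessel_tree(spec, seed=3)
        for j in tree.junctions:
            parent = tree.segments[j.parent_segment].radius
            for c in j.child_segments:
                assert tree.segments[c].radius < parent

    def test_nonterminating_spec_rejected(self):
        with pytest.raises(ValueError):
            vt.TreeSpec(radius_ratio_mean=1.2)


class TestTrueBranchTable:
    def test_arithmetic_from_definition(self):
        spec = vt.TreeSpec(root_radius=10.0, radius_ratio_mean=0.7,
                           radius_ratio_sd=0.0, asymmetry=1.0 / 7.0,
                           max_depth=2, min_radius=1.0)
        tree = vt.generate_vessel_tree(spec, seed=0)
        (rec,) = vt.true_branch_table(tree)
        assert rec.pre_radius == pytest.approx(10.0)
        assert rec.post_radius == pytest.approx(7.0)
        assert rec.K == pytest.approx(0.7)

    def test_symmetric_tree_all_k_equal(self):
        spec = vt.TreeSpec(root_radius=16.0, radius_ratio_mean=0.794,
                           radius_ratio_sd=0.0, asymmetry=0.0, max_depth=4,
                           min_radius=1.0)
        tree = vt.generate_vessel_tree(spec, seed=0)
        recs = vt.true_branch_table(tree)
        assert len(recs) == 7
        assert all(r.K == pytest.approx(0.794) for r in recs)

    def test_no_junctions_empty_table(self):
        tree = vt.generate_vessel_tree(vt.TreeSpec(max_depth=1), seed=0)
        assert vt.true_branch_table(tree) == []


class TestVoxelize:
    def test_straight_segment_cross_section_area(self):
        from vasctomo.phantom import Segment, VesselTree
        seg = Segment(np.array([5.0, 32.0, 32.0]), np.array([58.0, 32.0, 32.0]),
                      5.0, None, depth=1)
        tree = VesselTree([seg], [])
        pv = vt.voxelize_tree(tree, vt.GridSpec((64, 64, 64), 1.0), center=False)
        areas = pv.true_mask[20:40].sum(axis=(1, 2))
        assert np.all(np.abs(areas - np.pi * 25) / (np.pi * 25) < 0.10)

    def test_empty_tree_uniform_tissue(self):
        from vasctomo.phantom import VesselTree
        pv = vt.voxelize_tree(VesselTree([], []), vt.GridSpec((16, 16, 16), 2.0))
        assert not pv.true_mask.any()
        inside = pv.mu[8, 8, 8]
        assert inside > 0

    def test_subvoxel_segment_marks_axis(self):
        from vasctomo.phantom import Segment, VesselTree
        seg = Segment(np.array([4.0, 16.0, 16.0]), np.array([28.0, 16.0, 16.0]),
                      0.4, None, depth=1)
        tree = VesselTree([seg], [])
        with pytest.warns(UserWarning, match="voxel size exceeds"):
            pv = vt.voxelize_tree(tree, vt.GridSpec((32, 32, 32), 1.0),
                                  center=False)
        assert pv.true_mask[6:26, 16, 16].all()

    def test_lumen_below_tissue_everywhere(self, small_phantom):
        assert np.all(small_phantom.mu >= 0)
        assert small_phantom.mu[small_phantom.true_mask].max() \
            < small_phantom.mu.max()


class TestAcquisitionArithmetic:
    def test_angle_step_gives_projection_count(self):
        geo = vt.AcquisitionGeometry.from_step(180.0, 0.12)
        assert geo.n_angles == 1500

    def test_total_exposure(self):
        geo = vt.AcquisitionGeometry.from_step(180.0, 0.12, exposure_s=0.2)
        assert geo.total_exposure_s == pytest.approx(300.0)

    def test_effective_pixel_and_resolution(self):
        px = effective_pixel_um(7.4, 2.0)
        assert px == pytest.approx(3.7)
        assert min_resolvable_diameter_um(px) == pytest.approx(7.4)

    def test_wavelength_positive_and_decreasing(self):
        assert wavelength_um(16.0) < wavelength_um(8.0)


class TestSimulation:
    def test_zero_distance_uniform_phantom_constant_frames(self):
        from vasctomo.phantom import VesselTree
        pv = vt.voxelize_tree(VesselTree([], []), vt.GridSpec((16, 16, 16), 2.0))
        noise = vt.NoiseSpec.noiseless(photons_per_pixel=100.0, dark_offset=10.0)
        raw = vt.simulate_projections(
            pv, vt.AcquisitionGeometry(n_angles=2, distance_mm=0.0), noise)
        # rays through the support cylinder at angle 0: column-wise constant
        frame = raw.frames[0]
        assert np.allclose(frame, frame[0], atol=1e-9)

    def test_zero_distance_matches_raysum_oracle(self, small_phantom):
        noise = vt.NoiseSpec.noiseless()
        geo = vt.AcquisitionGeometry(n_angles=4, distance_mm=0.0)
        raw = vt.simulate_projections(small_phantom, geo, noise)
        corrected = vt.correct_set(raw)
        for i, ang in enumerate(raw.angles_deg):
            expected = np.exp(-raysum_projection(small_phantom.mu, ang,
                                                 small_phantom.grid.voxel_size))
            err = np.abs(corrected.frames[i] - expected) / np.abs(expected)
            assert err.max() < 1e-6

    def test_edge_gradient_grows_with_distance(self, small_phantom):
        noise = vt.NoiseSpec.noiseless()
        grads = []
        for d in (100.0, 700.0):
            geo = vt.AcquisitionGeometry(n_angles=1, distance_mm=d)
            raw = vt.simulate_projections(small_phantom, geo, noise)
            frame = vt.correct_set(raw).frames[0]
            grads.append(np.abs(np.gradient(frame, axis=1)).max())
        assert grads[1] > grads[0]

    def test_fringe_contrast_nondecreasing_up_to_800mm(self, small_phantom):
        noise = vt.NoiseSpec.noiseless()
        prev = -np.inf
        for d in (0.0, 100.0, 200.0, 400.0, 600.0, 800.0):
            geo = vt.AcquisitionGeometry(n_angles=1, distance_mm=d)
            frame = vt.correct_set(
                vt.simulate_projections(small_phantom, geo, noise)).frames[0]
            contrast = float(frame.max() - frame.min())
            assert contrast >= prev - 1e-9
            prev = contrast

    def test_flat_exceeds_dark_everywhere(self, small_phantom):
        noise = vt.NoiseSpec(photons_per_pixel=200.0, dark_offset=90.0,
                             dark_sd=5.0, vignette_strength=0.3, seed=5)
        raw = vt.simulate_projections(
            small_phantom, vt.AcquisitionGeometry(n_angles=3, distance_mm=0.0),
            noise)
        assert np.all(raw.flat - raw.dark > 0)

    def test_projections_deterministic_given_seed(self, small_phantom):
        noise = vt.NoiseSpec(seed=11)
        geo = vt.AcquisitionGeometry(n_angles=2, distance_mm=300.0)
        a = vt.simulate_projections(small_phantom, geo, noise)
        b = vt.simulate_projections(small_phantom, geo, noise)
        np.testing.assert_array_equal(a.frames, b.frames)
        np.testing.assert_array_equal(a.flat, b.flat)

    def test_excessive_distance_rejected(self, small_phantom):
        geo = vt.AcquisitionGeometry(n_angles=1, distance_mm=5e5)
        with pytest.raises(ValueError, match="distance too large"):
            vt.simulate_projections(small_phantom, geo, vt.NoiseSpec.noiseless())
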