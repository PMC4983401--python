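"""Skeletonization, branch graphs, radius-ratio statistics."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest


from vasctomo.morphometry import (BranchRecord, VesselGraph, branch_records,
                                  build_vessel_graph, filter_and_bin,
                                  group_compare, skeletonize_mask)


def straight_tube_mask(n=40, radius=4.0):
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
    return (yy - n // 2) ** 2 + (xx - n // 2) ** 2 < radius ** 2


def manual_graph(incident_radii):
    """A single junction with one branch per given radius."""
    g = nx.MultiGraph()
    g.add_node(0, position=(0.0, 0.0, 0.0), kind="junction", radius=max(incident_radii),
               voxels=[(0, 0, 0)])
    for i, r in enumerate(incident_radii, start=1):
        g.add_node(i, position=(float(i), 0.0, 0.0), kind="endpoint", radius=r,
                   voxels=[(i, 0, 0)])
        g.add_edge(0, i, voxels=[(0, 0, 0), (i, 0, 0)], radii=np.array([r, r]),
                   radius=float(r), length=10.0)
    return VesselGraph(graph=g, voxel_size=1.0)


def record(pre, post, n_daughters=2, jid=0):
    return BranchRecord(junction_id=jid, pre_radius=pre, post_radius=post,
                        K=post / pre, n_daughters=n_daughters,
                        position=(0.0, 0.0, 0.0))


class TestSkeletonize:
    def test_straight_tube_single_path_and_radius(self):
        mask = straight_tube_mask(40, 4.0)
        skel, radius_map = skeletonize_mask(mask, voxel_size=1.0)
        vox = np.argwhere(skel)
        assert len(vox) > 0
        # skeleton stays near the tube axis
        d = np.hypot(vox[:, 1] - 20, vox[:, 2] - 20)
        assert d.max() <= 1.5
        # per-voxel radii near truth (interior slices)
        interior = vox[(vox[:, 0] > 5) & (vox[:, 0] < 34)]
        radii = radius_map[interior[:, 0], interior[:, 1], interior[:, 2]]
        assert abs(np.median(radii) - 4.0) <= 1.0

    def test_ball_skeleton_contained_and_nonempty(self):
        zz, yy, xx = np.mgrid[0:24, 0:24, 0:24]
        ball = (zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2 < 8 ** 2
        skel, _ = skeletonize_mask(ball, 1.0)
        assert skel.any()
        assert not (skel & ~ball).any()

    def test_empty_mask_empty_skeleton(self):
        skel, radius_map = skeletonize_mask(np.zeros((8, 8, 8), bool), 1.0)
        assert not skel.any()
        assert radius_map.shape == (8, 8, 8)


class TestBuildGraph:
    def test_y_skeleton_one_junction_three_branches(self):
        skel = np.zeros((40, 40, 40), bool)
        skel[5:21, 20, 20] = True                   # stem
        for i in range(1, 15):                       # two arms
            skel[20 + i, 20 + i, 20] = True
            skel[20 + i, 20 - i, 20] = True
        radius_map = np.where(skel, 1.0, 0.0)
        g = build_vessel_graph(skel, radius_map, 1.0, prune_spur_factor=0.0,
                               junction_merge_factor=0.0)
        assert len(g.junctions) == 1
        assert g.graph.number_of_edges() == 3

    def test_straight_path_no_junctions(self):
        skel = np.zeros((30, 30, 30), bool)
        skel[5:25, 15, 15] = True
        g = build_vessel_graph(skel, np.where(skel, 2.0, 0.0), 1.0)
        assert len(g.junctions) == 0
        assert g.graph.number_of_edges() == 1
        kinds = [d["kind"] for _, d in g.graph.nodes(data=True)]
        assert kinds.count("endpoint") == 2

    def test_tube_mask_end_to_end_radius(self):
        mask = straight_tube_mask(40, 4.0)
        skel, radius_map = skeletonize_mask(mask, 1.0)
        g = build_vessel_graph(skel, radius_map, 1.0)
        (u, v, d), = g.graph.edges(data=True)
        assert d["radius"] == pytest.approx(4.0, abs=1.0)


class TestBranchRecords:
    def test_largest_radius_is_parent(self):
        recs = branch_records(manual_graph([10.0, 8.0, 6.0]))
        (r,) = recs
        assert r.pre_radius == 10.0
        assert r.post_radius == pytest.approx(7.0)
        assert r.K == pytest.approx(0.7)
        assert not r.tie_flagged

    def test_symmetric_junction(self):
        (r,) = branch_records(manual_graph([5.0, 4.0, 4.0]))
        assert r.K == pytest.approx(0.8)

    def test_all_equal_radii_tie_flagged(self):
        (r,) = branch_records(manual_graph([4.0, 4.0, 4.0]))
        assert r.tie_flagged
        assert r.K == pytest.approx(1.0)

    def test_conservation_one_record_per_junction(self):
        mask = straight_tube_mask(40, 4.0)
        skel, radius_map = skeletonize_mask(mask, 1.0)
        g = build_vessel_graph(skel, radius_map, 1.0)
        assert len(branch_records(g)) == len(g.junctions)

    def test_scale_equivariance_of_k(self):
        base = branch_records(manual_graph([10.0, 8.0, 6.0]))
        scaled = branch_records(manual_graph([30.0, 24.0, 18.0]))
        assert base[0].K == pytest.approx(scaled[0].K)


class TestFilterAndBin:
    def test_threshold_and_bins(self):
        recs = [record(5.0, 4.0, jid=0), record(10.0, 8.0, jid=1),
                record(25.0, 20.0, jid=2)]
        df = filter_and_bin(recs)
        assert len(df) == 2
        assert set(df["bin"]) == {"<7.4um", "7.4-20um"}
        assert df.loc[df["pre_radius_um"] == 5.0, "bin"].iloc[0] == "<7.4um"

    def test_all_large_radii_dropped(self):
        recs = [record(20.0, 15.0), record(30.0, 20.0)]
        assert len(filter_and_bin(recs)) == 0

    def test_boundary_record_goes_to_upper_bin(self):
        df = filter_and_bin([record(7.4, 6.0)])
        assert df["bin"].iloc[0] == "7.4-20um"

    def test_empty_input(self):
        assert len(filter_and_bin([])) == 0


def binned_table(ks, pre=5.0):
    df = pd.DataFrame({"junction_id": range(len(ks)),
                       "z_um": 0.0, "y_um": 0.0, "x_um": 0.0,
                       "pre_radius_um": pre, "post_radius_um": np.array(ks) * pre,
                       "K": ks, "n_daughters": 2})
    df["bin"] = "<7.4um" if pre < 7.4 else "7.4-20um"
    return df


class TestGroupCompare:
    def test_identical_groups_t_zero_p_one(self):
        tables = [binned_table([0.7, 0.8]), binned_table([0.6, 0.9])]
        res = group_compare(tables, [t.copy() for t in tables])
        small = [r for r in res if r.bin_label == "<7.4um"][0]
        assert small.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert small.p_value == pytest.approx(1.0)

    def test_swapped_groups_negate_t(self):
        a = [binned_table([0.80, 0.82]), binned_table([0.78, 0.81])]
        b = [binned_table([0.70, 0.72]), binned_table([0.68, 0.71])]
        r_ab = [r for r in group_compare(a, b) if r.bin_label == "<7.4um"][0]
        r_ba = [r for r in group_compare(b, a) if r.bin_label == "<7.4um"][0]
        assert r_ab.t_statistic == pytest.approx(-r_ba.t_statistic)
        assert r_ab.p_value == pytest.approx(r_ba.p_value)

    def test_monte_carlo_power(self):
        """Groups at K=0.79 vs 0.70 (sd 0.01, n=7) separate in >=95% of
        repeats — the statistical design has the power the study needs."""
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(200):
            a = [binned_table(rng.normal(0.79, 0.01, 5)) for _ in range(7)]
            b = [binned_table(rng.normal(0.70, 0.01, 5)) for _ in range(7)]
            res = [r for r in group_compare(a, b) if r.bin_label == "<7.4um"][0]
            hits += res.p_value < 0.05
        assert hits >= 190

    def test_animal_with_empty_bin_excluded(self):
        a = [binned_table([0.7, 0.8]), binned_table([0.75, 0.8]),
             binned_table([0.9], pre=10.0)]     # no small-bin junctions
        b = [binned_table([0.6, 0.7]), binned_table([0.65, 0.7])]
        with pytest.warns(UserWarning, match="excluded"):
            res = group_compare(a, b)
        small = [r for r in res if r.bin_label == "<7.4um"][0]
        assert small.n_a == 2

    def test_single_animal_groups_rejected(self):
        with pytest.raises(ValueError, match="two animals"):
            group_compare([binned_table([0.7])], [binned_table([0.6])])
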