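"""Morphometry: SWC I/O, arbor features, 3D Sholl, skeleton statistics."""

import io
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from socioglia.morphometry import (NeuronArbor, ShollProfile, SWCError,
                                   arbor_features, read_swc, sholl_profile,
                                   sholl_stats, skeleton_stats,
                                   timeseries_variability, write_swc,
                                   FEATURE_NAMES)
from socioglia.synth import ArborParams, gen_arbors

from _oracles import dense_sholl_counts, naive_features


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

class TestSWC:
    def test_two_node_file(self):
        arbor = read_swc("1 1 0 0 0 1 -1\n2 3 5 0 0 0.5 1\n")
        assert arbor.n_nodes == 2
        assert arbor.edge_lengths()[1] == pytest.approx(5.0)

    def test_dangling_parent_reports_reference(self):
        with pytest.raises(SWCError, match="99"):
            read_swc("1 1 0 0 0 1 -1\n2 3 5 0 0 1 99\n")

    def test_multiple_roots_rejected(self):
        with pytest.raises(SWCError, match="root"):
            read_swc("1 1 0 0 0 1 -1\n2 1 5 0 0 1 -1\n")

    def test_cycle_rejected(self):
        with pytest.raises(SWCError):
            NeuronArbor(ids=[1, 2, 3], types=[1, 3, 3],
                        xyz=np.zeros((3, 3)), radius=np.ones(3),
                        parent=[3, 1, 2])

    def test_malformed_line_numbered(self):
        with pytest.raises(SWCError, match="line 2"):
            read_swc("1 1 0 0 0 1 -1\n2 3 x 0 0 1 1\n")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_roundtrip_exact(self, seed):
        for arbor in gen_arbors(ArborParams(seed=seed), 3):
            back = read_swc(io.StringIO(write_swc(arbor)))
            assert np.array_equal(arbor.xyz, back.xyz)
            assert np.array_equal(arbor.parent, back.parent)
            assert np.array_equal(arbor.radius, back.radius)


# ---------------------------------------------------------------------------
# Sholl profile
# ---------------------------------------------------------------------------

class TestSholl:
    def test_straight_segment(self):
        arbor = read_swc("1 1 0 0 0 1 -1\n2 3 10.5 0 0 1 1\n")
        prof = sholl_profile(arbor, step=1.0)
        assert list(prof.counts[:10]) == [1] * 10
        assert prof.counts[10:].sum() == 0

    def test_hand_branched_geometry(self):
        # trunk to (5.5,0,0), daughters to (9,+-3,0): radial distance is
        # monotone along each daughter, so counts are 1 for r=1..5, 2 for
        # r=6..9 and 0 beyond
        arbor = NeuronArbor(
            ids=[1, 2, 3, 4], types=[1, 3, 3, 3],
            xyz=[[0, 0, 0], [5.5, 0, 0], [9, 3, 0], [9, -3, 0]],
            radius=[1.0] * 4, parent=[-1, 1, 2, 2])
        assert list(sholl_profile(arbor).counts) == [1, 1, 1, 1, 1, 2, 2, 2, 2, 0]

    def test_node_on_shell_counts_once(self):
        # child node exactly at r=5 then onward: crossing attributed once
        arbor = read_swc("1 1 0 0 0 1 -1\n2 3 5 0 0 1 1\n3 3 8.5 0 0 1 2\n")
        prof = sholl_profile(arbor, step=1.0)
        assert list(prof.counts) == [1, 1, 1, 1, 1, 1, 1, 1, 0]

    def test_tangent_edge_counts_once(self):
        # chord at distance exactly 2 from the soma grazes the r=2 sphere
        arbor = NeuronArbor(
            ids=[1, 2, 3], types=[1, 3, 3],
            xyz=[[0, 0, 0], [-1.5, 2, 0], [1.5, 2, 0]],
            radius=[1.0] * 3, parent=[-1, 1, 2])
        prof = sholl_profile(arbor, step=1.0)
        assert prof.counts[1] == 1 + 1  # one crossing on the trunk, one graze

    @pytest.mark.parametrize("branch", [0.02, 0.08])
    def test_matches_dense_sampling_oracle(self, branch):
        for arbor in gen_arbors(ArborParams(seed=5, branch_prob_per_um=branch), 15):
            mine = sholl_profile(arbor).counts
            oracle = dense_sholl_counts(arbor)
            n = max(len(mine), len(oracle))
            assert np.array_equal(np.pad(mine, (0, n - len(mine))),
                                  np.pad(oracle, (0, n - len(oracle))))

    def test_rigid_invariance(self):
        rng = np.random.default_rng(0)
        arbor = gen_arbors(ArborParams(seed=3, branch_prob_per_um=0.08), 1)[0]
        base = sholl_profile(arbor).counts
        for _ in range(5):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.normal(scale=50, size=3)
            moved = arbor.with_xyz(arbor.xyz @ R.T + t)
            assert np.array_equal(sholl_profile(moved).counts, base)

    def test_isotropic_scaling_stretches_radii(self):
        arbor = gen_arbors(ArborParams(seed=4, branch_prob_per_um=0.08), 1)[0]
        base = sholl_profile(arbor, step=1.0)
        scaled = sholl_profile(arbor.with_xyz(arbor.xyz * 2.0), step=2.0)
        assert np.array_equal(base.counts, scaled.counts)


class TestShollStats:
    def test_known_profile(self):
        stats = sholl_stats(ShollProfile(step=1.0, counts=[1, 1, 2, 2, 1]))
        assert stats == {"sholl_total": 7.0, "sholl_max": 2.0,
                         "sholl_max_radius": 5.0, "sholl_radius_at_max": 3.0}

    def test_all_zero_profile(self):
        stats = sholl_stats(ShollProfile(step=1.0, counts=[0, 0, 0]))
        assert all(v == 0.0 for v in stats.values())

    @pytest.mark.parametrize("seed", range(5))
    def test_random_profiles_match_array_scan(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 6, size=30)
        stats = sholl_stats(ShollProfile(step=0.5, counts=counts))
        radii = 0.5 * np.arange(1, 31)
        if counts.max() == 0:
            assert stats["sholl_max_radius"] == 0.0
        else:
            assert stats["sholl_total"] == counts.sum()
            assert stats["sholl_max"] == counts.max()
            assert stats["sholl_max_radius"] == radii[np.nonzero(counts)[0][-1]]
            assert stats["sholl_radius_at_max"] == radii[counts.argmax()]


# ---------------------------------------------------------------------------
# Arbor features
# ---------------------------------------------------------------------------

class TestArborFeatures:
    def test_unbranched_path(self, path_arbor):
        f = arbor_features(path_arbor)
        assert f["total_length"] == pytest.approx(10.0)
        assert f["n_branches"] == 1
        assert f["mean_branch_length"] == pytest.approx(10.0)
        assert f["arbor_depth"] == 0
        assert f["n_tips"] == 1
        assert f["n_branch_points"] == 0

    def test_symmetric_y(self, y_arbor):
        f = arbor_features(y_arbor)
        assert f["total_length"] == pytest.approx(15.0)
        assert f["n_branches"] == 3
        assert f["mean_branch_length"] == pytest.approx(5.0)
        assert f["arbor_depth"] == 1
        assert f["n_tips"] == 2
        assert f["n_branch_points"] == 1

    def test_single_node(self):
        arbor = read_swc("1 1 0 0 0 1 -1\n")
        f = arbor_features(arbor)
        assert f["total_length"] == 0.0
        assert f["arbor_depth"] == 0.0
        assert f["n_tips"] == 0.0

    @pytest.mark.parametrize("seed,branch", [(0, 0.03), (1, 0.08), (2, 0.10)])
    def test_matches_naive_traversal_oracle(self, seed, branch):
        for arbor in gen_arbors(ArborParams(seed=seed, branch_prob_per_um=branch), 10):
            mine = arbor_features(arbor)
            oracle = naive_features(arbor)
            for name in FEATURE_NAMES:
                assert mine[name] == pytest.approx(oracle[name], rel=1e-6), name

    def test_branch_count_identity_and_length_consistency(self):
        for arbor in gen_arbors(ArborParams(seed=9, branch_prob_per_um=0.08), 10):
            f = arbor_features(arbor)
            assert f["n_branches"] == f["n_branch_points"] + f["n_tips"]
            assert f["mean_branch_length"] * f["n_branches"] == pytest.approx(
                f["total_length"], abs=1e-9)

    def test_rigid_invariance_of_features(self):
        rng = np.random.default_rng(1)
        arbor = gen_arbors(ArborParams(seed=8, branch_prob_per_um=0.08), 1)[0]
        base = arbor_features(arbor)
        R = Rotation.random(rng=rng).as_matrix()
        moved = arbor.with_xyz(arbor.xyz @ R.T + rng.normal(scale=20, size=3))
        got = arbor_features(moved)
        for name in FEATURE_NAMES:
            if name == "bounding_box_volume":
                continue
            assert got[name] == pytest.approx(base[name], rel=1e-6), name

    def test_isotropic_scaling(self):
        arbor = gen_arbors(ArborParams(seed=2, branch_prob_per_um=0.08), 1)[0]
        base = arbor_features(arbor, sholl_step=1.0)
        scaled = arbor_features(arbor.with_xyz(arbor.xyz * 3.0), sholl_step=3.0)
        assert scaled["total_length"] == pytest.approx(3 * base["total_length"])
        assert scaled["max_path_distance"] == pytest.approx(3 * base["max_path_distance"])
        assert scaled["n_tips"] == base["n_tips"]
        assert scaled["arbor_depth"] == base["arbor_depth"]
        assert scaled["sholl_total"] == base["sholl_total"]


# ---------------------------------------------------------------------------
# Skeleton stats & time-series variability
# ---------------------------------------------------------------------------

class TestSkeletonStats:
    def test_y_skeleton(self, y_arbor):
        s = skeleton_stats(y_arbor)
        assert s["total_length"] == pytest.approx(15.0)
        assert s["n_endpoints"] == 2

    def test_straight_path_root_is_endpoint(self, path_arbor):
        assert skeleton_stats(path_arbor)["n_endpoints"] == 2

    def test_random_skeletons_match_degree_count(self):
        for sk in gen_arbors(ArborParams(seed=11, branch_prob_per_um=0.06), 5):
            children = sk.children_index()
            deg = np.array([len(children[i]) + (0 if i == sk.root_index else 1)
                            for i in range(sk.n_nodes)])
            expected = np.sum(deg == 1)
            if deg[sk.root_index] == 1 and np.any(deg >= 3):
                expected -= 1  # branched skeleton: soma end is not a tip
            assert skeleton_stats(sk)["n_endpoints"] == expected


class TestTimeseriesVariability:
    def test_constant_series_is_zero(self):
        assert timeseries_variability([7.0, 7.0, 7.0]) == 0.0

    def test_known_arithmetic(self):
        # {10,12,14}: sample variance 4, mean 12
        assert timeseries_variability([10, 12, 14]) == pytest.approx(4 / 12)

    def test_scales_linearly(self):
        base = timeseries_variability([3.0, 5.0, 9.0, 4.0])
        assert timeseries_variability([6.0, 10.0, 18.0, 8.0]) == pytest.approx(2 * base)

    def test_cv2_option(self):
        assert timeseries_variability([10, 12, 14], squared_mean=True) == pytest.approx(4 / 144)

    def test_zero_mean_errors(self):
        with pytest.raises(ValueError):
            timeseries_variability([-1.0, 1.0])
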