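"""Synthetic-data generators: determinism, bounds, planted structure."""

import numpy as np
import pytest
import scipy.stats

from socioglia.behavior import social_metrics
from socioglia.morphometry import arbor_features
from socioglia.synth import (ArborParams, DyadParams, ExprParams, VolumeParams,
                             default_fingerprint_genes, gen_arbors, gen_dyad,
                             gen_expression, gen_volume,
                             read_arbors_swc, read_expression_mtx, read_volume,
                             write_arbors_swc, write_expression_mtx,
                             write_volume, MICROGLIAL_TYPES)
from socioglia.volumetrics import density_metrics


class TestDyad:
    def test_determinism(self):
        p = DyadParams(seed=5, duration=20.0)
        a1, b1 = gen_dyad(p)
        a2, b2 = gen_dyad(p)
        assert np.array_equal(a1.positions, a2.positions)
        assert np.array_equal(b1.heading, b2.heading)

    def test_positions_inside_arena(self):
        f1, f2 = gen_dyad(DyadParams(seed=1, sociality=1.0, duration=60.0))
        for f in (f1, f2):
            assert f.positions.min() >= 0.0
            assert f.positions[:, 0].max() <= f.arena.width
            assert f.positions[:, 1].max() <= f.arena.length

    def test_full_sociality_maximizes_metrics(self):
        f1, _ = gen_dyad(DyadParams(sociality=1.0, seed=2))
        m = social_metrics(f1)
        assert m.relative_proximity >= 0.8
        assert m.pct_orienting_45_90 >= 80.0

    def test_zero_sociality_orienting_near_half(self):
        vals = []
        for seed in range(4):
            f1, f2 = gen_dyad(DyadParams(sociality=0.0, seed=seed))
            vals += [social_metrics(f).pct_orienting_45_90 for f in (f1, f2)]
        assert np.mean(vals) == pytest.approx(50.0, abs=3.0)

    def test_metrics_monotone_in_sociality(self):
        means = []
        for s in (0.0, 0.5, 1.0):
            ms = []
            for seed in range(6):
                f1, f2 = gen_dyad(DyadParams(sociality=s, seed=seed,
                                             duration=300.0))
                ms += [social_metrics(f) for f in (f1, f2)]
            means.append([np.mean([m.relative_proximity for m in ms]),
                          np.mean([m.pct_orienting_45_90 for m in ms]),
                          np.mean([m.pct_in_motion for m in ms]),
                          np.mean([m.swim_speed_mm_s for m in ms])])
        arr = np.array(means)
        assert np.all(np.diff(arr, axis=0) >= 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DyadParams(sociality=1.2)
        with pytest.raises(ValueError):
            DyadParams(swim_speed_mean=-1.0)
        with pytest.raises(ValueError):
            DyadParams(fps=float("nan"))


class TestArborGenerator:
    def test_zero_branching_gives_paths(self):
        for arbor in gen_arbors(ArborParams(branch_prob_per_um=0.0, seed=3), 5):
            f = arbor_features(arbor)
            assert f["n_branch_points"] == 0
            assert f["arbor_depth"] == 0

    def test_total_length_cap(self):
        for arbor in gen_arbors(ArborParams(max_total_um=100.0, seed=4), 10):
            assert arbor_features(arbor)["total_length"] <= 100.0 + 1e-9

    def test_edge_lengths_equal_step(self):
        p = ArborParams(seed=5)
        arbor = gen_arbors(p, 1)[0]
        lens = arbor.edge_lengths()[1:]
        assert np.allclose(lens, p.step_um)

    def test_branching_contrast_shifts_depth_and_length(self):
        lo = gen_arbors(ArborParams(branch_prob_per_um=0.02, seed=6), 60)
        hi = gen_arbors(ArborParams(branch_prob_per_um=0.10, seed=7), 60)
        f_lo = [arbor_features(a) for a in lo]
        f_hi = [arbor_features(a) for a in hi]
        for key in ("arbor_depth", "total_length"):
            x = [f[key] for f in f_lo]
            y = [f[key] for f in f_hi]
            assert np.median(y) > np.median(x)
            assert scipy.stats.mannwhitneyu(y, x, alternative="greater").pvalue < 0.01

    def test_monotone_in_branch_prob(self):
        med = []
        for b in (0.02, 0.05, 0.10):
            feats = [arbor_features(a)
                     for a in gen_arbors(ArborParams(branch_prob_per_um=b, seed=8), 30)]
            med.append((np.median([f["arbor_depth"] for f in feats]),
                        np.median([f["total_length"] for f in feats])))
        assert med[0] <= med[1] <= med[2]

    def test_per_step_probability_validated(self):
        with pytest.raises(ValueError):
            ArborParams(branch_prob_per_um=0.9, step_um=2.0)

    def test_determinism(self):
        a = gen_arbors(ArborParams(seed=10), 3)
        b = gen_arbors(ArborParams(seed=10), 3)
        for x, y in zip(a, b):
            assert np.array_equal(x.xyz, y.xyz)

    def test_swc_roundtrip(self, tmp_path):
        arbors = gen_arbors(ArborParams(seed=11), 3)
        paths = write_arbors_swc(arbors, str(tmp_path))
        back = read_arbors_swc(paths)
        for x, y in zip(arbors, back):
            assert np.array_equal(x.xyz, y.xyz)


class TestVolumeGenerator:
    def test_neuropil_fraction_hits_target(self):
        v = gen_volume(VolumeParams(neuropil_fraction=0.10, seed=1))
        assert density_metrics(v)["neuropil_density"] == pytest.approx(0.10, abs=0.01)

    def test_unbiased_z_is_centered(self):
        v = gen_volume(VolumeParams(dorsal_bias=0.0, n_microglia=200, seed=2))
        assert density_metrics(v)["microglia_mean_z_norm"] == pytest.approx(0.5, abs=0.05)

    def test_exact_centroid_count_inside_mask(self):
        v = gen_volume(VolumeParams(n_microglia=50, seed=3))
        assert len(v.microglia_centroids) == 50
        vox = np.asarray(v.voxel_um)
        idx = np.round(v.microglia_centroids / vox).astype(int)
        assert v.forebrain_mask[idx[:, 0], idx[:, 1], idx[:, 2]].all()

    def test_dorsal_bias_monotone(self):
        zs = [density_metrics(gen_volume(VolumeParams(dorsal_bias=b, seed=4)))
              ["microglia_mean_z_norm"] for b in (0.0, 1.5, 3.0)]
        assert zs[0] < zs[1] < zs[2]
        assert zs[1] > 0.5

    def test_fraction_bounds_validated(self):
        with pytest.raises(ValueError):
            VolumeParams(neuropil_fraction=0.0)
        with pytest.raises(ValueError):
            VolumeParams(neuropil_fraction=1.0)

    def test_tiff_roundtrip(self, tmp_path):
        v = gen_volume(VolumeParams(seed=5))
        back = read_volume(write_volume(v, str(tmp_path)))
        assert np.array_equal(v.forebrain_mask, back.forebrain_mask)
        assert np.array_equal(v.neuropil_mask, back.neuropil_mask)
        assert np.allclose(v.microglia_centroids, back.microglia_centroids)


class TestExpressionGenerator:
    def test_fingerprint_detectability_split(self):
        adata = gen_expression(ExprParams(seed=1))
        counts = adata.layers["counts"]
        fp_idx = [adata.var_names.get_loc(g) for g in adata.uns["fingerprint_genes"]]
        types = adata.obs["true_type"].to_numpy()
        micro = np.isin(types, MICROGLIAL_TYPES)
        frac_micro = (counts[np.ix_(micro, fp_idx)] > 0).mean()
        frac_mac = (counts[np.ix_(~micro, fp_idx)] > 0).mean()
        assert frac_micro > 0.95
        assert frac_mac < 0.15

    def test_determinism(self):
        a = gen_expression(ExprParams(seed=2))
        b = gen_expression(ExprParams(seed=2))
        assert np.array_equal(a.layers["counts"], b.layers["counts"])
        assert (a.obs["condition"] == b.obs["condition"]).all()

    def test_counts_are_nonnegative_integers(self):
        adata = gen_expression(ExprParams(seed=3))
        counts = adata.layers["counts"]
        assert counts.min() >= 0
        assert np.issubdtype(counts.dtype, np.integer)

    def test_fingerprint_monotone_in_mean(self):
        fracs = []
        for mean in (0.5, 3.0, 20.0):
            adata = gen_expression(ExprParams(seed=4, fingerprint_high_mean=mean))
            fp_idx = [adata.var_names.get_loc(g)
                      for g in adata.uns["fingerprint_genes"]]
            micro = np.isin(adata.obs["true_type"], MICROGLIAL_TYPES)
            fracs.append((adata.layers["counts"][np.ix_(micro, fp_idx)] > 0).mean())
        assert fracs[0] < fracs[1] < fracs[2]

    def test_planted_lfc_only_in_specified_type(self):
        adata = gen_expression(ExprParams(
            seed=5,
            n_cells_per_type={"ramified_microglia": 2000, "macrophage": 2000},
            condition_lfc={"ram_mk001": {"ramified_microglia": -1.0}}))
        counts = adata.layers["counts"]
        j = adata.var_names.get_loc("ram_mk001")
        t = adata.obs["true_type"].to_numpy()
        c = adata.obs["condition"].to_numpy()
        ram_ratio = (counts[(t == "ramified_microglia") & (c == "GF"), j].mean()
                     / counts[(t == "ramified_microglia") & (c == "CVZ"), j].mean())
        assert ram_ratio == pytest.approx(2.0, rel=0.15)
        # macrophages (background expression) untouched by the planted shift
        mac_gf = counts[(t == "macrophage") & (c == "GF"), j].mean()
        mac_cv = counts[(t == "macrophage") & (c == "CVZ"), j].mean()
        assert abs(mac_gf - mac_cv) < 0.1

    def test_gene_budget_validated(self):
        with pytest.raises(ValueError):
            ExprParams(n_genes=100)

    def test_default_fingerprint_has_75_genes(self):
        genes = default_fingerprint_genes()
        assert len(genes) == 75
        assert "c1qa" in genes and "c1qb" in genes

    def test_mtx_roundtrip(self, tmp_path):
        adata = gen_expression(ExprParams(seed=6))
        back = read_expression_mtx(write_expression_mtx(adata, str(tmp_path)))
        assert np.array_equal(adata.layers["counts"], back.layers["counts"])
        assert (back.obs["condition"].to_numpy()
                == adata.obs["condition"].to_numpy()).all()
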