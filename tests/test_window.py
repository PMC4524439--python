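"""Window selection, permutation Spearman, cluster collapsing, group profiles."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gdmomics import synth
from gdmomics.window import (P_FLOOR, build_networks, collapse_clusters,
                             group_difference_profile, permutation_spearman,
                             random_control_windows, select_window_features)


class TestSelectWindowFeatures:
    def _annots(self):
        probes = pd.DataFrame({
            "chrom": "chr1",
            "position": [90_000, 100_000, 150_000, 210_000, 210_001],
            "probe_type": "II", "snp_at_target": False, "cross_hyb_x": False,
        }, index=[f"cg{i}" for i in range(5)])
        genes = pd.DataFrame({
            "chrom": "chr1", "start": [100_000, 199_000, 200_001],
            "end": [120_000, 210_500, 220_000],
            "tss": [100_000, 199_000, 200_001], "coding": True,
        }, index=["gA", "gB", "gC"])
        return (synth.ProbeAnnotation(probes=probes),
                synth.GeneAnnotation(genes=genes))

    def test_flank_boundary_closed(self):
        pa, ga = self._annots()
        cpgs, genes = select_window_features(pa, ga, ("chr1", 100_000, 200_000),
                                             flank=10_000)
        # cg0 at exactly start - 10000 included; 210_001 excluded
        assert cpgs == ["cg0", "cg1", "cg2", "cg3"]

    def test_gene_tss_one_bp_outside_excluded(self):
        pa, ga = self._annots()
        _, genes = select_window_features(pa, ga, ("chr1", 100_000, 200_000))
        assert genes == ["gA", "gB"]  # gC TSS at 200_001

    def test_empty_window_rejected(self):
        pa, ga = self._annots()
        with pytest.raises(ValueError, match="empty"):
            select_window_features(pa, ga, ("chr1", 200, 100))


class TestPermutationSpearman:
    def test_perfect_anticorrelation(self):
        x = np.arange(30.0)
        rho, p = permutation_spearman(x, -x, n_perm=200, seed=0)
        assert rho == pytest.approx(-1.0)

    def test_monotone_pair_hits_imputation_floor(self):
        x = np.arange(30.0)
        y = np.exp(x / 10)
        rho, p = permutation_spearman(x, y, n_perm=2000, seed=1)
        assert rho == pytest.approx(1.0)
        assert p == P_FLOOR  # no permutation can match, p = 0 -> 1e-6

    def test_constant_vector_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = permutation_spearman(np.ones(12), np.arange(12.0),
                                          n_perm=100, seed=2)
        assert np.isnan(rho) and np.isnan(p)

    def test_reproducible_and_seed_sensitive(self, rng):
        x = rng.normal(size=25)
        y = 0.5 * x + rng.normal(size=25)
        a = permutation_spearman(x, y, n_perm=500, seed=3)
        b = permutation_spearman(x, y, n_perm=500, seed=3)
        assert a == b

    def test_matches_scipy_rho_with_ties(self, rng):
        from scipy.stats import spearmanr
        x = rng.integers(0, 5, size=20).astype(float)  # ties
        y = rng.normal(size=20)
        rho, _ = permutation_spearman(x, y, n_perm=50, seed=4)
        assert rho == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="n >= 10"):
            permutation_spearman(np.arange(5.0), np.arange(5.0))


class TestBuildNetworks:
    def _window_data(self, n=30, seed=0, latent=True):
        r = np.random.default_rng(seed)
        f = r.normal(size=n)
        genes = {}
        for g in range(8):
            genes[f"G{g}"] = (0.9 * f + 0.45 * r.normal(size=n)) if latent \
                else r.normal(size=n)
        expr = pd.DataFrame(genes).T
        expr.columns = [f"S{i}" for i in range(n)]
        beta = pd.DataFrame(r.uniform(0.2, 0.8, size=(10, n)),
                            index=[f"cg{i}" for i in range(10)],
                            columns=expr.columns)
        return beta, expr

    def test_shared_latent_factor_gives_dense_positive_coexpression(self):
        beta, expr = self._window_data(latent=True)
        nets = build_networks(beta, expr, n_perm=500, seed=5)
        assert len(nets.expr_expr) >= 20
        assert (nets.expr_expr["rho"] > 0).mean() > 0.9

    def test_generator_block_coexpression_detected(self, gene_annot):
        """The coordinated block's shared latent factor produces a dense,
        positively-signed co-expression network at full study scale."""
        from gdmomics.expr import preprocess_expression
        cohort = synth.generate_cohort(40, seed=51)
        tab, truth = synth.generate_expression(
            cohort, gene_annot,
            synth.ExpressionEffects(probes_per_gene_mean=4.0), seed=52)
        em = preprocess_expression(tab)
        expr_w = em.values.loc[truth.block_genes]
        r = np.random.default_rng(53)
        beta = pd.DataFrame(r.uniform(0.2, 0.8, size=(5, expr_w.shape[1])),
                            index=[f"cg{i}" for i in range(5)],
                            columns=expr_w.columns)
        nets = build_networks(beta, expr_w, n_perm=500, seed=54)
        assert len(nets.expr_expr) >= 10
        assert (nets.expr_expr["rho"] > 0).mean() > 0.9

    def test_null_window_yields_no_significant_edges(self):
        beta, expr = self._window_data(latent=False, seed=6)
        nets = build_networks(beta, expr, n_perm=500, seed=7)
        total = len(nets.meth_expr) + len(nets.expr_expr)
        assert total <= 2

    def test_families_corrected_separately(self):
        beta, expr = self._window_data(latent=True)
        nets = build_networks(beta, expr, n_perm=300, seed=8)
        # q-values recomputed within family must match a family-local BH
        from gdmomics.enrich import fdr_correct
        ee = nets.all_expr_expr
        assert np.allclose(ee["q_value"],
                           fdr_correct(ee["perm_p"].to_numpy()))

    def test_mismatched_columns_rejected(self):
        beta, expr = self._window_data()
        with pytest.raises(ValueError, match="columns"):
            build_networks(beta, expr[expr.columns[::-1]], n_perm=50, seed=9)


class TestCollapseClusters:
    def _beta(self, positions):
        idx = [f"cg{i}" for i in range(len(positions))]
        beta = pd.DataFrame(np.arange(len(positions) * 2, dtype=float)
                            .reshape(len(positions), 2) / 10.0,
                            index=idx, columns=["s1", "s2"])
        return beta, pd.Series(positions, index=idx)

    def test_hand_trace_single_cluster(self):
        beta, pos = self._beta([100, 4000, 9000])
        out, members = collapse_clusters(beta, pos)
        assert len(out) == 1
        assert members.iloc[0]["n_cpgs"] == 3  # span 8900 <= 10 kb, gaps <= 5 kb
        assert np.allclose(out.iloc[0], beta.mean(axis=0))

    def test_hand_trace_three_singletons(self):
        beta, pos = self._beta([100, 9000, 15_000])
        out, members = collapse_clusters(beta, pos)
        assert len(out) == 3  # gaps 8900 and 6000 both exceed 5 kb
        assert (members["n_cpgs"] == 1).all()

    def test_max_width_caps_cluster(self):
        beta, pos = self._beta([0, 4000, 8000, 12_000])
        out, members = collapse_clusters(beta, pos)
        # 12_000 is 4 kb from 8000 but span would be 12 kb > 10 kb
        assert members["n_cpgs"].tolist() == [3, 1]

    def test_single_cpg_passthrough(self):
        beta, pos = self._beta([500])
        out, _ = collapse_clusters(beta, pos)
        assert np.allclose(out.iloc[0], beta.iloc[0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 10**6), min_size=1, max_size=40,
                    unique=True))
    def test_partition_property(self, positions):
        positions = sorted(positions)
        beta, pos = self._beta(positions)
        _, members = collapse_clusters(beta, pos)
        covered = [p for ids in members["probe_ids"]
                   for p in ids.split(",")]
        assert sorted(covered) == sorted(beta.index)  # each CpG exactly once


class TestGroupProfiles:
    def test_identical_groups_zero_difference(self):
        samples = pd.DataFrame({"gdm": [1, 1, 0, 0]},
                               index=["a", "b", "c", "d"])
        mat = pd.DataFrame([[1.0, 2.0, 1.0, 2.0]], index=["cl0"],
                           columns=samples.index)
        expr = pd.DataFrame([[3.0, 4.0, 3.0, 4.0]], index=["g"],
                            columns=samples.index)
        prof = group_difference_profile(mat, expr, samples)
        assert (prof["difference"] == 0).all()

    def test_random_control_windows_avoid_excluded(self, probe_annot, gene_annot):
        wins = random_control_windows(probe_annot, gene_annot, width=2_000_000,
                                      n_windows=8, seed=3,
                                      exclude=probe_annot.block)
        assert len(wins) == 8
        bc, bs, be = probe_annot.block
        for c, s, e in wins:
            assert c not in ("chrX", "chrY")
            assert not (c == bc and s <= be and e >= bs)
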