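"""Beta computation, quantile normalization, probe-type adjustment, filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ks_2samp

from gdmomics import synth
from gdmomics.meth import (BetaMatrix, adjust_probe_type, compute_beta,
                           filter_probes, intensities_to_beta,
                           quantile_normalize)


class TestComputeBeta:
    @pytest.mark.parametrize("M,U,expected", [
        (0.0, 0.0, 0.0),
        (100.0, 100.0, 100.0 / 300.0),
        (50.0, 150.0, 50.0 / 300.0),
        (1e6, 0.0, 1e6 / (1e6 + 100.0)),
    ])
    def test_formula(self, M, U, expected):
        assert compute_beta(M, U) == pytest.approx(expected, rel=1e-12)

    def test_always_below_one(self, rng):
        M = rng.uniform(0, 1e7, size=1000)
        U = rng.uniform(0, 1e7, size=1000)
        b = compute_beta(M, U)
        assert (b >= 0).all() and (b < 1).all()

    def test_negative_intensity_names_probe_and_sample(self):
        M = pd.DataFrame([[1.0, -2.0]], index=["cgA"], columns=["s1", "s2"])
        U = pd.DataFrame([[1.0, 1.0]], index=["cgA"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="cgA.*s2"):
            compute_beta(M, U)

    def test_zero_offset_inverts_generator_exactly(self, cohort20, probe_annot):
        """With zero noise the generated intensities carry the true
        (type-compressed) betas exactly; compute_beta with offset 0 is the
        exact inverse of the intensity construction."""
        cfg = synth.MethylationEffects(noise_sd=0.0, batch_sd=0.0,
                                       n_affected_sites=0, n_regions=0,
                                       n_block_sites=0)
        im, _ = synth.generate_methylation(cohort20, probe_annot, cfg, seed=5)
        b = compute_beta(im.methylated, im.unmethylated, offset=0.0)
        # within probe type the values are the noise-free apparent betas:
        # identical across samples
        assert np.allclose(b.to_numpy().std(axis=1), 0.0, atol=1e-12)


class TestQuantileNormalize:
    def test_two_sample_order_statistics_mean(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        assert np.allclose(out["a"], [2.5, 3.5, 4.5])
        assert np.allclose(out["b"], [2.5, 3.5, 4.5])

    def test_identical_columns_fixed_point(self, rng):
        col = np.sort(rng.normal(size=50))
        m = pd.DataFrame({"a": col, "b": col[::-1]})
        out = quantile_normalize(m)
        assert np.allclose(np.sort(out["a"]), np.sort(out["b"]))
        assert np.allclose(np.sort(out["a"].to_numpy()), np.sort(col))

    def test_distributions_identical_after(self, rng):
        m = pd.DataFrame(rng.lognormal(0, 1, size=(300, 4)))
        out = quantile_normalize(m)
        for j in range(1, 4):
            assert ks_2samp(out[0], out[j]).statistic == pytest.approx(0, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_ranks_preserved(self, seed):
        r = np.random.default_rng(seed)
        m = pd.DataFrame(r.normal(size=(40, 3)))
        out = quantile_normalize(m)
        for j in range(3):
            assert (np.argsort(out[j].to_numpy(), kind="stable")
                    == np.argsort(m[j].to_numpy(), kind="stable")).all()

    def test_single_sample_identity_with_warning(self):
        m = pd.DataFrame({"a": [3.0, 1.0]})
        with pytest.warns(UserWarning):
            out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out, m)


class TestAdjustProbeType:
    def _beta(self, probe_annot, meth_study):
        im, _ = meth_study
        return intensities_to_beta(im)

    def test_type_one_values_never_altered(self, probe_annot, meth_study):
        b = self._beta(probe_annot, meth_study)
        out = adjust_probe_type(b, probe_annot)
        is1 = probe_annot.probes["probe_type"] == "I"
        pd.testing.assert_frame_equal(out.values.loc[is1], b.values.loc[is1])

    def test_type_two_rank_order_preserved(self, probe_annot, meth_study):
        b = self._beta(probe_annot, meth_study)
        out = adjust_probe_type(b, probe_annot)
        is2 = (probe_annot.probes["probe_type"] == "II").to_numpy()
        col = b.values.columns[0]
        before = b.values.loc[is2, col].rank()
        after = out.values.loc[is2, col].rank()
        assert (before == after).all()

    def test_compression_removed(self, probe_annot, meth_study):
        """The generator compresses type II betas toward 0.5; after quantile
        mapping, the median gap between the type distributions shrinks >=90%."""
        b = self._beta(probe_annot, meth_study)
        out = adjust_probe_type(b, probe_annot)
        is1 = (probe_annot.probes["probe_type"] == "I").to_numpy()
        def spread_gap(mat):
            s1 = mat.loc[is1].to_numpy().std()
            s2 = mat.loc[~is1].to_numpy().std()
            return abs(s1 - s2)
        assert spread_gap(out.values) < 0.1 * spread_gap(b.values)

    def test_too_few_probes_skips_with_warning(self):
        idx = [f"cg{i}" for i in range(20)]
        probes = pd.DataFrame({
            "chrom": "chr1", "position": np.arange(20) * 1000 + 1,
            "probe_type": ["I"] * 10 + ["II"] * 10,
            "snp_at_target": False, "cross_hyb_x": False}, index=idx)
        annot = synth.ProbeAnnotation(probes=probes)
        b = BetaMatrix(values=pd.DataFrame(
            np.random.default_rng(0).uniform(size=(20, 3)), index=idx))
        with pytest.warns(UserWarning, match="skipped"):
            out = adjust_probe_type(b, annot)
        pd.testing.assert_frame_equal(out.values, b.values)


def _toy_beta_annot():
    idx = [f"cg{i}" for i in range(10)]
    probes = pd.DataFrame({
        "chrom": ["chr1"] * 6 + ["chrX"] * 2 + ["chr2"] * 2,
        "position": [100, 200, 300, 400, 500, 600, 100, 200, 100, 200],
        "probe_type": "II",
        "snp_at_target": [True] + [False] * 9,
        "cross_hyb_x": [False] * 5 + [True] + [False] * 4,
    }, index=pd.Index(idx, name="probe_id"))
    beta = BetaMatrix(values=pd.DataFrame(
        np.full((10, 2), 0.5), index=idx, columns=["s1", "s2"]))
    return beta, synth.ProbeAnnotation(probes=probes)


class TestFilterProbes:
    def test_toy_counts(self):
        beta, annot = _toy_beta_annot()
        out = filter_probes(beta, annot)
        # removed: 1 SNP, 1 cross-hyb, 2 chrX -> 6 retained
        assert len(out.values) == 6
        rep = out.filter_report.set_index("criterion")["n"]
        assert rep["non_autosomal"] == 2
        assert rep["snp_at_target"] == 1
        assert rep["cross_hyb_x"] == 1
        assert rep["retained"] == 6

    def test_idempotent(self):
        beta, annot = _toy_beta_annot()
        once = filter_probes(beta, annot)
        twice = filter_probes(once, annot)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_multiply_flagged_probe_counted_under_each_criterion(self):
        beta, annot = _toy_beta_annot()
        annot.probes.loc["cg6", "snp_at_target"] = True  # chrX AND SNP
        out = filter_probes(beta, annot)
        rep = out.filter_report.set_index("criterion")["n"]
        assert rep["non_autosomal"] == 2 and rep["snp_at_target"] == 2
        assert len(out.values) == 6  # removed once

    def test_missing_annotation_rejected(self):
        beta, annot = _toy_beta_annot()
        annot2 = synth.ProbeAnnotation(probes=annot.probes.drop(index=["cg3"]))
        with pytest.raises(ValueError, match="missing annotation"):
            filter_probes(beta, annot2)

    def test_clean_autosomal_input_identity(self):
        beta, annot = _toy_beta_annot()
        clean = annot.probes.copy()
        clean["chrom"] = "chr1"
        clean["position"] = np.arange(10) * 100 + 1
        clean["snp_at_target"] = False
        clean["cross_hyb_x"] = False
        out = filter_probes(beta, synth.ProbeAnnotation(probes=clean))
        assert len(out.values) == 10
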