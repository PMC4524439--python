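"""Bump hunting vs a brute-force maximal-run enumeration oracle."""

import numpy as np
import pandas as pd
import pytest

from gdmomics import synth
from gdmomics.bumps import (find_bumps, rank_candidates_for_validation,
                            regions_to_bed)


def _toy(positions, t_stats, effects=None, chrom="chr1"):
    """Build an aligned (assoc, annot) pair from raw vectors."""
    n = len(positions)
    idx = pd.Index([f"cg{i:04d}" for i in range(n)], name="probe_id")
    if effects is None:
        effects = np.sign(t_stats) * 0.05
    assoc = pd.DataFrame({"effect": effects, "t_stat": t_stats,
                          "p_value": np.full(n, 1e-5), "robust_se": 0.01,
                          "n": 40}, index=idx)
    probes = pd.DataFrame({"chrom": chrom, "position": positions,
                           "probe_type": "II", "snp_at_target": False,
                           "cross_hyb_x": False}, index=idx)
    return assoc, synth.ProbeAnnotation(probes=probes)


def brute_force_regions(positions, t_stats, effects, threshold, max_gap=500,
                        min_probes=2, strict=True, split_sign=True):
    """Oracle: enumerate maximal qualifying runs by direct definition."""
    n = len(positions)
    cand = np.abs(t_stats) >= threshold
    runs, cur = [], []
    for i in range(n):
        if not cand[i]:
            if strict and cur:
                runs.append(cur); cur = []
            continue
        if cur and positions[i] - positions[cur[-1]] <= max_gap:
            cur.append(i)
        else:
            if cur:
                runs.append(cur)
            cur = [i]
    if cur:
        runs.append(cur)
    final = []
    for run in runs:
        if split_sign:
            piece = [run[0]]
            for i in run[1:]:
                if np.sign(effects[i]) == np.sign(effects[piece[-1]]):
                    piece.append(i)
                else:
                    final.append(piece); piece = [i]
            final.append(piece)
        else:
            final.append(run)
    return [r for r in final if len(r) >= min_probes]


class TestHandTraces:
    def test_three_candidates_within_gap_form_one_region(self):
        assoc, annot = _toy([100, 400, 800], [5.0, 6.0, 5.5])
        res = find_bumps(assoc, annot, quantile=0.0)
        assert len(res.regions) == 1
        r = res.regions.iloc[0]
        assert r["n_probes"] == 3 and r["start"] == 100 and r["end"] == 800

    def test_gap_over_500_splits_into_unreported_singletons(self):
        assoc, annot = _toy([100, 700], [5.0, 6.0])
        res = find_bumps(assoc, annot, quantile=0.0, min_probes=2)
        assert len(res.regions) == 0
        assert len(res.singletons) == 2

    def test_intervening_subthreshold_probe_breaks_run_in_strict_mode(self):
        assoc, annot = _toy([100, 300, 500], [5.0, 0.1, 5.0])
        strict = find_bumps(assoc, annot, quantile=0.6, min_probes=2)
        assert len(strict.regions) == 0  # broken into two singletons
        loose = find_bumps(assoc, annot, quantile=0.6, min_probes=2, strict=False)
        assert len(loose.regions) == 1 and loose.regions.iloc[0]["n_probes"] == 2

    def test_mixed_sign_run_split(self):
        assoc, annot = _toy([100, 300, 500, 700], [5.0, 5.5, -5.0, -6.0],
                            effects=[0.1, 0.1, -0.1, -0.1])
        res = find_bumps(assoc, annot, quantile=0.0)
        assert len(res.regions) == 2
        assert res.regions["summary_effect"].tolist() == pytest.approx([0.1, -0.1])

    def test_unsorted_input_rejected(self):
        assoc, annot = _toy([100, 400, 800], [5.0, 6.0, 5.5])
        annot.probes["position"] = [800, 100, 400]
        with pytest.raises(ValueError, match="sorted"):
            find_bumps(assoc, annot)

    def test_empty_candidate_set_gives_empty_list(self):
        assoc, annot = _toy([100, 400], [0.1, 0.2])
        res = find_bumps(assoc, annot, quantile=0.999999)
        # the quantile threshold always admits the max |t| probe; push above
        assoc2 = assoc.copy()
        res = find_bumps(assoc2, annot, quantile=0.999999)
        assert len(res.regions) == 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("strict", [True, False])
    def test_random_instances_match_brute_force(self, strict):
        r = np.random.default_rng(99)
        for _ in range(150):
            n = int(r.integers(5, 200))
            pos = np.sort(r.choice(np.arange(1, 50_000), size=n, replace=False))
            t = r.normal(0, 2, n)
            eff = np.sign(t) * r.uniform(0.01, 0.2, n)
            assoc, annot = _toy(pos, t, eff)
            q = float(r.uniform(0.5, 0.95))
            res = find_bumps(assoc, annot, quantile=q, strict=strict)
            thr = np.quantile(np.abs(t), q)
            oracle = brute_force_regions(pos, t, eff, thr, strict=strict)
            got = [tuple(map(int, np.searchsorted(pos, (rr["start"], rr["end"]))))
                   for _, rr in res.regions.iterrows()]
            want = [(run[0], run[-1]) for run in oracle]
            assert sorted(got) == sorted(want)

    def test_regions_sorted_and_disjoint(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 30_000), size=150, replace=False))
        t = rng.normal(0, 2, 150)
        assoc, annot = _toy(pos, t)
        res = find_bumps(assoc, annot, quantile=0.6)
        reg = res.regions
        assert (reg["start"].diff().dropna() > 0).all()
        assert (reg["start"].to_numpy()[1:] > reg["end"].to_numpy()[:-1]).all()

    def test_raising_quantile_never_adds_candidates(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 30_000), size=150, replace=False))
        t = rng.normal(0, 2, 150)
        assoc, annot = _toy(pos, t)
        counts = []
        for q in (0.5, 0.7, 0.9, 0.99):
            res = find_bumps(assoc, annot, quantile=q, min_probes=1)
            counts.append(int(res.regions["n_probes"].sum()))
        assert counts == sorted(counts, reverse=True)


class TestCandidateRanking:
    def test_flagged_peak_excluded_and_ranked_by_effect(self):
        assoc, annot = _toy([100, 300, 2000, 2300],
                            [5.0, 5.5, 7.0, 6.0],
                            effects=[0.14, 0.14, 0.10, 0.10])
        annot.probes.loc["cg0002", "snp_at_target"] = True  # peak of region 2
        res = find_bumps(assoc, annot, quantile=0.0)
        cand = rank_candidates_for_validation(res, assoc, annot)
        kept = cand[~cand["excluded"]]
        assert len(kept) == 1 and kept.iloc[0]["summary_effect"] == pytest.approx(0.14)
        dropped = cand[cand["excluded"]]
        assert (dropped["exclusion_reason"] == "flagged_peak").all()

    def test_larger_effect_ranked_first(self):
        assoc, annot = _toy([100, 300, 2000, 2300],
                            [5.0, 5.5, 7.0, 6.0],
                            effects=[0.10, 0.10, 0.14, 0.14])
        res = find_bumps(assoc, annot, quantile=0.0)
        cand = rank_candidates_for_validation(res, assoc, annot)
        assert cand.iloc[0]["summary_effect"] == pytest.approx(0.14)

    def test_empty_region_list(self):
        assoc, annot = _toy([100, 700], [0.5, 0.4])
        res = find_bumps(assoc, annot, quantile=0.99)
        cand = rank_candidates_for_validation(res, assoc, annot)
        assert len(cand) == 0

    def test_bed_export_offsets(self):
        assoc, annot = _toy([100, 400], [5.0, 6.0])
        res = find_bumps(assoc, annot, quantile=0.0)
        bed = regions_to_bed(res.regions)
        assert bed.iloc[0]["start"] == 99 and bed.iloc[0]["end"] == 400
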