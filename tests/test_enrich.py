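"""Term universe, semantic similarity, closest-gene mapping, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from gdmomics import synth
from gdmomics.enrich import (TermUniverse, assign_closest_gene, closest_genes,
                             expression_enrichment, fdr_correct,
                             jiang_conrath, methylation_enrichment,
                             reduce_terms)


def _tiny_universe():
    """root -> {A, B}; A -> {A1, A2}; B -> {B1}.  20 genes at the root."""
    genes = [f"g{i}" for i in range(20)]
    parents = {"root": (), "A": ("root",), "B": ("root",),
               "A1": ("A",), "A2": ("A",), "B1": ("B",)}
    annotations = {"A1": set(genes[:5]), "A2": set(genes[3:8]),
                   "B1": set(genes[10:14]), "A": set(genes[8:10]),
                   "B": set(genes[14:16]), "root": set(genes)}
    return TermUniverse(parents=parents, annotations=annotations), genes


class TestTermUniverse:
    def test_ic_root_zero_and_monotone_to_leaves(self):
        u, _ = _tiny_universe()
        assert u.ic["root"] == 0.0
        for t, ps in u.parents.items():
            for p in ps:
                assert u.ic[t] >= u.ic[p] - 1e-12

    def test_annotation_propagates_up(self):
        u, genes = _tiny_universe()
        assert u.genes("A") >= u.genes("A1") | u.genes("A2")
        assert u.genes("root") == frozenset(genes)

    def test_cycle_rejected(self):
        with pytest.raises(Exception):
            TermUniverse(parents={"a": ("b",), "b": ("a",)},
                         annotations={"a": {"g"}, "b": {"g"}})


class TestJiangConrath:
    def test_identity_similarity_one(self):
        u, _ = _tiny_universe()
        for t in u.terms:
            assert jiang_conrath(t, t, u) == pytest.approx(1.0)

    def test_root_mica_formula_value(self):
        # IC(a) = IC(b) = 1 and MICA at the root -> d = 2, sim = 1/3
        genes = [f"g{i}" for i in range(100)]
        e = math.e
        k = round(100 / e)  # 37 genes -> IC ~ 1
        parents = {"root": (), "a": ("root",), "b": ("root",)}
        annotations = {"a": set(genes[:k]), "b": set(genes[-k:]),
                       "root": set(genes)}
        u = TermUniverse(parents=parents, annotations=annotations)
        d = u.ic["a"] + u.ic["b"]
        assert jiang_conrath("a", "b", u) == pytest.approx(1.0 / (1.0 + d))
        assert jiang_conrath("a", "b", u) == pytest.approx(1.0 / 3.0, abs=0.01)

    def test_symmetric(self):
        u, _ = _tiny_universe()
        terms = u.terms
        r = np.random.default_rng(0)
        for _ in range(30):
            a, b = r.choice(terms, size=2)
            assert jiang_conrath(a, b, u) == jiang_conrath(b, a, u)

    def test_linear_scaling_option(self):
        u, _ = _tiny_universe()
        assert jiang_conrath("A1", "A1", u, scaling="linear") == 1.0

    def test_unknown_term_rejected(self):
        u, _ = _tiny_universe()
        with pytest.raises(KeyError):
            jiang_conrath("A1", "nope", u)


class TestReduceTerms:
    def test_planted_duplicate_clusters_collapse_to_representatives(self):
        bun = synth.generate_term_universe(n_genes=500, n_terms=40, seed=22)
        reps = reduce_terms(bun.universe, min_genes=10, max_genes=400)
        for cluster in bun.duplicate_clusters:
            sized = [t for t in cluster
                     if 10 <= len(bun.universe.genes(t)) <= 400]
            survivors = set(reps) & set(cluster)
            assert len(survivors) == 1
            # representative is the largest-annotation member
            best = max(sized, key=lambda t: (len(bun.universe.genes(t)),
                                             [-ord(c) for c in t]))
            assert survivors == {best}

    def test_exact_duplicates_keep_lexicographically_smallest(self):
        genes = [f"g{i}" for i in range(30)]
        parents = {"root": (), "x": ("root",), "y": ("root",)}
        annotations = {"x": set(genes[:25]), "y": set(genes[:25]),
                       "root": set(genes)}
        u = TermUniverse(parents=parents, annotations=annotations)
        reps = reduce_terms(u, min_genes=5, max_genes=29)
        assert reps == ["x"]

    def test_size_window_filters(self):
        u, _ = _tiny_universe()
        reps = reduce_terms(u, min_genes=6, max_genes=15, sim_cutoff=0.99)
        sizes = {t: len(u.genes(t)) for t in reps}
        assert all(6 <= s <= 15 for s in sizes.values())

    def test_order_invariance(self):
        bun = synth.generate_term_universe(n_genes=300, n_terms=30, seed=7)
        reps1 = reduce_terms(bun.universe, min_genes=10, max_genes=290)
        # rebuild with shuffled dict insertion order
        items = list(bun.universe.parents.items())[::-1]
        ann = {t: set(bun.universe.genes(t)) for t, _ in items}
        u2 = TermUniverse(parents=dict(items), annotations=ann)
        reps2 = reduce_terms(u2, min_genes=10, max_genes=290)
        assert reps1 == reps2

    def test_empty_window_rejected(self):
        u, _ = _tiny_universe()
        with pytest.raises(ValueError, match="size window"):
            reduce_terms(u, min_genes=1000, max_genes=1500)


class TestClosestGene:
    def test_inside_gene_body_distance_zero(self, probe_annot, gene_annot):
        g = gene_annot.genes.iloc[0]
        pos = np.array([(g["start"] + g["end"]) // 2])
        gid, dist = closest_genes(g["chrom"], pos, gene_annot)
        assert dist[0] == 0

    def test_equidistant_tie_goes_to_smaller_id(self):
        genes = pd.DataFrame({
            "chrom": "chr1", "start": [1000, 3000], "end": [1500, 3500],
            "tss": [1000, 3000], "coding": True}, index=["gB", "gA"])
        ga = synth.GeneAnnotation(genes=genes)
        gid, dist = closest_genes("chr1", np.array([2250]), ga)
        assert dist[0] == 750 and gid[0] == "gA"

    def test_matches_brute_force(self, gene_annot, rng):
        genes = gene_annot.genes
        for _ in range(50):
            chrom = str(rng.choice(genes["chrom"].unique()))
            pos = int(rng.integers(1, 20_000_000))
            gid, dist = closest_genes(chrom, np.array([pos]), gene_annot)
            sub = genes[genes["chrom"] == chrom]
            d = np.where((pos >= sub["start"]) & (pos <= sub["end"]), 0,
                         np.minimum((sub["start"] - pos).abs(),
                                    (sub["end"] - pos).abs()))
            want = min(zip(d, sub.index))
            assert (dist[0], gid[0]) == (want[0], want[1])

    def test_probe_level_wrapper(self, probe_annot, gene_annot):
        cpg = probe_annot.probes.index[0]
        gid = assign_closest_gene(cpg, probe_annot, gene_annot)
        assert gid == probe_annot.probes.loc[cpg, "nearest_gene_id"]


def brute_hypergeom_tail(k, N, K, n):
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += (math.comb(K, x) * math.comb(N - K, n - x)) / math.comb(N, n)
    return total


class TestExpressionEnrichment:
    def test_tail_matches_brute_force_summation(self):
        bun = synth.generate_term_universe(n_genes=200, n_terms=25, seed=9,
                                           plant_dense_term=False)
        u = bun.universe
        universe = sorted(u.genes(u.root))
        r = np.random.default_rng(10)
        sig = set(r.choice(universe, size=40, replace=False))
        res = expression_enrichment(sig, universe, u)
        for _, row in res.table.iterrows():
            want = brute_hypergeom_tail(int(row["n_sig_genes_in_term"]),
                                        len(universe),
                                        int(row["n_genes_in_term"]), 40)
            assert row["p_value"] == pytest.approx(want, rel=1e-9)

    def test_sig_equals_universe_gives_p_one(self):
        u, genes = _tiny_universe()
        res = expression_enrichment(set(genes), genes, u)
        assert np.allclose(res.table["p_value"], 1.0)

    def test_planted_enrichment_ranks_first(self):
        u, genes = _tiny_universe()
        sig = set(u.genes("A1"))  # 100% of one term
        res = expression_enrichment(sig, genes, u)
        assert res.table.iloc[0]["term_id"] == "A1"

    def test_sig_outside_universe_rejected(self):
        u, genes = _tiny_universe()
        with pytest.raises(ValueError):
            expression_enrichment({"not_a_gene"}, genes, u)


class TestMethylationEnrichment:
    def _setup(self, seed=0):
        ga = synth.generate_gene_annotation(60, seed=seed)
        pa = synth.generate_probe_annotation(ga, n_probes=500, seed=seed + 1)
        bun = synth.generate_term_universe(
            n_terms=15, seed=seed + 2, gene_ids=list(ga.genes.index),
            plant_dense_term=False)
        return ga, pa, bun.universe

    def test_minimum_attainable_p_is_one_over_resamples_plus_one(self):
        ga, pa, u = self._setup()
        # significant set = every probe mapping to one term's genes
        term = next(t for t in u.terms
                    if t != u.root and 5 <= len(u.genes(t)) <= 30)
        tg = u.genes(term)
        sig = set(pa.probes.index[pa.probes["nearest_gene_id"].isin(tg)])
        res = methylation_enrichment(sig, pa, u, terms=[term],
                                     n_resamples=200, seed=3)
        p = float(res.table["p_value"].iloc[0])
        assert p >= 1.0 / 201.0  # the +1 estimator can never reach zero
        assert p < 0.05

    def test_empty_sig_set_rejected(self):
        ga, pa, u = self._setup()
        with pytest.raises(ValueError):
            methylation_enrichment(set(), pa, u, n_resamples=10, seed=0)

    def test_deterministic_under_seed(self):
        ga, pa, u = self._setup(seed=5)
        sig = set(pa.probes.index[:30])
        a = methylation_enrichment(sig, pa, u, n_resamples=100, seed=8)
        b = methylation_enrichment(sig, pa, u, n_resamples=100, seed=8)
        pd.testing.assert_frame_equal(a.table, b.table)


def brute_bh(p):
    """Textbook step-up Benjamini-Hochberg q-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


class TestFdrCorrect:
    def test_hand_computed_example(self):
        q = fdr_correct([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert (fdr_correct([1.0, 1.0, 1.0]) == 1.0).all()

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.uniform(size=60)
        q = fdr_correct(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.uniform(0.0001, 1.0, size=int(rng.integers(1, 100)))
            assert np.allclose(fdr_correct(p), brute_bh(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_correct([0.0, 0.5])
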