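"""Calibration and recovery experiments over the synthetic study.

Each function measures one operating characteristic of the pipeline --
type-I error of the robust Wald models, sensitivity and bias at injected
effects, bump-hunting recovery, surrogate selection behavior, mixed-model
coverage, design-bias correction of the resampling enrichment null, and FDR
control of the window networks -- by running the actual package code on
generated data with known truth.  They are consumed by the acceptance
checks and by ``scripts/acceptance.py``.

Problem sizes are desk scale (hundreds of probes, tens to low hundreds of
replicate simulations), chosen so the full battery runs in a few minutes
while Monte-Carlo error stays well inside the tolerances being checked.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import synth
from .bumps import find_bumps
from .enrich import methylation_enrichment, fdr_correct
from .meth import filter_probes, intensities_to_beta, preprocess_methylation
from .models import build_design, run_ewas, run_twas
from .regional import fit_region_model
from .regional import test_effect_modification as _interaction_test
from .surrogates import estimate_surrogates
from .window import build_networks, permutation_spearman
from ._util import child_seeds


def _null_meth_cfg(**kw):
    return synth.MethylationEffects(n_affected_sites=0, n_regions=0,
                                    n_block_sites=0, batch_sd=0.0, **kw)


# ---------------------------------------------------------------------------
# type-I error
# ---------------------------------------------------------------------------

def ewas_type1_rate(seed: int, n_pairs: int = 41, n_probes: int = 2000,
                    alpha: float = 0.05) -> dict:
    """Robust-Wald rejection rate on a null methylation dataset."""
    seeds = child_seeds(seed, ["cohort", "genes", "probes", "meth"])
    design = synth.generate_cohort(n_pairs, seed=seeds["cohort"])
    ga = synth.generate_gene_annotation(150, seed=seeds["genes"])
    pa = synth.generate_probe_annotation(ga, n_probes=n_probes,
                                         seed=seeds["probes"])
    im, _ = synth.generate_methylation(design, pa, _null_meth_cfg(),
                                       seed=seeds["meth"])
    beta = intensities_to_beta(im)
    at = run_ewas(beta, design.samples, alpha=alpha)
    rate = float((at.table["p_value"] < alpha).mean())
    return {"rate": rate, "n_features": len(at.table), "alpha": alpha}


def twas_type1_rate(seed: int, n_pairs: int = 41, n_genes: int = 2000,
                    alpha: float = 0.05) -> dict:
    """Robust-Wald rejection rate on null summarized expression."""
    seeds = child_seeds(seed, ["cohort", "genes", "expr"])
    design = synth.generate_cohort(n_pairs, seed=seeds["cohort"])
    ga = synth.generate_gene_annotation(n_genes, seed=seeds["genes"])
    cfg = synth.ExpressionEffects(n_affected_genes=0, gene_effect=0.0,
                                  block_effect=0.0, batch_sd=0.0,
                                  probes_per_gene_mean=3.0)
    tab, _ = synth.generate_expression(design, ga, cfg, seed=seeds["expr"])
    from .expr import preprocess_expression
    em = preprocess_expression(tab)
    at = run_twas(em, design.samples, alpha=alpha, coding_only=False)
    rate = float((at.table["p_value"] < alpha).mean())
    return {"rate": rate, "n_features": len(at.table), "alpha": alpha}


def spearman_null_pvalues(seed: int, n_tests: int = 200, n: int = 30,
                          n_perm: int = 2000) -> np.ndarray:
    """Permutation Spearman p-values for independent pairs (null)."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_tests)
    for i in range(n_tests):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        _, out[i] = permutation_spearman(x, y, n_perm=n_perm, seed=int(seed) + i)
    return out


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

def ewas_recovery(seed: int, n_sims: int = 200, n_pairs: int = 40,
                  n_probes: int = 300, n_sites: int = 20,
                  effect: float = 0.10, alpha: float = 0.001) -> dict:
    """Sensitivity and effect-estimate bias at injected site effects.

    Type II compression is disabled here so the measurement isolates the
    estimation path (compression and its correction have their own tests).
    """
    seeds = child_seeds(seed, ["genes", "probes", "sims"])
    ga = synth.generate_gene_annotation(80, seed=seeds["genes"])
    pa = synth.generate_probe_annotation(ga, n_probes=n_probes,
                                         seed=seeds["probes"])
    cfg = synth.MethylationEffects(n_affected_sites=n_sites, site_effect=effect,
                                   n_regions=0, n_block_sites=0, batch_sd=0.0,
                                   type2_compression=1.0)
    sens, errs = [], []
    sim_rng = np.random.SeedSequence(seeds["sims"])
    for child in sim_rng.spawn(n_sims):
        s = int(child.generate_state(1)[0] % (2**31))
        design = synth.generate_cohort(n_pairs, seed=s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            im, truth = synth.generate_methylation(design, pa, cfg, seed=s + 1)
            beta = filter_probes(intensities_to_beta(im), pa)
            at = run_ewas(beta, design.samples, alpha=alpha)
        injected = [p for p in truth.affected_cpgs["probe_id"]
                    if p in at.table.index]
        hits = (at.table.loc[injected, "p_value"] < alpha).mean()
        sens.append(float(hits))
        errs.append(float(at.table.loc[injected, "effect"].mean() - effect))
    errs = np.asarray(errs)
    return {"sensitivity": float(np.mean(sens)),
            "mean_effect_error": float(errs.mean()),
            "mc_se": float(errs.std(ddof=1) / np.sqrt(len(errs))),
            "n_sims": n_sims}


def bump_recovery(seed: int, n_sims: int = 100, n_pairs: int = 40,
                  n_probes: int = 400, region_effect: float = 0.08) -> dict:
    """Fraction of injected 5-probe regions overlapped by a called region."""
    seeds = child_seeds(seed, ["genes", "probes", "sims"])
    ga = synth.generate_gene_annotation(80, seed=seeds["genes"])
    pa = synth.generate_probe_annotation(ga, n_probes=n_probes,
                                         seed=seeds["probes"], island_prob=0.6)
    cfg = synth.MethylationEffects(n_affected_sites=0, n_regions=1,
                                   region_n_probes=5,
                                   region_effect=region_effect,
                                   n_block_sites=0, batch_sd=0.0)
    hits, total = 0, 0
    sim_rng = np.random.SeedSequence(seeds["sims"])
    for child in sim_rng.spawn(n_sims):
        s = int(child.generate_state(1)[0] % (2**31))
        design = synth.generate_cohort(n_pairs, seed=s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            im, truth = synth.generate_methylation(design, pa, cfg, seed=s + 1)
            beta = filter_probes(intensities_to_beta(im), pa)
            at = run_ewas(beta, design.samples)
            res = find_bumps(at, pa)
        for _, tr in truth.affected_regions.iterrows():
            total += 1
            ov = res.regions[(res.regions["chrom"] == tr["chrom"])
                             & (res.regions["start"] <= tr["end"])
                             & (res.regions["end"] >= tr["start"])]
            hits += int(len(ov) > 0)
    return {"overlap_rate": hits / total if total else float("nan"),
            "n_regions": total}


# ---------------------------------------------------------------------------
# surrogates
# ---------------------------------------------------------------------------

def surrogate_batch_removal(seed: int, n_pairs: int = 20,
                            batch_sd: float = 0.4) -> dict:
    """Fraction of injected batch-shift variance captured by selected
    surrogates (squared projection of the residualized true shift vector
    onto the selected component span)."""
    seeds = child_seeds(seed, ["cohort", "genes", "probes", "meth", "sv"])
    design = synth.generate_cohort(n_pairs, seed=seeds["cohort"])
    ga = synth.generate_gene_annotation(100, seed=seeds["genes"])
    pa = synth.generate_probe_annotation(ga, n_probes=1200, seed=seeds["probes"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        im, truth = synth.generate_methylation(
            design, pa, synth.MethylationEffects(
                n_affected_sites=0, n_regions=0, n_block_sites=0,
                batch_sd=batch_sd), seed=seeds["meth"])
        beta = preprocess_methylation(im, pa)
        X, _ = build_design(design.samples)
        sv = estimate_surrogates(beta.values, X,
                                 design.samples[["chip", "row", "column",
                                                 "ethnicity"]],
                                 seed=seeds["sv"])
    s = truth.batch_shift.to_numpy()
    P = X @ np.linalg.pinv(X)
    sres = s - P @ s
    if sv.n_selected == 0:
        frac = 0.0
    else:
        Z = sv.selected - P @ sv.selected
        proj = Z @ np.linalg.pinv(Z)
        frac = float((sres @ proj @ sres) / (sres @ sres))
    return {"variance_removed": frac, "n_selected": sv.n_selected}


def surrogate_null_selection_rate(seed: int, n_runs: int = 100,
                                  n_pairs: int = 20) -> dict:
    """Fraction of pure-noise runs in which any surrogate is selected."""
    seeds = child_seeds(seed, ["genes", "probes", "runs"])
    ga = synth.generate_gene_annotation(100, seed=seeds["genes"])
    pa = synth.generate_probe_annotation(ga, n_probes=800, seed=seeds["probes"])
    conf_cols = ["chip", "row", "column", "ethnicity"]
    count = 0
    for child in np.random.SeedSequence(seeds["runs"]).spawn(n_runs):
        s = int(child.generate_state(1)[0] % (2**31))
        design = synth.generate_cohort(n_pairs, seed=s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            im, _ = synth.generate_methylation(design, pa, _null_meth_cfg(),
                                               seed=s + 1)
            beta = intensities_to_beta(im)
            X, _ = build_design(design.samples)
            sv = estimate_surrogates(beta.values, X, design.samples[conf_cols],
                                     seed=s + 2)
        count += int(sv.n_selected > 0)
    return {"selection_rate": count / n_runs, "n_runs": n_runs}


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------

def _pyro_long(n_pairs, effect, seed, re_sd=3.0, noise_sd=4.0,
               modifier_effects=None):
    r = np.random.default_rng(seed)
    n = 2 * n_pairs
    samples = pd.DataFrame({
        "gdm": np.repeat([1, 0], n_pairs),
        "age": r.normal(32, 4, n).round(1),
        "bmi": r.normal(26, 4, n).round(1),
        "sex": r.integers(0, 2, n),
        "smoking": r.integers(0, 2, n),
        "ethnicity": r.choice(["w", "b", "a"], n),
    }, index=pd.Index([f"S{i:03d}" for i in range(n)], name="sample_id"))
    u = r.normal(0, re_sd, n)
    mod = r.integers(0, 2, n) if modifier_effects is not None else None
    rows = []
    for j, mean in enumerate((55.0, 60.0)):
        eff = np.full(n, effect) if modifier_effects is None \
            else np.asarray([modifier_effects[m] for m in mod])
        vals = mean + u + eff * samples["gdm"].to_numpy() \
            + r.normal(0, noise_sd, n)
        rows.append(pd.DataFrame({"sample_id": samples.index,
                                  "cpg": f"cpg{j}", "percent": vals}))
    long = pd.concat(rows, ignore_index=True).join(samples, on="sample_id")
    if mod is not None:
        long = long.merge(pd.Series(mod, index=samples.index, name="mod"),
                          left_on="sample_id", right_index=True)
    return long


def mixed_model_calibration(seed: int, n_sims: int = 200, n_pairs: int = 40,
                            effect: float = -9.0) -> dict:
    """Bias and 95% CI coverage of the regional mixed-model GDM effect."""
    coefs, cover = [], []
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_sims)):
        s = int(child.generate_state(1)[0] % (2**31))
        long = _pyro_long(n_pairs, effect, s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_region_model(long)
        coefs.append(fit.coef)
        cover.append(fit.ci_low <= effect <= fit.ci_high)
    coefs = np.asarray(coefs)
    return {"mean_coef": float(coefs.mean()),
            "mc_se": float(coefs.std(ddof=1) / np.sqrt(n_sims)),
            "coverage": float(np.mean(cover)), "n_sims": n_sims}


def interaction_power(seed: int, n_sims: int = 100, n_pairs: int = 40,
                      effects=(-6.0, 6.0)) -> dict:
    """Power of the GDM x modifier interaction Wald test for opposite-sign
    stratum effects."""
    hits = 0
    done = 0
    for child in np.random.SeedSequence(seed).spawn(n_sims):
        s = int(child.generate_state(1)[0] % (2**31))
        long = _pyro_long(n_pairs, 0.0, s,
                          modifier_effects={0: effects[0], 1: effects[1]})
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = _interaction_test(long, "mod")
        except ValueError:
            continue
        done += 1
        hits += int(res.interaction_p < 0.05)
    return {"power": hits / done if done else float("nan"), "n_sims": done}


# ---------------------------------------------------------------------------
# enrichment design bias
# ---------------------------------------------------------------------------

def _probe_array_from_counts(probe_counts: pd.Series) -> synth.ProbeAnnotation:
    """Minimal probe table realizing a per-gene probe-count profile."""
    rows = []
    i = 0
    for g, k in probe_counts.items():
        for _ in range(int(k)):
            rows.append(dict(chrom="chr1", position=10 * i + 1,
                             probe_type="II", snp_at_target=False,
                             cross_hyb_x=False, nearest_gene_id=g,
                             distance_to_gene=0))
            i += 1
    df = pd.DataFrame(rows)
    df.index = pd.Index([f"cg{j:06d}" for j in range(len(df))],
                        name="probe_id")
    return synth.ProbeAnnotation(probes=df)


def design_bias_experiment(seed: int, n_experiments: int = 150,
                           n_genes: int = 150, n_sig: int = 300,
                           n_resamples: int = 500) -> dict:
    """Calibration of the resampling null vs the naive hypergeometric under a
    planted 10x probe-density imbalance.

    Random CpG sets are 'significant'; for the probe-dense term the
    resampling p should be uniform while the hypergeometric p (which ignores
    how CpG sampling over-represents probe-dense genes) rejects far too
    often.
    """
    seeds = child_seeds(seed, ["universe", "exps"])
    bun = synth.generate_term_universe(n_genes=n_genes, n_terms=25,
                                       seed=seeds["universe"],
                                       plant_dense_term=True)
    u, dense = bun.universe, bun.dense_term
    annot = _probe_array_from_counts(bun.probe_counts)
    probes = annot.probes.index.to_numpy()
    term_genes = u.genes(dense)
    gene_universe = sorted(set(annot.probes["nearest_gene_id"])
                           & u.genes(u.root))
    N, K = len(gene_universe), len(set(term_genes) & set(gene_universe))
    p_res, p_hyp = [], []
    for child in np.random.SeedSequence(seeds["exps"]).spawn(n_experiments):
        s = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(s)
        sig = set(rng.choice(probes, size=n_sig, replace=False))
        res = methylation_enrichment(sig, annot, u, terms=[dense],
                                     n_resamples=n_resamples, seed=s + 1)
        p_res.append(float(res.table["p_value"].iloc[0]))
        mapped = set(annot.probes.loc[sorted(sig), "nearest_gene_id"])
        k, n = len(mapped & set(term_genes)), len(mapped)
        p_hyp.append(float(stats.hypergeom.sf(k - 1, N, K, n)))
    p_res, p_hyp = np.asarray(p_res), np.asarray(p_hyp)
    return {"resampling_ks_p": float(stats.kstest(p_res, "uniform").pvalue),
            "resampling_frac05": float((p_res < 0.05).mean()),
            "hypergeom_frac05": float((p_hyp < 0.05).mean()),
            "n_experiments": n_experiments}


def balanced_probe_agreement(seed: int, n_genes: int = 150,
                             n_resamples: int = 2000) -> dict:
    """With balanced probe counts the resampling and hypergeometric nulls
    must agree: mean |p_resample - p_hypergeom| over the tested terms.

    One probe per gene makes probe draws and gene draws identical, so any
    residual difference is pure Monte-Carlo noise; with several (equal)
    probes per gene the resampling test additionally marginalizes over the
    mapped-set size while the hypergeometric conditions on it, a separate
    (small) difference unrelated to the design bias under test.
    """
    seeds = child_seeds(seed, ["universe", "sig"])
    bun = synth.generate_term_universe(n_genes=n_genes, n_terms=25,
                                       seed=seeds["universe"],
                                       plant_dense_term=False)
    u = bun.universe
    counts = pd.Series(1, index=sorted(u.genes(u.root)))
    annot = _probe_array_from_counts(counts)
    rng = np.random.default_rng(seeds["sig"])
    sig = set(rng.choice(annot.probes.index.to_numpy(), size=100,
                         replace=False))
    terms = [t for t in u.terms if t != u.root and len(u.genes(t)) >= 5]
    res = methylation_enrichment(sig, annot, u, terms=terms,
                                 n_resamples=n_resamples, seed=seeds["sig"] + 1)
    gene_universe = sorted(set(annot.probes["nearest_gene_id"]))
    N = len(gene_universe)
    mapped = set(annot.probes.loc[sorted(sig), "nearest_gene_id"])
    n = len(mapped)
    deltas = []
    for _, row in res.table.iterrows():
        K = int(row["n_genes_in_term"])
        k = int(row["n_sig_genes_in_term"])
        p_h = float(stats.hypergeom.sf(k - 1, N, K, n))
        deltas.append(abs(float(row["p_value"]) - p_h))
    return {"mean_abs_delta_p": float(np.mean(deltas)), "n_terms": len(deltas)}


# ---------------------------------------------------------------------------
# window-network FDR
# ---------------------------------------------------------------------------

def null_network_fdr(seed: int, n_sims: int = 50, n_cpgs: int = 20,
                     n_genes: int = 8, n_samples: int = 24,
                     n_perm: int = 400) -> dict:
    """Mean proportion of q<0.05 edges across null window networks."""
    props = []
    for child in np.random.SeedSequence(seed).spawn(n_sims):
        s = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(s)
        cols = [f"S{i}" for i in range(n_samples)]
        beta = pd.DataFrame(rng.uniform(0.2, 0.8, size=(n_cpgs, n_samples)),
                            index=[f"cg{i}" for i in range(n_cpgs)],
                            columns=cols)
        expr = pd.DataFrame(rng.normal(size=(n_genes, n_samples)),
                            index=[f"G{i}" for i in range(n_genes)],
                            columns=cols)
        nets = build_networks(beta, expr, n_perm=n_perm, seed=s + 1)
        n_edges = len(nets.all_meth_expr) + len(nets.all_expr_expr)
        n_sig = len(nets.meth_expr) + len(nets.expr_expr)
        props.append(n_sig / n_edges)
    return {"mean_sig_edge_proportion": float(np.mean(props)),
            "n_sims": n_sims}
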