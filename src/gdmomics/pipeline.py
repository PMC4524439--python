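"""End-to-end orchestration of the synthetic integrated study.

Stages run in a fixed order -- simulate, preprocess, surrogates, EWAS/TWAS,
bump hunting, pyrosequencing validation, window network, enrichment,
recovery report -- each consuming only files written by earlier stages into
the run directory, so any stage can be rerun (or audited) in isolation.  A
single master seed spawns independent per-stage seeds; rerunning with the
same configuration is bit-identical.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bumps as bumps_mod
from . import enrich, meth, models, regional, synth, window
from ._util import child_seeds, sha256_file, write_tsv, read_tsv
from .expr import preprocess_expression
from .surrogates import estimate_surrogates

STAGES = ["simulate", "preprocess", "surrogates", "ewas", "twas", "bumps",
          "pyro", "network", "enrich", "report"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All tunable parameters of a run.  ``seed`` is mandatory.

    Defaults are desk scale: a 10-pair cohort, a few thousand probes, 1000
    permutations/resamples.  Statistical thresholds default to the study
    conventions: alpha 0.001 for methylation and 0.01 for expression, bump
    hunting at the 99th percentile of |t| with a 500 bp gap, 10 kb CpG flank
    on the window, GO terms restricted to 20-1500 genes with the
    Jiang-Conrath 0.7 similarity cutoff.
    """

    seed: int
    n_pairs: int = 10
    n_probes: int = 2500
    n_genes: int = 300
    n_terms: int = 50
    ethnicity_chip_mix: float = 0.5
    # methylation effects
    n_affected_sites: int = 20
    site_effect: float = 0.10
    n_regions: int = 2
    region_n_probes: int = 5
    region_effect: float = 0.08
    n_block_sites: int = 10
    block_site_effect: float = -0.06
    meth_batch_sd: float = 0.3
    meth_noise_sd: float = 0.15
    # expression effects
    n_affected_genes: int = 50
    gene_effect: float = -0.5
    block_effect: float = -0.3
    probes_per_gene_mean: float = 21.0
    expr_batch_sd: float = 0.15
    # thresholds
    alpha_meth: float = 0.001
    alpha_expr: float = 0.01
    bump_max_gap: int = 500
    bump_quantile: float = 0.99
    bump_min_probes: int = 2
    window_flank: int = 10_000
    n_perm: int = 1000
    enrich_min_genes: int = 20
    enrich_max_genes: int = 1500
    enrich_sim_cutoff: float = 0.7
    n_resamples: int = 1000
    surrogate_q: float = 0.05
    surrogate_k_max: int | None = None
    pyro_depth: int = 30
    n_pyro_candidates: int = 4

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        for name in ("alpha_meth", "alpha_expr", "bump_quantile",
                     "enrich_sim_cutoff", "surrogate_q"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name}={v} must be in (0, 1)")
        for name in ("n_pairs", "n_probes", "n_genes", "n_terms", "n_perm",
                     "n_resamples", "bump_max_gap", "window_flank", "pyro_depth"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 <= self.ethnicity_chip_mix <= 1.0:
            raise ConfigError("ethnicity_chip_mix must be in [0, 1]")
        if self.enrich_min_genes >= self.enrich_max_genes:
            raise ConfigError("enrich_min_genes must be < enrich_max_genes")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ConfigError("config must set a seed")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _log(run_dir: Path, stage: str, payload: dict) -> None:
    rec = {"stage": stage, **payload}
    with open(run_dir / "run_log.jsonl", "a") as fh:
        fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")


def _hash_outputs(run_dir: Path, names: list[str]) -> dict[str, str]:
    return {n: sha256_file(run_dir / n) for n in names if (run_dir / n).exists()}


# ---------------------------------------------------------------------------
# stage implementations (file-to-file)
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, run_dir: Path) -> None:
    seeds = child_seeds(cfg.seed, STAGES)
    s = seeds["simulate"]
    design = synth.generate_cohort(cfg.n_pairs, seed=s,
                                   ethnicity_chip_mix=cfg.ethnicity_chip_mix)
    gene_annot = synth.generate_gene_annotation(cfg.n_genes, seed=s + 1)
    annot = synth.generate_probe_annotation(gene_annot, n_probes=cfg.n_probes,
                                            seed=s + 2)
    meff = synth.MethylationEffects(
        n_affected_sites=cfg.n_affected_sites, site_effect=cfg.site_effect,
        n_regions=cfg.n_regions, region_n_probes=cfg.region_n_probes,
        region_effect=cfg.region_effect, n_block_sites=cfg.n_block_sites,
        block_site_effect=cfg.block_site_effect, batch_sd=cfg.meth_batch_sd,
        noise_sd=cfg.meth_noise_sd)
    im, truth_m = synth.generate_methylation(design, annot, meff, seed=s + 3)
    eeff = synth.ExpressionEffects(
        n_affected_genes=cfg.n_affected_genes, gene_effect=cfg.gene_effect,
        block_effect=cfg.block_effect, probes_per_gene_mean=cfg.probes_per_gene_mean,
        batch_sd=cfg.expr_batch_sd)
    eprobes, truth_e = synth.generate_expression(design, gene_annot, eeff, seed=s + 4)
    bundle = synth.generate_term_universe(
        n_terms=cfg.n_terms, seed=s + 5, gene_ids=list(gene_annot.genes.index),
        plant_dense_term=False)

    write_tsv(design.samples, run_dir / "covariates.tsv")
    write_tsv(annot.probes, run_dir / "probe_annotation.tsv")
    write_tsv(gene_annot.genes, run_dir / "gene_annotation.tsv")
    write_tsv(im.methylated, run_dir / "intensity_meth.tsv")
    write_tsv(im.unmethylated, run_dir / "intensity_unmeth.tsv")
    write_tsv(eprobes, run_dir / "expression_probes.tsv")
    write_tsv(truth_m.affected_cpgs, run_dir / "truth_cpgs.tsv", index=False)
    write_tsv(truth_m.affected_regions, run_dir / "truth_regions.tsv", index=False)
    write_tsv(truth_e.affected_genes, run_dir / "truth_genes.tsv", index=False)
    edges = [(t, p) for t, ps in bundle.universe.parents.items() for p in ps]
    write_tsv(pd.DataFrame(edges, columns=["term", "parent"]),
              run_dir / "term_dag.tsv", index=False)
    # store the propagated term->gene map (propagation is idempotent, so IC
    # and enrichment are unchanged on reload)
    t2g = [(t, g) for t in bundle.universe.terms
           for g in sorted(bundle.universe.genes(t))]
    write_tsv(pd.DataFrame(t2g, columns=["term", "gene"]),
              run_dir / "term_genes.tsv", index=False)
    meta = {"block": list(annot.block),
            "region_probes": {str(k): v for k, v in truth_m.region_probes.items()},
            "block_genes": truth_e.block_genes,
            "clip_warnings": truth_m.clip_warnings}
    (run_dir / "truth_meta.json").write_text(json.dumps(meta, sort_keys=True))
    _log(run_dir, "simulate", {"params": asdict(cfg),
                               "hashes": _hash_outputs(run_dir, [
                                   "covariates.tsv", "probe_annotation.tsv",
                                   "intensity_meth.tsv", "expression_probes.tsv"])})


def _load_annot(run_dir: Path):
    meta = json.loads((run_dir / "truth_meta.json").read_text())
    block = tuple(meta["block"])
    probes = read_tsv(run_dir / "probe_annotation.tsv")
    genes = read_tsv(run_dir / "gene_annotation.tsv")
    return (synth.ProbeAnnotation(probes=probes, block=block),
            synth.GeneAnnotation(genes=genes, block=block), meta)


def stage_preprocess(cfg: PipelineConfig, run_dir: Path) -> None:
    annot, _, _ = _load_annot(run_dir)
    im = synth.IntensityMatrix(
        methylated=read_tsv(run_dir / "intensity_meth.tsv"),
        unmethylated=read_tsv(run_dir / "intensity_unmeth.tsv"))
    beta = meth.preprocess_methylation(im, annot)
    write_tsv(beta.values, run_dir / "beta_filtered.tsv")
    write_tsv(beta.filter_report, run_dir / "filter_report.tsv", index=False)
    eprobes = read_tsv(run_dir / "expression_probes.tsv")
    em = preprocess_expression(eprobes)
    write_tsv(em.values, run_dir / "expression_genes.tsv")
    _log(run_dir, "preprocess",
         {"filter_report": beta.filter_report.to_dict("records"),
          "hashes": _hash_outputs(run_dir, ["beta_filtered.tsv",
                                            "expression_genes.tsv"])})


def stage_surrogates(cfg: PipelineConfig, run_dir: Path) -> None:
    seeds = child_seeds(cfg.seed, STAGES)
    samples = read_tsv(run_dir / "covariates.tsv")
    X, _ = models.build_design(samples)
    conf = samples[["chip", "row", "column", "ethnicity"]]
    for tag, fname in (("meth", "beta_filtered.tsv"),
                       ("expr", "expression_genes.tsv")):
        data = read_tsv(run_dir / fname)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sv = estimate_surrogates(data, X, conf, k_max=cfg.surrogate_k_max,
                                     q_threshold=cfg.surrogate_q,
                                     seed=seeds["surrogates"])
        write_tsv(pd.DataFrame(sv.selected, index=samples.index,
                               columns=[f"sv{i + 1}" for i in range(sv.n_selected)]),
                  run_dir / f"surrogates_{tag}.tsv")
        write_tsv(sv.report, run_dir / f"surrogate_report_{tag}.tsv", index=False)
        _log(run_dir, "surrogates", {"matrix": tag, "method": sv.method,
                                     "n_selected": sv.n_selected})


def _load_surrogates(run_dir: Path, tag: str):
    sv = read_tsv(run_dir / f"surrogates_{tag}.tsv")
    return sv.to_numpy(dtype=float) if sv.shape[1] else None


def _fit_with_covariate_fallback(runner, *args, **kwargs):
    """Drop covariates that are collinear at very small n (e.g. smoking
    coinciding with sex across a handful of pairs), logging implicitly via
    the association table's covariate list."""
    covs = list(models.DEFAULT_COVARIATES)
    while True:
        try:
            return runner(*args, covariates=tuple(covs), **kwargs)
        except models.RankDeficientDesignError as exc:
            droppable = [c for c in covs if c in exc.columns]
            if not droppable:
                raise
            for c in droppable:
                covs.remove(c)


def stage_ewas(cfg: PipelineConfig, run_dir: Path) -> None:
    samples = read_tsv(run_dir / "covariates.tsv")
    beta = read_tsv(run_dir / "beta_filtered.tsv")
    at = _fit_with_covariate_fallback(
        models.run_ewas, beta, samples, alpha=cfg.alpha_meth,
        surrogates=_load_surrogates(run_dir, "meth"))
    write_tsv(at.table, run_dir / "ewas.tsv")
    _log(run_dir, "ewas", {"n_significant": at.n_significant,
                           "alpha": cfg.alpha_meth,
                           "covariates": at.covariate_names,
                           "hashes": _hash_outputs(run_dir, ["ewas.tsv"])})


def stage_twas(cfg: PipelineConfig, run_dir: Path) -> None:
    samples = read_tsv(run_dir / "covariates.tsv")
    expr = read_tsv(run_dir / "expression_genes.tsv")
    _, gene_annot, _ = _load_annot(run_dir)
    at = _fit_with_covariate_fallback(
        models.run_twas, expr, samples, alpha=cfg.alpha_expr,
        surrogates=_load_surrogates(run_dir, "expr"),
        gene_annot=gene_annot, coding_only=True)
    write_tsv(at.table, run_dir / "twas.tsv")
    _log(run_dir, "twas", {"n_significant": at.n_significant,
                           "alpha": cfg.alpha_expr,
                           "hashes": _hash_outputs(run_dir, ["twas.tsv"])})


def stage_bumps(cfg: PipelineConfig, run_dir: Path) -> None:
    annot, _, _ = _load_annot(run_dir)
    ewas = read_tsv(run_dir / "ewas.tsv")
    res = bumps_mod.find_bumps(ewas, annot, max_gap=cfg.bump_max_gap,
                               quantile=cfg.bump_quantile,
                               min_probes=cfg.bump_min_probes)
    cand = bumps_mod.rank_candidates_for_validation(res, ewas, annot,
                                                    peak_alpha=cfg.alpha_meth)
    write_tsv(res.regions, run_dir / "bumps.tsv", index=False)
    write_tsv(res.singletons, run_dir / "bump_singletons.tsv", index=False)
    write_tsv(cand, run_dir / "candidates.tsv", index=False)
    write_tsv(bumps_mod.regions_to_bed(res.regions), run_dir / "bumps.bed",
              index=False)
    _log(run_dir, "bumps", {"threshold": res.threshold,
                            "n_regions": len(res.regions),
                            "n_candidates": int((~cand["excluded"]).sum())
                            if len(cand) else 0})


def stage_pyro(cfg: PipelineConfig, run_dir: Path) -> None:
    """Pyrosequencing validation of top candidate regions.

    Reads are drawn binomially from the processed array betas of the member
    probes (the array estimate is the best available per-sample methylation
    proportion), then the regional mixed model and an age effect-modification
    test are fit on the percent scale.
    """
    seeds = child_seeds(cfg.seed, STAGES)
    samples = read_tsv(run_dir / "covariates.tsv")
    beta = read_tsv(run_dir / "beta_filtered.tsv")
    cand = read_tsv(run_dir / "candidates.tsv", index_col=None)
    picked = cand[~cand["excluded"]].head(cfg.n_pyro_candidates) \
        if len(cand) else cand
    rows = []
    for r, (_, region) in enumerate(picked.iterrows()):
        ids = [p for p in str(region["probe_ids"]).split(",") if p in beta.index]
        if len(ids) < 2:
            continue
        C, T = synth.generate_pyro_counts(beta.loc[ids], cfg.pyro_depth,
                                          seed=seeds["pyro"] + r)
        long = regional.make_region_long(C, T, samples)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = regional.fit_region_model(long)
        row = dict(region=r, chrom=region["chrom"], start=region["start"],
                   end=region["end"], n_cpgs=fit.n_cpgs, coef=fit.coef,
                   ci_low=fit.ci_low, ci_high=fit.ci_high, p_value=fit.p_value,
                   method=fit.method)
        try:
            long = long.assign(age_hi=(long["age"] >
                                       samples["age"].median()).astype(int))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mr = regional.test_effect_modification(long, "age_hi")
            row["age_interaction_p"] = mr.interaction_p
        except ValueError:
            row["age_interaction_p"] = np.nan
        rows.append(row)
    write_tsv(pd.DataFrame(rows), run_dir / "pyro_regional.tsv", index=False)
    _log(run_dir, "pyro", {"n_regions": len(rows), "depth": cfg.pyro_depth})


def stage_network(cfg: PipelineConfig, run_dir: Path) -> None:
    seeds = child_seeds(cfg.seed, STAGES)
    annot, gene_annot, meta = _load_annot(run_dir)
    samples = read_tsv(run_dir / "covariates.tsv")
    beta = read_tsv(run_dir / "beta_filtered.tsv")
    expr = read_tsv(run_dir / "expression_genes.tsv")
    win = tuple(meta["block"])
    cpgs, genes = window.select_window_features(annot, gene_annot, win,
                                                flank=cfg.window_flank)
    cpgs = [c for c in cpgs if c in beta.index]
    genes = [g for g in genes if g in expr.index]
    beta_w = beta.loc[cpgs]
    expr_w = expr.loc[genes]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nets = window.build_networks(beta_w, expr_w, n_perm=cfg.n_perm,
                                     seed=seeds["network"])
    write_tsv(nets.meth_expr, run_dir / "network_meth_expr.tsv", index=False)
    write_tsv(nets.expr_expr, run_dir / "network_expr_expr.tsv", index=False)
    pos = annot.probes.loc[cpgs, "position"]
    collapsed, members = window.collapse_clusters(beta_w, pos)
    write_tsv(collapsed, run_dir / "window_clusters.tsv")
    write_tsv(members, run_dir / "window_cluster_members.tsv", index=False)
    prof = window.group_difference_profile(collapsed, expr_w, samples)
    write_tsv(prof, run_dir / "group_differences.tsv", index=False)
    _log(run_dir, "network", {"window": list(win), "n_cpgs": len(cpgs),
                              "n_genes": len(genes),
                              "n_meth_expr_edges": len(nets.meth_expr),
                              "n_expr_expr_edges": len(nets.expr_expr)})


def _load_universe(run_dir: Path) -> enrich.TermUniverse:
    dag = read_tsv(run_dir / "term_dag.tsv", index_col=None)
    t2g = read_tsv(run_dir / "term_genes.tsv", index_col=None)
    parents: dict[str, tuple] = {}
    for _, r in dag.iterrows():
        parents.setdefault(r["term"], ())
        parents.setdefault(r["parent"], ())
    for _, r in dag.iterrows():
        parents[r["term"]] = parents[r["term"]] + (r["parent"],)
    annotations: dict[str, set] = {}
    for _, r in t2g.iterrows():
        annotations.setdefault(r["term"], set()).add(r["gene"])
    return enrich.TermUniverse(parents=parents, annotations=annotations)


def stage_enrich(cfg: PipelineConfig, run_dir: Path) -> None:
    seeds = child_seeds(cfg.seed, STAGES)
    annot, _, _ = _load_annot(run_dir)
    universe = _load_universe(run_dir)
    beta = read_tsv(run_dir / "beta_filtered.tsv")
    ewas = read_tsv(run_dir / "ewas.tsv")
    twas = read_tsv(run_dir / "twas.tsv")
    try:
        terms = enrich.reduce_terms(universe, min_genes=cfg.enrich_min_genes,
                                    max_genes=cfg.enrich_max_genes,
                                    sim_cutoff=cfg.enrich_sim_cutoff)
    except ValueError:
        _log(run_dir, "enrich", {"skipped": "no terms in size window"})
        return
    sig_cpgs = set(ewas.index[ewas["p_value"] < cfg.alpha_meth])
    if sig_cpgs:
        res_m = enrich.methylation_enrichment(
            sig_cpgs, annot, universe, terms=terms,
            n_resamples=cfg.n_resamples, seed=seeds["enrich"],
            retained_probes=list(beta.index))
        write_tsv(res_m.table, run_dir / "enrichment_meth.tsv", index=False)
    sig_genes = set(twas.index[twas["p_value"] < cfg.alpha_expr])
    expr_universe = list(twas.index)
    res_e = enrich.expression_enrichment(sig_genes, expr_universe, universe,
                                         terms=terms)
    write_tsv(res_e.table, run_dir / "enrichment_expr.tsv", index=False)
    _log(run_dir, "enrich", {"n_terms_tested": len(terms),
                             "n_sig_cpgs": len(sig_cpgs),
                             "n_sig_genes": len(sig_genes)})


def recovery_report(run_dir: Path, cfg: PipelineConfig) -> pd.DataFrame:
    """Sensitivity / false-discovery metrics of every stage vs the truth ledger."""
    meta = json.loads((run_dir / "truth_meta.json").read_text())
    truth_cpgs = read_tsv(run_dir / "truth_cpgs.tsv", index_col=None)
    truth_regions = read_tsv(run_dir / "truth_regions.tsv", index_col=None)
    truth_genes = read_tsv(run_dir / "truth_genes.tsv", index_col=None)
    ewas = read_tsv(run_dir / "ewas.tsv")
    twas = read_tsv(run_dir / "twas.tsv")
    bumps_df = read_tsv(run_dir / "bumps.tsv", index_col=None)

    region_probe_ids = {p for v in meta["region_probes"].values() for p in v}
    true_cpgs = set(truth_cpgs["probe_id"]) | region_probe_ids
    sig_cpgs = set(ewas.index[ewas["p_value"] < cfg.alpha_meth])
    true_in_test = true_cpgs & set(ewas.index)
    rows = [dict(
        stage="ewas",
        n_true=len(true_in_test), n_called=len(sig_cpgs),
        sensitivity=(len(sig_cpgs & true_in_test) / len(true_in_test))
        if true_in_test else np.nan,
        fdr=(len(sig_cpgs - true_cpgs) / len(sig_cpgs)) if sig_cpgs else 0.0)]

    true_genes = set(truth_genes["gene_id"])
    sig_genes = set(twas.index[twas["p_value"] < cfg.alpha_expr])
    true_g_in = true_genes & set(twas.index)
    rows.append(dict(
        stage="twas", n_true=len(true_g_in), n_called=len(sig_genes),
        sensitivity=(len(sig_genes & true_g_in) / len(true_g_in))
        if true_g_in else np.nan,
        fdr=(len(sig_genes - true_genes) / len(sig_genes)) if sig_genes else 0.0))

    hit = 0
    for _, tr in truth_regions.iterrows():
        ov = bumps_df[(bumps_df["chrom"] == tr["chrom"])
                      & (bumps_df["start"] <= tr["end"])
                      & (bumps_df["end"] >= tr["start"])]
        hit += int(len(ov) > 0)
    rows.append(dict(stage="bumps", n_true=len(truth_regions),
                     n_called=len(bumps_df),
                     sensitivity=(hit / len(truth_regions))
                     if len(truth_regions) else np.nan,
                     fdr=np.nan))
    rep = pd.DataFrame(rows)
    write_tsv(rep, run_dir / "recovery.tsv", index=False)
    return rep


def stage_report(cfg: PipelineConfig, run_dir: Path) -> dict:
    rep = recovery_report(run_dir, cfg)
    outputs = sorted(p.name for p in run_dir.iterdir()
                     if p.suffix in (".tsv", ".bed", ".json")
                     and p.name != "summary.json")
    summary = {
        "config": asdict(cfg),
        "recovery": rep.to_dict("records"),
        "file_hashes": _hash_outputs(run_dir, outputs),
    }
    (run_dir / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, default=str, indent=1))
    _log(run_dir, "report", {"n_files": len(outputs)})
    return summary


_STAGE_FUNCS = {
    "simulate": stage_simulate, "preprocess": stage_preprocess,
    "surrogates": stage_surrogates, "ewas": stage_ewas, "twas": stage_twas,
    "bumps": stage_bumps, "pyro": stage_pyro, "network": stage_network,
    "enrich": stage_enrich, "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig, run_dir: str | Path) -> dict:
    """Run every stage in order; halt on stage failure with partial outputs kept."""
    cfg.validate()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    log_path = run_dir / "run_log.jsonl"
    if log_path.exists():
        log_path.unlink()
    cfg.to_yaml(run_dir / "config.yaml")
    t0 = time.time()
    summary = None
    for stage in STAGES:
        try:
            out = _STAGE_FUNCS[stage](cfg, run_dir)
            if stage == "report":
                summary = out
        except Exception as exc:
            _log(run_dir, stage, {"error": repr(exc)})
            raise RuntimeError(f"pipeline halted at stage {stage!r}: {exc}") from exc
    summary["elapsed_seconds"] = round(time.time() - t0, 2)
    return summary
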