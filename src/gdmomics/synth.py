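"""Synthetic study generator for an integrated placental methylome/transcriptome analysis.

Emulates a matched case-control study of gestational diabetes (GDM): paired
covariates, 450K-like two-channel methylation intensities with probe-type and
batch artifacts, transcriptome-array probe intensities summarizable by median
polish, a rooted gene-ontology-like term DAG with heterogeneous probe counts
per gene, and binomial pyrosequencing read counts.  Every injected effect is
recorded in a :class:`GroundTruth` ledger so downstream stages can be scored
for sensitivity, bias and false-discovery rate against a known answer.

The generator is fully deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd


class InvalidDesignError(ValueError):
    """Raised when a requested cohort design cannot support the models."""


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

ETHNICITIES = ("white", "black", "asian")


@dataclass
class CohortDesign:
    """A matched case-control cohort.

    ``samples`` has one row per placenta sample with columns
    ``pair_id, gdm, age, bmi, sex, smoking, ethnicity, chip, row, column``.
    Exactly one case (gdm=1) and one control (gdm=0) per pair; sex, smoking
    and ethnicity are identical within pair and maternal age differs by at
    most 5 years, mirroring individual matching.
    """

    samples: pd.DataFrame
    n_pairs: int

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    def validate(self) -> None:
        g = self.samples.groupby("pair_id")
        if not (g["gdm"].sum() == 1).all() or not (g.size() == 2).all():
            raise InvalidDesignError("each pair must contain one case and one control")
        for col in ("sex", "smoking", "ethnicity"):
            if (g[col].nunique() != 1).any():
                raise InvalidDesignError(f"matched covariate {col!r} differs within a pair")
        if (g["age"].max() - g["age"].min() > 5 + 1e-9).any():
            raise InvalidDesignError("age difference within a pair exceeds 5 years")


def generate_cohort(
    n_pairs: int,
    seed: int,
    ethnicity_chip_mix: float = 0.5,
    chip_size: int = 12,
) -> CohortDesign:
    """Generate ``n_pairs`` matched case-control pairs with batch labels.

    Chips hold ``chip_size`` samples arranged as 6 rows x 2 columns (the
    layout of the 450K BeadChip).  ``ethnicity_chip_mix`` in [0,1] controls
    how strongly chip assignment tracks ethnicity (0 = random plating,
    1 = fully sorted), so that surrogate-variable adjustment has a real,
    identifiable confounding structure to find.
    """
    if n_pairs < 3:
        raise InvalidDesignError(
            f"n_pairs={n_pairs} < 3: downstream models are unidentifiable"
        )
    if not 0.0 <= ethnicity_chip_mix <= 1.0:
        raise ValueError("ethnicity_chip_mix must be in [0, 1]")
    rng = np.random.default_rng(seed)

    rows = []
    for p in range(n_pairs):
        age_case = float(np.clip(rng.normal(32.0, 4.5), 18.0, 45.0))
        age_ctrl = float(np.clip(age_case + rng.uniform(-2.5, 2.5), 18.0, 45.0))
        bmi_case = float(np.clip(rng.normal(26.0, 5.0), 17.0, 45.0))
        bmi_ctrl = float(np.clip(bmi_case + rng.normal(0.0, 1.5), 17.0, 45.0))
        sex = int(rng.integers(0, 2))
        smoking = int(rng.random() < 0.15)
        ethnicity = str(rng.choice(ETHNICITIES, p=[0.6, 0.25, 0.15]))
        for gdm, age, bmi in ((1, age_case, bmi_case), (0, age_ctrl, bmi_ctrl)):
            rows.append(
                dict(pair_id=f"P{p:03d}", gdm=gdm, age=round(age, 1),
                     bmi=round(bmi, 1), sex=sex, smoking=smoking,
                     ethnicity=ethnicity)
            )
    df = pd.DataFrame(rows)
    df.index = pd.Index([f"S{i:03d}" for i in range(len(df))], name="sample_id")

    # plate samples onto chips; sort key blends ethnicity with noise so the
    # ethnicity-chip correlation is tunable but never degenerate
    eth_code = df["ethnicity"].map({e: i for i, e in enumerate(ETHNICITIES)}).to_numpy()
    key = ethnicity_chip_mix * (eth_code / max(len(ETHNICITIES) - 1, 1)) + (
        1.0 - ethnicity_chip_mix
    ) * rng.random(len(df)) + 1e-6 * rng.random(len(df))
    order = np.argsort(key, kind="stable")
    chip = np.empty(len(df), dtype=int)
    pos = np.empty(len(df), dtype=int)
    chip[order] = np.arange(len(df)) // chip_size
    pos[order] = np.arange(len(df)) % chip_size
    df["chip"] = [f"chip{c:02d}" for c in chip]
    df["row"] = [f"r{p % 6}" for p in pos]
    df["column"] = [f"c{p // 6}" for p in pos]

    design = CohortDesign(samples=df, n_pairs=n_pairs)
    design.validate()
    return design


# ---------------------------------------------------------------------------
# genome layout: genes and probes
# ---------------------------------------------------------------------------

#: default chromosome lengths (bp).  Five autosome analogs plus X and Y so the
#: autosomal-probe filter has something to remove.
DEFAULT_CHROMS = {
    "chr1": 30_000_000, "chr2": 30_000_000, "chr3": 30_000_000,
    "chr4": 30_000_000, "chr5": 30_000_000, "chrX": 20_000_000,
    "chrY": 5_000_000,
}

#: coordinated-regulation window analog (an MHC-like 5 Mb block on chr5)
DEFAULT_BLOCK = ("chr5", 10_000_000, 15_000_000)


@dataclass
class GeneAnnotation:
    """Gene coordinates: gene_id -> chrom, start, end, tss, coding flag."""

    genes: pd.DataFrame
    block: tuple[str, int, int] = DEFAULT_BLOCK

    @property
    def block_genes(self) -> list[str]:
        c, s, e = self.block
        g = self.genes
        m = (g["chrom"] == c) & (g["tss"] >= s) & (g["tss"] <= e)
        return list(g.index[m])


@dataclass
class ProbeAnnotation:
    """450K-like probe annotation.

    One row per probe: ``chrom, position`` (1-based), ``probe_type`` ("I" or
    "II"), ``snp_at_target`` and ``cross_hyb_x`` exclusion flags,
    ``nearest_gene_id`` and ``distance_to_gene`` (bp, 0 when inside the gene
    body).  Positions are strictly increasing within chromosome.
    """

    probes: pd.DataFrame
    block: tuple[str, int, int] = DEFAULT_BLOCK

    def validate(self) -> None:
        for _, sub in self.probes.groupby("chrom"):
            if not sub["position"].is_monotonic_increasing:
                raise ValueError("probe positions must be sorted within chromosome")
            if sub["position"].duplicated().any():
                raise ValueError("duplicate probe positions on a chromosome")

    def to_bed(self) -> pd.DataFrame:
        """0-based half-open BED view of the (1-based internal) positions."""
        p = self.probes
        return pd.DataFrame(
            {"chrom": p["chrom"], "start": p["position"] - 1,
             "end": p["position"], "name": p.index}
        ).reset_index(drop=True)


def generate_gene_annotation(
    n_genes: int = 300,
    seed: int = 0,
    chroms: dict[str, int] | None = None,
    block: tuple[str, int, int] = DEFAULT_BLOCK,
    n_block_genes: int = 15,
    coding_fraction: float = 0.85,
) -> GeneAnnotation:
    """Scatter genes over the genome, forcing ``n_block_genes`` into the block."""
    chroms = dict(chroms or DEFAULT_CHROMS)
    rng = np.random.default_rng(seed)
    autosomes = [c for c in chroms if c not in ("chrX", "chrY")]
    recs = []
    bc, bs, be = block
    for i in range(n_genes):
        if i < n_block_genes:
            chrom = bc
            start = int(rng.integers(bs, be - 100_000))
        else:
            chrom = str(rng.choice(autosomes + ["chrX"], p=[0.18] * 5 + [0.1]))
            start = int(rng.integers(50_000, chroms[chrom] - 100_000))
        length = int(rng.integers(5_000, 60_000))
        recs.append(dict(chrom=chrom, start=start, end=start + length, tss=start,
                         coding=bool(rng.random() < coding_fraction)))
    df = pd.DataFrame(recs, index=pd.Index([f"G{i:04d}" for i in range(n_genes)],
                                           name="gene_id"))
    return GeneAnnotation(genes=df, block=block)


def generate_probe_annotation(
    gene_annot: GeneAnnotation,
    n_probes: int = 3000,
    seed: int = 0,
    chroms: dict[str, int] | None = None,
    island_prob: float = 0.35,
    snp_rate: float = 0.02,
    cross_hyb_rate: float = 0.015,
    type2_fraction: float = 0.7,
) -> ProbeAnnotation:
    """Place CpG probes by a background Poisson process plus promoter "island" bursts.

    A fraction of genes receive a dense burst of probes near the TSS
    (inter-probe gaps of 50-300 bp), producing both the run structure that
    bump hunting needs and the strong probe-count-per-gene imbalance that the
    resampling enrichment null corrects for.  Flags are assigned
    independently of any effect injection.
    """
    chroms = dict(chroms or DEFAULT_CHROMS)
    rng = np.random.default_rng(seed)
    positions: dict[str, list[int]] = {c: [] for c in chroms}

    genes = gene_annot.genes
    # island bursts near a subset of TSSs
    n_island_probes = 0
    for gid, g in genes.iterrows():
        if rng.random() < island_prob:
            k = int(rng.integers(3, 13))
            pos = int(g["tss"]) - int(rng.integers(0, 500))
            for _ in range(k):
                if 1 <= pos < chroms[g["chrom"]]:
                    positions[g["chrom"]].append(pos)
                pos += int(rng.integers(50, 301))
            n_island_probes += k
    # background probes fill the remainder, uniform over the genome
    n_bg = max(n_probes - n_island_probes, 0)
    tot = sum(chroms.values())
    for c, ln in chroms.items():
        k = int(round(n_bg * ln / tot))
        positions[c].extend(int(p) for p in rng.integers(1, ln, size=k))

    recs = []
    from .enrich import closest_genes  # shared nearest-gene logic

    for c in chroms:
        pos = np.array(sorted(set(positions[c])), dtype=int)
        if pos.size == 0:
            continue
        gid, dist = closest_genes(c, pos, gene_annot)
        for p, g, d in zip(pos, gid, dist):
            recs.append(dict(chrom=c, position=int(p), nearest_gene_id=g,
                             distance_to_gene=int(d) if g is not None else -1))
    df = pd.DataFrame(recs)
    df = df.sort_values(["chrom", "position"], kind="stable").reset_index(drop=True)
    df.index = pd.Index([f"cg{i:07d}" for i in range(len(df))], name="probe_id")
    df["probe_type"] = np.where(rng.random(len(df)) < type2_fraction, "II", "I")
    df["snp_at_target"] = rng.random(len(df)) < snp_rate
    df["cross_hyb_x"] = rng.random(len(df)) < cross_hyb_rate
    annot = ProbeAnnotation(probes=df, block=gene_annot.block)
    annot.validate()
    return annot


# ---------------------------------------------------------------------------
# ground truth ledger
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Ledger of every injected effect; the reference for recovery scoring."""

    affected_cpgs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["probe_id", "effect"]))
    affected_regions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start", "end", "n_probes", "effect"]))
    region_probes: dict[int, list[str]] = field(default_factory=dict)
    affected_genes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "effect"]))
    block_span: tuple[str, int, int] | None = None
    block_genes: list[str] = field(default_factory=list)
    enriched_terms: list[str] = field(default_factory=list)
    clip_warnings: int = 0
    batch_shift: pd.Series | None = None  # injected per-sample batch score

    @property
    def affected_cpg_ids(self) -> set[str]:
        ids = set(self.affected_cpgs["probe_id"])
        for probes in self.region_probes.values():
            ids.update(probes)
        return ids


# ---------------------------------------------------------------------------
# methylation intensities
# ---------------------------------------------------------------------------

@dataclass
class IntensityMatrix:
    """Paired methylated/unmethylated channel intensities, probe x sample."""

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame

    def validate(self) -> None:
        if (self.methylated.values < 0).any() or (self.unmethylated.values < 0).any():
            raise ValueError("negative intensities")
        if not self.methylated.index.equals(self.unmethylated.index):
            raise ValueError("channel probe indices differ")


@dataclass
class MethylationEffects:
    """Configuration of injected methylation signal and technical artifacts.

    Effects are on the beta (methylation-fraction) scale.  ``noise_sd`` is the
    SD of log-normal multiplicative noise applied to each channel, which
    yields beta-scale noise of roughly ``noise_sd * beta * (1 - beta) * sqrt(2)``
    -- heteroscedastic and largest at intermediate methylation, the pattern
    robust standard errors exist to absorb.
    """

    n_affected_sites: int = 20
    site_effect: float = 0.10
    n_regions: int = 2
    region_n_probes: int = 5
    region_effect: float = 0.08
    n_block_sites: int = 10
    block_site_effect: float = -0.06
    batch_sd: float = 0.0          # chip-level logit-scale shift SD
    noise_sd: float = 0.15
    type2_compression: float = 0.8  # type II betas shrunk toward 0.5 by this factor
    total_intensity: float = 3000.0


def _baseline_betas(rng: np.random.Generator, n: int) -> np.ndarray:
    """Bimodal per-probe mean methylation typical of CpG arrays."""
    comp = rng.choice(3, size=n, p=[0.45, 0.45, 0.10])
    out = np.empty(n)
    out[comp == 0] = rng.beta(2.0, 10.0, size=(comp == 0).sum())
    out[comp == 1] = rng.beta(10.0, 2.0, size=(comp == 1).sum())
    out[comp == 2] = rng.beta(6.0, 6.0, size=(comp == 2).sum())
    return np.clip(out, 0.02, 0.98)


def _eligible_region_runs(annot: ProbeAnnotation, n_probes: int,
                          max_gap: int = 400) -> list[list[str]]:
    """Maximal autosomal runs of >= n_probes consecutive probes with gaps <= max_gap."""
    runs = []
    p = annot.probes
    for c, sub in p[~p["chrom"].isin(["chrX", "chrY"])].groupby("chrom"):
        ids = list(sub.index)
        pos = sub["position"].to_numpy()
        start = 0
        for i in range(1, len(ids) + 1):
            if i == len(ids) or pos[i] - pos[i - 1] > max_gap:
                if i - start >= n_probes:
                    runs.append(ids[start:i])
                start = i
    return runs


def generate_methylation(
    design: CohortDesign,
    annot: ProbeAnnotation,
    effect_cfg: MethylationEffects | None = None,
    seed: int = 0,
) -> tuple[IntensityMatrix, GroundTruth]:
    """Simulate two-channel intensities with injected site, region and block effects.

    True betas are built per probe x sample (baseline + GDM effects in cases,
    clipped to (0,1) with clips counted in the truth ledger), compressed
    toward 0.5 for type II probes, then converted to intensities
    ``M = beta * total * exp(s/2 + eM)``, ``U = (1-beta) * total * exp(-s/2 + eU)``
    where ``s`` is a chip/row/column batch shift (applied antisymmetrically so
    it moves the beta value, as position effects do on real arrays) and
    ``eM, eU`` are independent log-normal noises.
    """
    cfg = effect_cfg or MethylationEffects()
    rng = np.random.default_rng(seed)
    probes = annot.probes
    n_p, n_s = len(probes), len(design.samples)
    truth = GroundTruth(block_span=annot.block)

    base = _baseline_betas(rng, n_p)
    gdm = design.samples["gdm"].to_numpy()

    effect = np.zeros(n_p)
    pid_index = pd.Index(probes.index)

    # region effects first: claim runs of nearby probes
    runs = _eligible_region_runs(annot, cfg.region_n_probes)
    rng.shuffle(runs)
    claimed: set[str] = set()
    region_rows = []
    for r, run in enumerate(runs[: cfg.n_regions]):
        members = run[: cfg.region_n_probes]
        locs = pid_index.get_indexer(members)
        effect[locs] += cfg.region_effect
        # keep region baselines interior so the injected shift survives clipping
        base[locs] = np.clip(base[locs], 0.2, 0.7)
        claimed.update(members)
        sub = probes.loc[members]
        region_rows.append(dict(chrom=sub["chrom"].iloc[0],
                                start=int(sub["position"].min()),
                                end=int(sub["position"].max()),
                                n_probes=len(members), effect=cfg.region_effect))
        truth.region_probes[r] = list(members)
    truth.affected_regions = pd.DataFrame(
        region_rows, columns=["chrom", "start", "end", "n_probes", "effect"])

    # scattered single-site effects on clean autosomal probes
    eligible = probes.index[
        (~probes["chrom"].isin(["chrX", "chrY"]))
        & ~probes["snp_at_target"] & ~probes["cross_hyb_x"]
        & (base > 0.15) & (base < 0.75) & ~probes.index.isin(claimed)
    ]
    n_sites = min(cfg.n_affected_sites, len(eligible))
    sites = rng.choice(eligible, size=n_sites, replace=False) if n_sites else []
    locs = pid_index.get_indexer(sites)
    effect[locs] += cfg.site_effect
    truth.affected_cpgs = pd.DataFrame(
        {"probe_id": list(sites), "effect": cfg.site_effect})

    # scattered sites inside the coordinated block
    bc, bs, be = annot.block
    in_block = probes.index[(probes["chrom"] == bc)
                            & probes["position"].between(bs, be)
                            & ~probes.index.isin(claimed) & ~probes.index.isin(sites)]
    n_blk = min(cfg.n_block_sites, len(in_block))
    if n_blk:
        blk = rng.choice(in_block, size=n_blk, replace=False)
        effect[pid_index.get_indexer(blk)] += cfg.block_site_effect
        truth.affected_cpgs = pd.concat(
            [truth.affected_cpgs,
             pd.DataFrame({"probe_id": list(blk), "effect": cfg.block_site_effect})],
            ignore_index=True)

    true_beta = base[:, None] + effect[:, None] * gdm[None, :]
    n_clip = int(((true_beta < 1e-3) | (true_beta > 1 - 1e-3)).sum())
    if n_clip:
        warnings.warn(f"{n_clip} true beta values clipped into (0,1)", stacklevel=2)
        truth.clip_warnings = n_clip
    true_beta = np.clip(true_beta, 1e-3, 1 - 1e-3)

    is2 = (probes["probe_type"] == "II").to_numpy()
    apparent = true_beta.copy()
    apparent[is2] = 0.5 + (apparent[is2] - 0.5) * cfg.type2_compression

    # batch shifts per chip/row/column, modulated by a per-probe loading so
    # the artifact is probe-specific (a purely global per-sample shift would
    # be removed entirely by quantile normalization; real position effects
    # are not, which is why surrogate adjustment exists)
    shift = np.zeros(n_s)
    loading = np.zeros(n_p)
    if cfg.batch_sd > 0:
        for col, sd in (("chip", cfg.batch_sd), ("row", cfg.batch_sd / 2),
                        ("column", cfg.batch_sd / 2)):
            levels = design.samples[col].unique()
            eff = dict(zip(levels, rng.normal(0.0, sd, size=len(levels))))
            shift += design.samples[col].map(eff).to_numpy()
        loading = rng.normal(0.0, 1.0, size=n_p)
    truth.batch_shift = pd.Series(shift, index=design.sample_ids, name="batch_shift")
    S = loading[:, None] * shift[None, :]

    total = rng.lognormal(np.log(cfg.total_intensity), 0.3, size=n_p)[:, None]
    e_m = rng.normal(0.0, cfg.noise_sd, size=(n_p, n_s))
    e_u = rng.normal(0.0, cfg.noise_sd, size=(n_p, n_s))
    M = apparent * total * np.exp(S / 2 + e_m)
    U = (1.0 - apparent) * total * np.exp(-S / 2 + e_u)

    cols = design.sample_ids
    im = IntensityMatrix(
        methylated=pd.DataFrame(M, index=probes.index, columns=cols),
        unmethylated=pd.DataFrame(U, index=probes.index, columns=cols))
    im.validate()
    return im, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionEffects:
    """Injected expression signal.  Effects are log2-scale shifts in cases."""

    n_affected_genes: int = 50
    gene_effect: float = -0.5
    block_effect: float = -0.3
    block_latent_sd: float = 0.35  # shared co-regulation factor in the block
    probes_per_gene_mean: float = 21.0
    affinity_sd: float = 0.5
    noise_sd: float = 0.25
    biological_sd: float = 0.4
    batch_sd: float = 0.0
    background: float = 30.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5


def generate_expression(
    design: CohortDesign,
    gene_annot: GeneAnnotation,
    effect_cfg: ExpressionEffects | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate probe-level transcriptome-array intensities (linear scale).

    Probe signal is additive on the log2 scale -- gene level + probe affinity
    + batch + noise -- so median polish can recover the per-sample gene value;
    an additive linear-scale background is layered on top for the background
    correction step to remove.  Genes inside the coordinated block share a
    common ``block_effect`` down-shift in cases.

    Returns a long-ish wide table (rows = probes, columns = ``gene_id`` plus
    one column per sample) and the truth ledger.
    """
    cfg = effect_cfg or ExpressionEffects()
    rng = np.random.default_rng(seed)
    genes = gene_annot.genes
    gdm = design.samples["gdm"].to_numpy()
    n_s = len(design.samples)
    truth = GroundTruth(block_span=gene_annot.block,
                        block_genes=gene_annot.block_genes)

    block = set(gene_annot.block_genes)
    non_block = [g for g in genes.index if g not in block]
    n_aff = min(cfg.n_affected_genes, len(non_block))
    affected = list(rng.choice(non_block, size=n_aff, replace=False)) if n_aff else []
    eff = pd.Series(0.0, index=genes.index)
    eff[affected] = cfg.gene_effect
    eff[list(block)] += cfg.block_effect
    truth.affected_genes = pd.DataFrame(
        {"gene_id": affected + list(block),
         "effect": [cfg.gene_effect] * len(affected) + [cfg.block_effect] * len(block)})

    # chip effect with per-gene loading (a uniform shift would be undone by
    # quantile normalization; gene-specific batch response is what persists)
    if cfg.batch_sd > 0:
        chip_eff = {c: rng.normal(0.0, cfg.batch_sd)
                    for c in design.samples["chip"].unique()}
        batch = design.samples["chip"].map(chip_eff).to_numpy()
        gene_loading = rng.normal(0.0, 1.0, size=len(genes))
    else:
        batch = np.zeros(n_s)
        gene_loading = np.zeros(len(genes))
    truth.batch_shift = pd.Series(batch, index=design.sample_ids,
                                  name="batch_shift")

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(genes))
    # block genes share a latent per-sample factor: the co-regulation the
    # window correlation analysis is built to detect
    latent = rng.normal(0.0, cfg.block_latent_sd, size=n_s) \
        if cfg.block_latent_sd > 0 else np.zeros(n_s)
    recs, probe_gene = [], []
    for gi, gid in enumerate(genes.index):
        k = 1 + rng.poisson(max(cfg.probes_per_gene_mean - 1.0, 0.0))
        sig = (baseline[gi] + eff[gid] * gdm + gene_loading[gi] * batch
               + (latent if gid in block else 0.0)
               + rng.normal(0.0, cfg.biological_sd, size=n_s))
        aff = rng.normal(0.0, cfg.affinity_sd, size=k)
        noise = rng.normal(0.0, cfg.noise_sd, size=(k, n_s))
        log2 = sig[None, :] + aff[:, None] + noise
        recs.append(np.power(2.0, log2) + cfg.background)
        probe_gene.extend([gid] * k)
    mat = np.vstack(recs)
    df = pd.DataFrame(mat, columns=design.sample_ids)
    df.insert(0, "gene_id", probe_gene)
    df.index = pd.Index([f"ep{i:06d}" for i in range(len(df))], name="probe_id")
    return df, truth


# ---------------------------------------------------------------------------
# term universe
# ---------------------------------------------------------------------------

@dataclass
class TermUniverseBundle:
    """A generated ontology plus the planted structures tests rely on."""

    universe: "object"                      # gdmomics.enrich.TermUniverse
    probe_counts: pd.Series                 # probes per gene on the array analog
    duplicate_clusters: list[list[str]]     # planted near-duplicate term groups
    dense_term: str | None                  # term whose genes carry 10x probes


def generate_term_universe(
    n_genes: int = 2000,
    n_terms: int = 60,
    seed: int = 0,
    gene_ids: list[str] | None = None,
    n_duplicate_clusters: int = 3,
    plant_dense_term: bool = True,
) -> TermUniverseBundle:
    """Build a rooted is_a DAG with propagated gene annotations.

    Term sizes span below, inside and above the 20-1500 gene window used by
    the enrichment stage (the root annotates every gene).  ``n_duplicate_clusters``
    groups of near-identical terms (>= 90 % gene overlap) are planted to
    exercise semantic-similarity redundancy reduction, and one mid-sized term
    is optionally given ~10x probe density to make the array-design bias that
    the resampling null corrects for measurable.
    """
    from .enrich import TermUniverse

    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    n_genes = len(gene_ids)

    root = "T:0000"
    parents: dict[str, tuple[str, ...]] = {root: ()}
    level1 = [f"T:{i:04d}" for i in range(1, 6)]
    for t in level1:
        parents[t] = (root,)
    others = []
    i = 6
    while len(parents) < max(n_terms - 2 * n_duplicate_clusters, 8):
        t = f"T:{i:04d}"
        pool = level1 + others
        k = 1 if rng.random() < 0.8 else 2
        parents[t] = tuple(rng.choice(pool, size=min(k, len(pool)), replace=False))
        others.append(t)
        i += 1

    # direct annotations: each gene lands in 1-3 non-root terms, with
    # log-normal term popularity so sizes are heavy-tailed (tiny to huge)
    annot: dict[str, set[str]] = {t: set() for t in parents}
    terms = [t for t in parents if t != root]
    pop = rng.lognormal(0.0, 1.2, size=len(terms))
    pop /= pop.sum()
    for g in gene_ids:
        for t in rng.choice(terms, size=int(rng.integers(1, 4)), replace=False,
                            p=pop):
            annot[t].add(g)
    # a few explicit tiny leaf terms guarantee sizes below the 20-gene floor
    for _ in range(3):
        tid = f"T:{i:04d}"
        i += 1
        parents[tid] = (str(rng.choice(level1)),)
        annot[tid] = set(rng.choice(gene_ids, size=int(rng.integers(5, 16)),
                                    replace=False))
        terms.append(tid)
    # the root directly annotates every gene (=> IC 0 and size above any cap)
    annot[root] = set(gene_ids)

    # planted near-duplicate clusters: each is a leaf term plus two children
    # holding ~95 % of its genes.  As children, the copies share the original
    # as most-informative common ancestor, so Jiang-Conrath similarity within
    # the cluster is near 1 while leaf terms sitting under broad (low-IC)
    # parents stay well separated from everything else.
    provisional = TermUniverse(parents=parents, annotations=annot)
    dup_clusters = []
    used_as_parent = {p for ps in parents.values() for p in ps}
    candidates = [
        t for t in others
        if t not in used_as_parent and len(annot[t]) >= 20
        # isolation margin: similarity to the nearest DAG relative < 0.7
        and min(provisional.ic[t] - provisional.ic[p] for p in parents[t]) > 0.6
    ]
    rng.shuffle(candidates)
    for t in candidates[:n_duplicate_clusters]:
        genes_t = sorted(annot[t])
        cluster = [t]
        for _ in range(2):
            tid = f"T:{i:04d}"
            i += 1
            parents[tid] = (t,)
            n_keep = max(1, int(np.ceil(0.95 * len(genes_t))))
            keep = rng.choice(len(genes_t), size=n_keep, replace=False)
            annot[tid] = {genes_t[k] for k in keep}
            cluster.append(tid)
        dup_clusters.append(cluster)

    universe = TermUniverse(parents=parents, annotations=annot)

    probe_counts = pd.Series(rng.integers(1, 8, size=n_genes), index=gene_ids,
                             name="n_probes")
    dense = None
    if plant_dense_term:
        mids = [t for t in terms
                if 20 <= len(universe.genes(t)) <= max(40, n_genes // 10)]
        if mids:
            dense = str(rng.choice(mids))
            dense_genes = list(universe.genes(dense))
            probe_counts.loc[dense_genes] = probe_counts.loc[dense_genes] * 10
    return TermUniverseBundle(universe=universe, probe_counts=probe_counts,
                              duplicate_clusters=dup_clusters, dense_term=dense)


# ---------------------------------------------------------------------------
# pyrosequencing
# ---------------------------------------------------------------------------

def generate_pyro_counts(
    beta_truth: pd.DataFrame, depth: int, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binomial bisulfite-read counts: C ~ Binomial(depth, true beta) per CpG x sample.

    Returns (C, T) count DataFrames shaped like ``beta_truth``.
    """
    if depth < 10:
        raise ValueError(f"depth={depth} < 10: below usable pyrosequencing coverage")
    rng = np.random.default_rng(seed)
    b = np.asarray(beta_truth, dtype=float)
    if (b < 0).any() or (b > 1).any():
        raise ValueError("true beta outside [0, 1]")
    C = rng.binomial(depth, b)
    return (pd.DataFrame(C, index=beta_truth.index, columns=beta_truth.columns),
            pd.DataFrame(depth - C, index=beta_truth.index, columns=beta_truth.columns))
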