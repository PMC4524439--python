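"""Bump hunting: differentially methylated regions as runs of extreme probes.

A probe is a candidate when the absolute adjusted-model T statistic meets or
exceeds the chosen genome-wide quantile (default the 99th percentile over all
retained probes).  A region is a maximal run of candidate probes on one
chromosome in which consecutive members are at most ``max_gap`` (default
500 bp) apart.  In the default strict reading of "contiguous", a retained
sub-threshold probe lying between two candidates breaks the run; a permissive
mode chains candidates across intervening probes.  Runs are split where the
effect changes sign (a region is directionally coherent) and summarized by
the mean per-probe effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class BumpResult:
    """Regions (n_probes >= min_probes), singleton site-level hits, threshold."""

    regions: pd.DataFrame
    singletons: pd.DataFrame
    threshold: float
    params: dict = field(default_factory=dict)


_REGION_COLS = ["chrom", "start", "end", "n_probes", "summary_effect",
                "max_abs_t", "probe_ids"]


def _runs_from_flags(pos: np.ndarray, cand: np.ndarray, max_gap: int,
                     strict: bool) -> list[list[int]]:
    """Index runs of candidate probes under the gap/contiguity rule."""
    runs, cur = [], []
    for i in range(len(pos)):
        if not cand[i]:
            if strict and cur:
                runs.append(cur)
                cur = []
            continue
        if cur and pos[i] - pos[cur[-1]] <= max_gap:
            cur.append(i)
        else:
            if cur:
                runs.append(cur)
            cur = [i]
    if cur:
        runs.append(cur)
    return runs


def _split_on_sign(run: list[int], effect: np.ndarray) -> list[list[int]]:
    out, cur = [], [run[0]]
    for i in run[1:]:
        if np.sign(effect[i]) == np.sign(effect[cur[-1]]):
            cur.append(i)
        else:
            out.append(cur)
            cur = [i]
    out.append(cur)
    return out


def find_bumps(assoc, annot, max_gap: int = 500, quantile: float = 0.99,
               min_probes: int = 2, strict: bool = True,
               split_sign: bool = True, summary: str = "mean") -> BumpResult:
    """Detect DMRs among contiguous extreme probes.

    ``assoc`` is an AssociationTable (or its table) indexed by probe id;
    ``annot`` the matching ProbeAnnotation.  Probes must be sorted by
    (chromosome, position).  Regions are returned sorted and disjoint,
    ranked by \\|summary_effect\\|; runs shorter than ``min_probes`` are
    reported separately as site-level singletons.
    """
    table = getattr(assoc, "table", assoc)
    probes = annot.probes.loc[annot.probes.index.intersection(table.index)]
    if len(probes) != len(table):
        raise ValueError("association table and annotation are not aligned")
    merged = table.join(probes[["chrom", "position"]])
    for _, sub in merged.groupby("chrom"):
        if not sub["position"].is_monotonic_increasing:
            raise ValueError("probes must be sorted by (chromosome, position)")

    abs_t = merged["t_stat"].abs().to_numpy()
    threshold = float(np.quantile(abs_t, quantile))
    region_rows, singleton_rows = [], []
    for chrom, sub in merged.groupby("chrom", sort=True):
        pos = sub["position"].to_numpy()
        eff = sub["effect"].to_numpy()
        tt = sub["t_stat"].abs().to_numpy()
        cand = tt >= threshold
        ids = sub.index.to_numpy()
        for run in _runs_from_flags(pos, cand, max_gap, strict):
            pieces = _split_on_sign(run, eff) if split_sign else [run]
            for piece in pieces:
                se = float(eff[piece].mean()) if summary == "mean" \
                    else float(eff[piece].sum())
                row = dict(chrom=chrom, start=int(pos[piece[0]]),
                           end=int(pos[piece[-1]]), n_probes=len(piece),
                           summary_effect=se, max_abs_t=float(tt[piece].max()),
                           probe_ids=",".join(ids[piece]))
                (region_rows if len(piece) >= min_probes else singleton_rows).append(row)

    regions = pd.DataFrame(region_rows, columns=_REGION_COLS)
    singletons = pd.DataFrame(singleton_rows, columns=_REGION_COLS)
    regions = regions.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return BumpResult(regions=regions, singletons=singletons, threshold=threshold,
                      params=dict(max_gap=max_gap, quantile=quantile,
                                  min_probes=min_probes, strict=strict,
                                  split_sign=split_sign, summary=summary))


_BED_COLS = ["chrom", "start", "end", "name", "score", "strand",
             "summary_effect", "n_probes"]


def regions_to_bed(regions: pd.DataFrame) -> pd.DataFrame:
    """BED6+ export: 0-based half-open intervals covering member probes."""
    if regions.empty:
        return pd.DataFrame(columns=_BED_COLS)
    return pd.DataFrame({
        "chrom": regions["chrom"],
        "start": regions["start"] - 1,
        "end": regions["end"],
        "name": [f"dmr{i}" for i in range(len(regions))],
        "score": regions["max_abs_t"].round(3),
        "strand": ".",
        "summary_effect": regions["summary_effect"],
        "n_probes": regions["n_probes"],
    })


def rank_candidates_for_validation(result: BumpResult, assoc, annot,
                                   peak_alpha: float = 0.001) -> pd.DataFrame:
    """Select and rank regions for pyrosequencing validation.

    The peak probe (largest \\|t\\|) of each region must be free of SNP and
    cross-hybridization flags (such probes make primer design unreliable)
    and significant at ``peak_alpha``; surviving regions are ranked by
    \\|summary_effect\\| descending.  Excluded regions are returned too,
    flagged, so the selection is auditable.
    """
    table = getattr(assoc, "table", assoc)
    flags = annot.probes[["snp_at_target", "cross_hyb_x"]]
    rows = []
    for _, r in result.regions.iterrows():
        ids = r["probe_ids"].split(",")
        sub = table.loc[ids]
        peak = sub["t_stat"].abs().idxmax()
        flagged = bool(flags.loc[peak].any())
        peak_p = float(sub.loc[peak, "p_value"])
        rows.append(dict(**r, peak_probe=peak, peak_p=peak_p,
                         excluded=flagged or peak_p >= peak_alpha,
                         exclusion_reason=("flagged_peak" if flagged else
                                           ("peak_p" if peak_p >= peak_alpha else ""))))
    if not rows:
        return pd.DataFrame(columns=_REGION_COLS + ["peak_probe", "peak_p",
                                                    "excluded", "exclusion_reason"])
    out = pd.DataFrame(rows)
    out["rank"] = out["summary_effect"].abs().where(~out["excluded"]).rank(
        ascending=False)
    return out.sort_values(["excluded", "rank"], kind="stable").reset_index(drop=True)
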