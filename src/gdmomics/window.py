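"""Coordinated-regulation analysis within a genomic window.

Models the MHC-style analysis: Spearman correlations between every CpG within
10 kb of the window and every gene with TSS inside it (methylation-expression
edges), and between all gene pairs (co-expression edges), with significance
from a permutation null (default 10,000 permutations; a permutation p of
exactly 0 is floored at 1e-6) and Benjamini-Hochberg "regional" FDR applied
separately within each edge family.  Regional methylation summaries collapse
CpGs into clusters within 5 kb, capping cluster width at 10 kb.

Permutations use one shared index stream per seed, so an edge's p-value does
not depend on how many other edges are tested or in what order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .enrich import fdr_correct


P_FLOOR = 1e-6  # imputed when no permutation reaches the observed statistic


def select_window_features(annot, gene_annot, window: tuple[str, int, int],
                           flank: int = 10_000):
    """CpGs within ``flank`` bp of the window (closed interval) and genes with
    TSS strictly inside it.

    Coordinates are 1-based inclusive.  A CpG exactly at ``start - flank`` is
    included; a gene with TSS 1 bp outside the window is not.
    """
    chrom, start, end = window
    if end < start:
        raise ValueError("empty window")
    p = annot.probes
    cpgs = p.index[(p["chrom"] == chrom)
                   & p["position"].between(start - flank, end + flank)]
    g = gene_annot.genes
    genes = g.index[(g["chrom"] == chrom) & g["tss"].between(start, end)]
    return list(cpgs), list(genes)


def _rank_z(mat: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, standardized; rows with zero variance -> NaN."""
    r = np.apply_along_axis(rankdata, 1, mat)
    r = r - r.mean(axis=1, keepdims=True)
    sd = r.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, r / sd, np.nan)
    return z


def _perm_index(n: int, n_perm: int, seed: int) -> np.ndarray:
    """The shared permutation stream: an (n_perm, n) index matrix."""
    rng = np.random.default_rng(seed)
    return np.argsort(rng.random((n_perm, n)), axis=1)


def _pairwise_perm(zx: np.ndarray, zy: np.ndarray, perm: np.ndarray,
                   pairs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Observed rho and permutation p for given (row-of-zx, row-of-zy) pairs.

    rho is the Pearson correlation of standardized ranks (ties averaged);
    the second member of each pair is permuted.  Two-sided p =
    #{|rho_perm| >= |rho_obs|} / n_perm, floored at P_FLOOR when zero.
    """
    n = zx.shape[1]
    n_perm = perm.shape[0]
    rho = np.einsum("ij,ij->i", zx[pairs[:, 0]], zy[pairs[:, 1]]) / n
    ge = np.zeros(len(pairs), dtype=np.int64)
    for j in np.unique(pairs[:, 1]):
        yp = zy[j][perm]                       # n_perm x n, shared stream
        rows = np.where(pairs[:, 1] == j)[0]
        rp = zx[pairs[rows, 0]] @ yp.T / n      # edges-of-j x n_perm
        ge[rows] = (np.abs(rp) >= np.abs(rho[rows])[:, None] - 1e-12).sum(axis=1)
    p = ge / n_perm
    p = np.where(p == 0.0, P_FLOOR, p)
    return rho, p


def permutation_spearman(x, y, n_perm: int = 10_000, seed: int = 0):
    """Spearman rho with two-sided permutation significance for one pair.

    Requires paired vectors of length >= 10.  Constant input leaves rho
    undefined: the pair is reported as (nan, nan) with a warning so callers
    can drop the edge.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D vectors")
    if len(x) < 10:
        raise ValueError("permutation Spearman needs n >= 10")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman correlation undefined, "
                      "edge dropped", stacklevel=2)
        return np.nan, np.nan
    zx = _rank_z(x[None, :])
    zy = _rank_z(y[None, :])
    perm = _perm_index(len(x), n_perm, seed)
    rho, p = _pairwise_perm(zx, zy, perm, np.array([[0, 0]]))
    return float(rho[0]), float(p[0])


@dataclass
class WindowNetworks:
    """q<0.05 edge tables for the two families, plus all tested edges."""

    meth_expr: pd.DataFrame
    expr_expr: pd.DataFrame
    all_meth_expr: pd.DataFrame = field(repr=False, default=None)
    all_expr_expr: pd.DataFrame = field(repr=False, default=None)


def build_networks(beta_w: pd.DataFrame, expr_w: pd.DataFrame,
                   n_perm: int = 10_000, seed: int = 0,
                   q_threshold: float = 0.05,
                   max_expr_edges: int = 100) -> WindowNetworks:
    """Permutation Spearman networks over a window.

    ``beta_w``: CpG x sample methylation; ``expr_w``: gene x sample
    expression (aligned columns).  Both families are BH-corrected separately
    across the window; the methylation-expression network returns every
    q < ``q_threshold`` edge, the co-expression network the
    ``max_expr_edges`` strongest (by |rho|) of its significant edges.
    """
    if list(beta_w.columns) != list(expr_w.columns):
        raise ValueError("sample columns of the two matrices differ")
    n = beta_w.shape[1]
    if n < 10:
        raise ValueError("window correlation needs >= 10 samples")
    zc = _rank_z(beta_w.to_numpy(dtype=float))
    zg = _rank_z(expr_w.to_numpy(dtype=float))
    ok_c = ~np.isnan(zc).any(axis=1)
    ok_g = ~np.isnan(zg).any(axis=1)
    if (~ok_c).any() or (~ok_g).any():
        warnings.warn("constant features dropped from the window network",
                      stacklevel=2)
    perm = _perm_index(n, n_perm, seed)

    ci = np.where(ok_c)[0]
    gi = np.where(ok_g)[0]
    me_pairs = np.array([(i, j) for i in ci for j in gi], dtype=int)
    if len(me_pairs):
        rho, p = _pairwise_perm(zc, zg, perm, me_pairs)
        me = pd.DataFrame({"cpg": beta_w.index[me_pairs[:, 0]],
                           "gene": expr_w.index[me_pairs[:, 1]],
                           "rho": rho, "perm_p": p})
        me["q_value"] = fdr_correct(me["perm_p"].to_numpy())
    else:
        me = pd.DataFrame(columns=["cpg", "gene", "rho", "perm_p", "q_value"])

    if len(gi) >= 2:
        ee_pairs = np.array([(a, b) for k, a in enumerate(gi) for b in gi[k + 1:]],
                            dtype=int)
        rho, p = _pairwise_perm(zg, zg, perm, ee_pairs)
        ee = pd.DataFrame({"gene_a": expr_w.index[ee_pairs[:, 0]],
                           "gene_b": expr_w.index[ee_pairs[:, 1]],
                           "rho": rho, "perm_p": p})
        ee["q_value"] = fdr_correct(ee["perm_p"].to_numpy())
    else:
        warnings.warn("fewer than 2 genes: co-expression family skipped",
                      stacklevel=2)
        ee = pd.DataFrame(columns=["gene_a", "gene_b", "rho", "perm_p", "q_value"])

    me_sig = me[me["q_value"] < q_threshold].reset_index(drop=True)
    ee_sig = ee[ee["q_value"] < q_threshold]
    ee_sig = ee_sig.reindex(ee_sig["rho"].abs().sort_values(ascending=False).index)
    ee_sig = ee_sig.head(max_expr_edges).reset_index(drop=True)
    return WindowNetworks(meth_expr=me_sig, expr_expr=ee_sig,
                          all_meth_expr=me, all_expr_expr=ee)


def collapse_clusters(beta_w: pd.DataFrame, positions: pd.Series,
                      within: int = 5_000, max_width: int = 10_000):
    """Greedy left-to-right CpG clustering with per-sample mean methylation.

    Extend the current cluster while the next CpG is within ``within`` bp of
    the last member and the total span stays <= ``max_width``.  Every CpG
    belongs to exactly one cluster.  Returns (cluster x sample mean-beta
    DataFrame, membership DataFrame).
    """
    positions = positions.loc[beta_w.index]
    if not positions.is_monotonic_increasing:
        raise ValueError("positions must be sorted")
    pos = positions.to_numpy()
    clusters: list[list[int]] = []
    for i in range(len(pos)):
        if clusters and pos[i] - pos[clusters[-1][-1]] <= within \
                and pos[i] - pos[clusters[-1][0]] <= max_width:
            clusters[-1].append(i)
        else:
            clusters.append([i])
    vals, members = [], []
    for k, idx in enumerate(clusters):
        vals.append(beta_w.iloc[idx].mean(axis=0))
        members.append(dict(cluster=f"cl{k:03d}", start=int(pos[idx[0]]),
                            end=int(pos[idx[-1]]), n_cpgs=len(idx),
                            probe_ids=",".join(beta_w.index[idx])))
    mem = pd.DataFrame(members)
    out = pd.DataFrame(vals, index=pd.Index(mem["cluster"], name="cluster"))
    return out, mem


def group_difference_profile(collapsed_meth: pd.DataFrame, expr_w: pd.DataFrame,
                             samples: pd.DataFrame) -> pd.DataFrame:
    """Unadjusted case-minus-control mean difference per cluster and per gene."""
    gdm = samples["gdm"].astype(bool)
    cases = samples.index[gdm]
    ctrls = samples.index[~gdm]
    if len(cases) == 0 or len(ctrls) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for kind, mat in (("methylation", collapsed_meth), ("expression", expr_w)):
        diff = mat[cases].mean(axis=1) - mat[ctrls].mean(axis=1)
        for feat, d in diff.items():
            rows.append(dict(feature=feat, kind=kind, difference=float(d)))
    return pd.DataFrame(rows)


def random_control_windows(annot, gene_annot, width: int, n_windows: int,
                           seed: int = 0, exclude: tuple[str, int, int] | None = None):
    """Random same-width windows on autosomes, avoiding ``exclude``; for the
    control-envelope comparison of group differences."""
    rng = np.random.default_rng(seed)
    chroms = [c for c in annot.probes["chrom"].unique() if c not in ("chrX", "chrY")]
    maxpos = annot.probes.groupby("chrom")["position"].max()
    out = []
    tries = 0
    while len(out) < n_windows and tries < 100 * n_windows:
        tries += 1
        c = str(rng.choice(chroms))
        hi = int(maxpos[c]) - width
        if hi <= 1:
            continue
        s = int(rng.integers(1, hi))
        w = (c, s, s + width)
        if exclude and c == exclude[0] and not (w[2] < exclude[1] or w[1] > exclude[2]):
            continue
        out.append(w)
    return out
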