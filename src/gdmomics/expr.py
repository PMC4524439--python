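"""Expression preprocessing: background correction, quantile normalization,
median-polish summarization, and qRT-PCR delta-Ct.

Probe-level array intensities are background-corrected by subtracting a
per-sample low-quantile baseline (floored at a small positive constant so the
subsequent log2 is defined), quantile-normalized across samples on the log2
scale, and summarized to one value per gene by median polish of the
probes-of-a-gene x samples block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .meth import quantile_normalize


@dataclass
class ExpressionMatrix:
    """Gene x sample summarized log2 expression."""

    values: pd.DataFrame

    def validate(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("non-finite expression values")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene rows")


def background_correct(probe_matrix: pd.DataFrame, baseline_quantile: float = 0.025,
                       floor: float = 1.0) -> pd.DataFrame:
    """Subtract a per-sample low-quantile baseline from linear-scale intensities.

    The correction removes an additive background while preserving
    within-sample order (it is a monotone shift); values are floored at
    ``floor`` so log2 downstream is finite.
    """
    x = probe_matrix.to_numpy(dtype=float)
    if (x <= 0).any():
        raise ValueError("background correction requires positive intensities")
    base = np.quantile(x, baseline_quantile, axis=0)
    out = np.maximum(x - base[None, :], floor)
    return pd.DataFrame(out, index=probe_matrix.index, columns=probe_matrix.columns)


def median_polish(block: np.ndarray, tol: float = 1e-6, max_iter: int = 20):
    """Additive decomposition x_ij ~ overall + row_i + col_j by median sweeps.

    Sweeps rows then columns (fixed order, for determinism) until the largest
    change in a sweep falls below ``tol`` or ``max_iter`` iterations.  Returns
    ``(overall, row_effects, col_effects, residuals)``.
    """
    x = np.asarray(block, dtype=float)
    if x.ndim != 2 or x.size == 0:
        raise ValueError("median polish needs a non-empty 2-D block")
    if np.isnan(x).all():
        raise ValueError("all-missing block")
    r = x.copy()
    overall = 0.0
    row = np.zeros(x.shape[0])
    col = np.zeros(x.shape[1])
    for _ in range(max_iter):
        row_med = np.nanmedian(r, axis=1)
        r -= row_med[:, None]
        row += row_med
        shift = np.nanmedian(row)
        row -= shift
        overall += shift
        col_med = np.nanmedian(r, axis=0)
        r -= col_med[None, :]
        col += col_med
        shift2 = np.nanmedian(col)
        col -= shift2
        overall += shift2
        delta = max(np.abs(row_med).max(), np.abs(col_med).max(),
                    abs(shift), abs(shift2))
        if delta < tol:
            break
    return overall, row, col, r


def summarize_genes(probe_matrix: pd.DataFrame, probe_gene: pd.Series,
                    tol: float = 1e-6, max_iter: int = 20) -> ExpressionMatrix:
    """Median-polish each gene's probe block into one per-sample value.

    ``probe_matrix`` is log2-scale probes x samples; ``probe_gene`` maps each
    probe row to its gene.  The gene value is overall + column effect, i.e.
    the robust per-sample level after removing probe affinities.
    """
    if not probe_matrix.index.equals(probe_gene.index):
        probe_gene = probe_gene.loc[probe_matrix.index]
    out, gene_ids = [], []
    for gid, idx in probe_matrix.groupby(probe_gene, sort=True).groups.items():
        block = probe_matrix.loc[idx].to_numpy(dtype=float)
        overall, _, colfx, _ = median_polish(block, tol=tol, max_iter=max_iter)
        out.append(overall + colfx)
        gene_ids.append(gid)
    em = ExpressionMatrix(values=pd.DataFrame(
        np.vstack(out), index=pd.Index(gene_ids, name="gene_id"),
        columns=probe_matrix.columns))
    em.validate()
    return em


def preprocess_expression(probe_table: pd.DataFrame,
                          baseline_quantile: float = 0.025) -> ExpressionMatrix:
    """Background-correct -> log2 -> quantile-normalize -> median polish.

    ``probe_table`` is the generator/array export: a ``gene_id`` column plus
    one linear-scale intensity column per sample.
    """
    gene = probe_table["gene_id"]
    mat = probe_table.drop(columns=["gene_id"])
    corrected = background_correct(mat, baseline_quantile=baseline_quantile)
    log2 = np.log2(corrected)
    qn = quantile_normalize(log2)
    return summarize_genes(qn, gene)


def delta_ct(ct_long: pd.DataFrame, ref_gene: str = "GAPDH") -> pd.DataFrame:
    """qRT-PCR expression: delta Ct = Ct(gene of interest) - Ct(reference gene).

    ``ct_long`` is long format with columns ``sample, gene, replicate, ct``;
    replicates (typically triplicates) are averaged per sample x gene before
    subtraction.  A missing replicate is tolerated with a warning; a sample
    with no usable Ct for a gene yields a missing delta Ct.
    """
    d = ct_long.copy()
    if (d["ct"].dropna() <= 0).any():
        raise ValueError("Ct values must be positive")
    n_expected = d.groupby(["sample", "gene"])["ct"].size()
    means = d.groupby(["sample", "gene"])["ct"].mean()
    n_obs = d.groupby(["sample", "gene"])["ct"].count()
    if (n_obs < n_expected).any():
        warnings.warn("missing qRT-PCR replicates averaged over remaining wells",
                      stacklevel=2)
    wide = means.unstack("gene")
    if ref_gene not in wide.columns:
        raise ValueError(f"reference gene {ref_gene!r} not measured")
    out = wide.drop(columns=[ref_gene]).sub(wide[ref_gene], axis=0)
    out.columns.name = "gene"
    return out
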