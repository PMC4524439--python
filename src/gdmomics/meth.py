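"""Methylation preprocessing: beta computation, normalization, probe-type
adjustment and probe filtering.

The beta value is the standard Infinium methylation-fraction estimate
``beta = M / (M + U + 100)`` with a +100 offset that regularizes low-intensity
probes and keeps beta strictly below 1.  Quantile normalization operates on
channel intensities across samples; probe-type bias (type II betas are
compressed relative to type I) is removed by mapping each sample's type II
values onto its own type I empirical distribution; and analysis is restricted
to autosomal probes free of SNP-at-target and X-cross-hybridization artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .synth import IntensityMatrix, ProbeAnnotation


@dataclass
class BetaMatrix:
    """Methylation levels in [0, 1], probe x sample, with provenance flags."""

    values: pd.DataFrame
    normalized: bool = False
    type_adjusted: bool = False
    filtered: bool = False
    filter_report: pd.DataFrame | None = field(default=None, repr=False)

    def validate(self) -> None:
        v = self.values.to_numpy()
        if np.isnan(v).any():
            raise ValueError("missing beta values")
        if (v < 0).any() or (v > 1).any():
            raise ValueError("beta values outside [0, 1]")


def compute_beta(M, U, offset: float = 100.0):
    """``beta = M / (M + U + offset)``, elementwise.

    Accepts scalars, arrays or aligned DataFrames.  Negative intensities are
    an upstream error and are reported with probe/sample coordinates when the
    inputs are labelled.
    """
    M_arr, U_arr = np.asarray(M, dtype=float), np.asarray(U, dtype=float)
    for name, arr, obj in (("methylated", M_arr, M), ("unmethylated", U_arr, U)):
        if (arr < 0).any():
            where = ""
            if isinstance(obj, pd.DataFrame):
                r, c = np.argwhere(arr < 0)[0]
                where = f" (first at probe {obj.index[r]!r}, sample {obj.columns[c]!r})"
            raise ValueError(f"negative {name} intensity{where}")
    beta = M_arr / (M_arr + U_arr + offset)
    if isinstance(M, pd.DataFrame):
        return pd.DataFrame(beta, index=M.index, columns=M.columns)
    return beta


def intensities_to_beta(im: IntensityMatrix, offset: float = 100.0) -> BetaMatrix:
    return BetaMatrix(values=compute_beta(im.methylated, im.unmethylated, offset))


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean empirical distribution.

    After normalization the sorted values of each column equal the
    cross-sample mean of order statistics; within-column ranks are preserved
    and ties receive the average of the tied reference positions.
    """
    if matrix.shape[1] < 2:
        warnings.warn("quantile normalization with a single sample is the identity",
                      stacklevel=2)
        return matrix.copy()
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing values not supported in quantile normalization")
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    grid = np.arange(1, x.shape[0] + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")  # ties -> averaged positions
        out[:, j] = np.interp(ranks, grid, ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def normalize_intensities(im: IntensityMatrix) -> IntensityMatrix:
    """Quantile-normalize each channel across samples."""
    return IntensityMatrix(methylated=quantile_normalize(im.methylated),
                           unmethylated=quantile_normalize(im.unmethylated))


def adjust_probe_type(beta: BetaMatrix, annot: ProbeAnnotation,
                      min_probes: int = 50) -> BetaMatrix:
    """Map type II betas onto the type I empirical distribution, per sample.

    A direct empirical quantile mapping: each type II value at within-type
    quantile q is replaced by the q-th quantile of the same sample's type I
    values.  Type I values are never altered; type II rank order is
    preserved.  Samples with fewer than ``min_probes`` probes of either type
    are left unadjusted with a warning.  This is the module's probe-chemistry
    harmonization step; a model-based beta-mixture fit can be swapped in at
    this hook point.
    """
    types = annot.probes.loc[beta.values.index, "probe_type"]
    is1 = (types == "I").to_numpy()
    is2 = ~is1
    if is1.sum() == 0 or is2.sum() == 0:
        raise ValueError("both probe types must be present")
    out = beta.values.to_numpy(dtype=float).copy()
    if is1.sum() < min_probes or is2.sum() < min_probes:
        warnings.warn("too few probes of one type; probe-type adjustment skipped",
                      stacklevel=2)
        return BetaMatrix(values=beta.values.copy(), normalized=beta.normalized,
                          type_adjusted=False, filtered=beta.filtered)
    n2 = int(is2.sum())
    for j in range(out.shape[1]):
        t1 = np.sort(out[is1, j])
        v2 = out[is2, j]
        if n2 == 1:
            q = np.array([0.5])
        else:
            q = (rankdata(v2, method="average") - 1.0) / (n2 - 1.0)
        out[is2, j] = np.quantile(t1, q)
    out = np.clip(out, 0.0, 1.0)
    return BetaMatrix(values=pd.DataFrame(out, index=beta.values.index,
                                          columns=beta.values.columns),
                      normalized=beta.normalized, type_adjusted=True,
                      filtered=beta.filtered)


def filter_probes(beta: BetaMatrix, annot: ProbeAnnotation,
                  autosomes: tuple[str, ...] | None = None) -> BetaMatrix:
    """Restrict to autosomal probes without SNP-at-target or X-cross-hybridization.

    A probe failing several criteria is removed once but counted under each.
    Probes missing annotation raise (never silently retained).  Idempotent.
    """
    missing = beta.values.index.difference(annot.probes.index)
    if len(missing):
        raise ValueError(f"{len(missing)} probes missing annotation "
                         f"(first: {missing[0]!r})")
    sub = annot.probes.loc[beta.values.index]
    if autosomes is None:
        non_auto = sub["chrom"].isin(["chrX", "chrY"])
    else:
        non_auto = ~sub["chrom"].isin(autosomes)
    snp = sub["snp_at_target"].astype(bool)
    xhyb = sub["cross_hyb_x"].astype(bool)
    keep = ~(non_auto | snp | xhyb)
    report = pd.DataFrame(
        {"criterion": ["non_autosomal", "snp_at_target", "cross_hyb_x", "retained"],
         "n": [int(non_auto.sum()), int(snp.sum()), int(xhyb.sum()), int(keep.sum())]})
    return BetaMatrix(values=beta.values.loc[keep], normalized=beta.normalized,
                      type_adjusted=beta.type_adjusted, filtered=True,
                      filter_report=report)


def preprocess_methylation(im: IntensityMatrix, annot: ProbeAnnotation,
                           normalize: bool = True, adjust_types: bool = True,
                           do_filter: bool = True) -> BetaMatrix:
    """Full preprocessing chain: QN on intensities -> beta -> type adjust -> filter."""
    if normalize:
        im = normalize_intensities(im)
    beta = intensities_to_beta(im)
    beta.normalized = normalize
    if adjust_types:
        beta = adjust_probe_type(beta, annot)
    if do_filter:
        beta = filter_probes(beta, annot)
    beta.validate()
    return beta
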