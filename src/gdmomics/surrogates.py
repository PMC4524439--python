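"""Data-driven surrogate variables for technical and error-prone confounders.

Chip/row/column plating effects and error-prone self-reported covariates
(ethnicity) leave structured variation in high-dimensional molecular data
even after normalization.  This module estimates latent sample-space
components of that structure and keeps only the ones that demonstrably track
a measured confounder surrogate, so downstream models adjust for real batch
axes rather than arbitrary principal components.

Procedure: (1) residualize the feature matrix on the full primary design
(including the exposure, so exposure signal cannot be absorbed into a
surrogate); (2) decompose the residual into ``k_max`` sample-space components
-- by default the leading right singular vectors (principal axes; an
optional FastICA rotation of that subspace is available, but at desk-scale
sample sizes the ICA rotation splits a single batch axis across several
components and weakens the screen); (3) test every
component against every confounder (one-way ANOVA across the categorical
levels); (4) select components with Benjamini-Hochberg q < 0.05 against any
confounder.  Components are returned orthonormalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .enrich import fdr_correct


@dataclass
class SurrogateSet:
    """Estimated components (samples x k), association report, selection."""

    components: np.ndarray
    report: pd.DataFrame          # component, confounder, p_value, q_value
    selected_idx: list[int]
    method: str

    @property
    def selected(self) -> np.ndarray:
        return self.components[:, self.selected_idx]

    @property
    def n_selected(self) -> int:
        return len(self.selected_idx)


def estimate_surrogates(
    data: pd.DataFrame | np.ndarray,
    primary_design: np.ndarray,
    confounders: pd.DataFrame,
    k_max: int | None = None,
    q_threshold: float = 0.05,
    method: str = "pca",
    seed: int = 0,
    n_assoc_perm: int = 1999,
) -> SurrogateSet:
    """Estimate and screen latent confounder surrogates.

    ``data`` is features x samples; ``primary_design`` the samples x p model
    matrix of the main analysis; ``confounders`` a samples x c table of
    categorical confounder surrogates (chip, row, column, ethnicity).
    """
    Y = np.asarray(getattr(data, "values", data), dtype=float)
    if isinstance(data, pd.DataFrame):
        Y = data.to_numpy(dtype=float)
    X = np.asarray(primary_design, dtype=float)
    n = X.shape[0]
    if Y.shape[1] != n or len(confounders) != n:
        raise ValueError("data, design and confounder tables disagree on sample count")
    rank = np.linalg.matrix_rank(X)
    if k_max is None:
        k_max = min(10, n // 5)
    if k_max >= n:
        raise ValueError(f"k_max={k_max} must be < n_samples={n}")
    k_max = min(k_max, n - rank - 1)
    if k_max < 1:
        raise ValueError("no residual degrees of freedom for surrogate estimation")

    # residualize on the full primary design (exposure included: protection)
    P = X @ np.linalg.pinv(X)
    R = Y - Y @ P.T

    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    scores = Vt[:k_max].T * s[:k_max]          # samples x k, scaled
    used = method
    if method == "ica":
        rng_state = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                ica = FastICA(n_components=k_max, random_state=rng_state,
                              whiten="unit-variance", max_iter=500)
                comps = ica.fit_transform(scores)
        except (ConvergenceWarning, ValueError):
            comps = scores
            used = "pca-fallback"
    elif method == "pca":
        comps = scores
    else:
        raise ValueError(f"unknown method {method!r}")
    # orthonormal basis of the component space, fixed sign convention
    comps, _ = np.linalg.qr(comps)
    sign = np.sign(comps[np.abs(comps).argmax(axis=0), np.arange(comps.shape[1])])
    comps = comps * np.where(sign == 0, 1.0, sign)

    # permutation one-way ANOVA: ICA components are intentionally
    # non-Gaussian, so the parametric F reference is anti-conservative on
    # null data; permuting the confounder labels is exact here
    perm_rng = np.random.default_rng(
        np.random.SeedSequence(seed).generate_state(2)[1] % (2**31))
    perm = np.argsort(perm_rng.random((n_assoc_perm, n)), axis=1)
    rows = []
    for c in confounders.columns:
        codes, _ = pd.factorize(confounders[c])
        sizes = np.bincount(codes)
        if (sizes > 0).sum() < 2:
            for j in range(comps.shape[1]):
                rows.append(dict(component=j, confounder=c, p_value=1.0))
            continue
        G = np.zeros((n, len(sizes)))
        G[np.arange(n), codes] = 1.0
        for j in range(comps.shape[1]):
            x = comps[:, j]
            tot = x.sum()
            def between(v):
                gs = v @ G
                return float(((gs**2) / np.maximum(sizes, 1)).sum()
                             - tot**2 / n)
            obs = between(x)
            xp = x[perm]                       # n_perm x n
            gs = xp @ G                        # n_perm x groups
            b = ((gs**2) / np.maximum(sizes, 1)).sum(axis=1) - tot**2 / n
            p = float((np.sum(b >= obs - 1e-12) + 1) / (n_assoc_perm + 1))
            rows.append(dict(component=j, confounder=c, p_value=p))
    report = pd.DataFrame(rows)
    report["q_value"] = fdr_correct(report["p_value"].to_numpy())
    sel = sorted(report.loc[report["q_value"] < q_threshold, "component"].unique())
    if not sel:
        warnings.warn("no surrogate component associated with any confounder; "
                      "models proceed unadjusted", stacklevel=2)
    return SurrogateSet(components=comps, report=report,
                        selected_idx=[int(j) for j in sel], method=used)
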