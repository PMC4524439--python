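"""Regional pyrosequencing analysis via linear mixed models.

Pyrosequencing reports percent methylation ``100 * C / (C + T)`` at each CpG
in an amplicon.  The regional association with GDM is estimated by a linear
mixed model over all CpG x sample observations with a random intercept per
sample (CpGs from one sample share a placenta) and fixed adjustment for
maternal age, pre-pregnancy BMI, infant sex, smoking and self-reported
ethnicity.  Effect modification is tested by the Wald p of a GDM x modifier
interaction, with stratum-specific GDM effects reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm


REGIONAL_COVARIATES = ("age", "bmi", "sex", "smoking", "ethnicity")


def percent_methylation(C, T):
    """Percent methylation = 100 * C / (C + T); zero depth -> missing."""
    C_arr = np.asarray(C, dtype=float)
    T_arr = np.asarray(T, dtype=float)
    depth = C_arr + T_arr
    if (depth == 0).any():
        warnings.warn("zero-depth CpG(s): percent methylation set to missing",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(depth > 0, 100.0 * C_arr / depth, np.nan)
    if isinstance(C, pd.DataFrame):
        return pd.DataFrame(out, index=C.index, columns=C.columns)
    return out


def make_region_long(C: pd.DataFrame, T: pd.DataFrame,
                     samples: pd.DataFrame) -> pd.DataFrame:
    """Long-format region records: one row per CpG x sample, covariates joined."""
    pct = percent_methylation(C, T)
    long = pct.reset_index(names="cpg").melt(id_vars="cpg", var_name="sample_id",
                                             value_name="percent")
    long = long.join(samples, on="sample_id")
    return long.dropna(subset=["percent"]).reset_index(drop=True)


@dataclass
class RegionalFit:
    coef: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_samples: int
    n_cpgs: int
    method: str  # "mixed" or "fixed_cluster" fallback


def _region_exog(data: pd.DataFrame, covariates, extra_cols=()):
    cols = [pd.Series(1.0, index=data.index, name="intercept"),
            data["gdm"].astype(float)]
    for c in covariates:
        s = data[c]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(s, prefix=c, drop_first=True).astype(float)
            cols.extend(d[c2] for c2 in d.columns)
        else:
            cols.append(s.astype(float))
    for name, vals in extra_cols:
        cols.append(pd.Series(np.asarray(vals, dtype=float), index=data.index,
                              name=name))
    X = pd.concat(cols, axis=1)
    return X


def _fit_mixed(data: pd.DataFrame, X: pd.DataFrame, param: str):
    """REML random-intercept fit; cluster-robust OLS fallback on singular fits."""
    endog = data["percent"].to_numpy(dtype=float)
    groups = data["sample_id"].to_numpy()
    method = "mixed"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            md = sm.MixedLM(endog, X, groups=groups)
            fit = md.fit(reml=True)
            bse_fe = np.asarray(fit.bse_fe)
            singular = (not np.isfinite(bse_fe).all()) or \
                float(np.asarray(fit.cov_re)[0, 0]) < 1e-8
        except (np.linalg.LinAlgError, ValueError):
            singular, fit = True, None
    if singular:
        method = "fixed_cluster"
        ols = sm.OLS(endog, X.to_numpy(dtype=float)).fit(
            cov_type="cluster", cov_kwds={"groups": groups})
        params = pd.Series(np.asarray(ols.params), index=X.columns)
        bse = pd.Series(np.asarray(ols.bse), index=X.columns)
    else:
        params = pd.Series(np.asarray(fit.fe_params), index=X.columns)
        bse = pd.Series(bse_fe, index=X.columns)
    coef, se = float(params[param]), float(bse[param])
    z = coef / se if se > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    half = 1.959963984540054 * se
    return coef, se, coef - half, coef + half, p, method


def fit_region_model(data: pd.DataFrame,
                     covariates=REGIONAL_COVARIATES) -> RegionalFit:
    """Regional GDM effect on percent methylation (random intercept per sample).

    ``data`` is long format with columns ``sample_id, cpg, percent`` plus the
    covariates.  Requires >= 2 CpGs and >= 10 samples.  Wald 95 % CI with a
    normal reference on the fixed effect.
    """
    n_cpgs = data["cpg"].nunique()
    n_samp = data["sample_id"].nunique()
    if n_cpgs < 2:
        raise ValueError("regional model needs >= 2 CpGs")
    if n_samp < 10:
        raise ValueError("regional model needs >= 10 samples")
    X = _region_exog(data, covariates)
    coef, se, lo, hi, p, method = _fit_mixed(data, X, "gdm")
    if method == "fixed_cluster":
        warnings.warn("singular random-intercept fit; cluster-robust "
                      "fixed-effects estimates reported", stacklevel=2)
    return RegionalFit(coef=coef, se=se, ci_low=lo, ci_high=hi, p_value=p,
                       n_samples=n_samp, n_cpgs=n_cpgs, method=method)


@dataclass
class ModificationResult:
    interaction_p: float
    interaction_coef: float
    strata: pd.DataFrame  # stratum, coef, ci_low, ci_high, p_value, n_samples


def test_effect_modification(data: pd.DataFrame, modifier: str,
                             covariates=REGIONAL_COVARIATES) -> ModificationResult:
    """GDM x modifier interaction Wald test plus stratum-specific effects.

    ``modifier`` names a dichotomous column of ``data`` (e.g. age dichotomized
    at the discovery-cohort median).  Both strata must contain at least three
    cases and three controls.
    """
    mod = data[modifier]
    levels = sorted(mod.unique())
    if len(levels) != 2:
        raise ValueError(f"modifier {modifier!r} must be dichotomous, "
                         f"got {len(levels)} level(s)")
    per_sample = data.drop_duplicates("sample_id")
    for lev in levels:
        sub = per_sample[per_sample[modifier] == lev]
        if (sub["gdm"] == 1).sum() < 3 or (sub["gdm"] == 0).sum() < 3:
            raise ValueError(f"stratum {modifier}={lev!r} has fewer than "
                             "3 cases or 3 controls")

    base_covs = tuple(c for c in covariates if c != modifier)
    mod01 = (mod == levels[1]).astype(float)
    inter = mod01 * data["gdm"].astype(float)
    X = _region_exog(data, base_covs,
                     extra_cols=[(f"{modifier}_hi", mod01),
                                 (f"gdm_x_{modifier}", inter)])
    coef, se, _, _, p, _ = _fit_mixed(data, X, f"gdm_x_{modifier}")

    strata_rows = []
    for lev in levels:
        sub = data[data[modifier] == lev]
        fit = fit_region_model(sub, covariates=base_covs)
        strata_rows.append(dict(stratum=f"{modifier}={lev}", coef=fit.coef,
                                ci_low=fit.ci_low, ci_high=fit.ci_high,
                                p_value=fit.p_value, n_samples=fit.n_samples))
    return ModificationResult(interaction_p=p, interaction_coef=coef,
                              strata=pd.DataFrame(strata_rows))
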