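"""Per-gene, sex-stratified linear exposure models.

Each gene's log2 expression is regressed on long-term PM10 or PM2.5 exposure
(ug/m3) with covariate adjustment; the exposure coefficient beta (log2 units
per ug/m3) is reported as a fold change per 5 ug/m3 increment,
``fc5 = 2**(5*beta)``, with a t-based 95% CI. Residual-driven significance is
guarded by a reproducible outlier rule: observations with absolute externally
studentized residual above a threshold (default 4) are dropped once and the
model refit. p-values are Benjamini-Hochberg adjusted within each
sex-by-exposure analysis and genes ranked by ascending p.

A pooled sex-interaction scan (sex main effect plus sex x exposure product
term) quantifies whether associations differ between men and women.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DesignError, InputDataError

#: covariate sets matching the two study designs
DISCOVERY_COVARIATES = ("age", "bmi", "ses", "season", "daytime")
VALIDATION_COVARIATES = (
    "age",
    "bmi",
    "ses",
    "smoking",
    "leukocytes",
    "neutrophils",
    "season",
    "daytime",
)

_CATEGORICAL = {
    "ses": ("low", "medium", "high"),
    "season": ("cold", "warm"),
    "daytime": ("<1200", "1200-1500", "1500-1800", ">2000"),
    "smoking": ("never", "former", "current"),
}


@dataclass
class DesignSpec:
    exposure: str = "pm10"
    covariates: tuple = DISCOVERY_COVARIATES
    stratum: str = "M"  # "M", "F" or "pooled"
    outlier_threshold: float = 4.0
    increment: float = 5.0

    def validate(self) -> None:
        if self.exposure not in ("pm10", "pm25"):
            raise DesignError(f"unknown exposure {self.exposure!r}")
        if self.stratum not in ("M", "F", "pooled"):
            raise DesignError(f"unknown stratum {self.stratum!r}")


@dataclass
class GeneFit:
    slope: float
    se: float
    p: float
    df_resid: int
    n_used: int
    outliers_removed: int
    degenerate: bool = False


def _encode_covariates(cohort: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric covariate design columns; categorical levels use the first
    category as reference and unobserved levels produce no column."""
    X = pd.DataFrame(index=cohort.index)
    for cov in covariates:
        if cov in _CATEGORICAL:
            levels = _CATEGORICAL[cov]
            observed = [lv for lv in levels if (cohort[cov] == lv).any()]
            for lv in observed[1:]:
                X[f"{cov}[{lv}]"] = (cohort[cov] == lv).astype(float)
        else:
            if cohort[cov].isna().any():
                raise InputDataError(f"covariate {cov!r} has missing values")
            X[cov] = cohort[cov].astype(float)
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # name columns whose removal restores full rank
        culprits = []
        for j, col in enumerate(X.columns):
            sub = np.delete(A, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                culprits.append(col)
        raise DesignError(f"rank-deficient design; collinear columns: {culprits}")


def build_design(cohort: pd.DataFrame, design: DesignSpec):
    """Subset the cohort to the stratum and build the regression matrix.

    Returns ``(sub_cohort, X)`` where X has a constant, the exposure column
    and the encoded covariates, verified to be full rank.
    """
    design.validate()
    sub = cohort if design.stratum == "pooled" else cohort[cohort["sex"] == design.stratum]
    if len(sub) == 0:
        raise DesignError(f"no participants in stratum {design.stratum!r}")
    X = pd.DataFrame(index=sub.index)
    X["const"] = 1.0
    X[design.exposure] = sub[design.exposure].astype(float)
    X = pd.concat([X, _encode_covariates(sub, design.covariates)], axis=1)
    _check_full_rank(X)
    return sub, X


def _studentized_external(res) -> np.ndarray:
    """Externally studentized residuals computed from the fitted OLS results."""
    X = res.model.exog
    h = (X * np.linalg.pinv(X).T).sum(axis=1)
    e = res.resid
    n, p = X.shape
    sse = float(e @ e)
    denom_df = n - p - 1
    if denom_df <= 0:
        return np.zeros(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2_loo = (sse - e ** 2 / (1.0 - h)) / denom_df
        t = e / np.sqrt(np.maximum(s2_loo, 0.0) * (1.0 - h))
    return np.where(np.isfinite(t), t, 0.0)


def fit_gene_model(y: pd.Series, cohort: pd.DataFrame, design: DesignSpec) -> GeneFit:
    """OLS of one gene's log2 expression on exposure plus covariates.

    ``y`` is indexed by sample_id; samples missing from y (or NaN) are
    dropped. A zero-variance response returns the degenerate convention
    (slope 0, p 1). Observations with |externally studentized residual| above
    the design threshold are removed once and the model refit.
    """
    sub, X = build_design(cohort, design)
    yv = y.reindex(sub["sample_id"]).astype(float)
    keep = yv.notna().to_numpy()
    yv = yv.to_numpy(float)[keep]
    Xv = X.to_numpy(float)[keep]
    n = len(yv)
    if n < Xv.shape[1] + 2:
        raise InputDataError(f"too few observations ({n}) for {Xv.shape[1]} design columns")
    if np.ptp(yv) == 0.0:
        return GeneFit(0.0, 0.0, 1.0, n - Xv.shape[1], n, 0, degenerate=True)

    res = sm.OLS(yv, Xv).fit()
    outliers_removed = 0
    if design.outlier_threshold is not None and np.isfinite(design.outlier_threshold):
        t_ext = _studentized_external(res)
        mask = np.abs(t_ext) <= design.outlier_threshold
        if not mask.all() and mask.sum() >= Xv.shape[1] + 2:
            outliers_removed = int((~mask).sum())
            yv, Xv = yv[mask], Xv[mask]
            res = sm.OLS(yv, Xv).fit()

    slope = float(res.params[1])
    se = float(res.bse[1])
    if not np.isfinite(se) or se == 0.0:
        p = 1.0 if slope == 0.0 else 0.0
        se = 0.0
    else:
        p = float(res.pvalues[1])
    return GeneFit(slope, se, p, int(res.df_resid), len(yv), outliers_removed)


def fc_per_increment(slope: float, se: float, df: int, increment: float = 5.0):
    """Fold change for an exposure increment: ``2**(increment*slope)`` with CI.

    The CI uses the t quantile at the residual degrees of freedom:
    ``2**(increment*(slope +/- t_{0.975,df}*se))``.
    """
    if se < 0:
        raise InputDataError("se must be >= 0")
    fc = float(2.0 ** (increment * slope))
    tq = stats.t.ppf(0.975, df) if df > 0 else np.inf
    half = increment * tq * se
    lo = float(2.0 ** (increment * slope - half))
    hi = float(2.0 ** (increment * slope + half))
    return fc, (lo, hi)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    ``q_(i) = min_{j >= i} (m * p_(j) / j)``, clipped at 1.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise InputDataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def rank_genes(results: pd.DataFrame) -> pd.DataFrame:
    """Sort ascending by p (ties: lexicographic gene id) and set 1-based ranks."""
    out = results.sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def analyze(expr: pd.DataFrame, cohort: pd.DataFrame, design: DesignSpec) -> pd.DataFrame:
    """Fit every gene and assemble the ranked association table.

    Returns one row per gene: slope (log2 per ug/m3), se, fc5 with CI, p, BH
    q within this analysis family, rank, n_used and outliers_removed.
    """
    rows = []
    for gene in expr.index:
        fit = fit_gene_model(expr.loc[gene], cohort, design)
        fc, (lo, hi) = fc_per_increment(fit.slope, fit.se, fit.df_resid, design.increment)
        rows.append(
            {
                "gene": gene,
                "n_used": fit.n_used,
                "slope": fit.slope,
                "se": fit.se,
                "fc5": fc,
                "ci_low": lo,
                "ci_high": hi,
                "p": fit.p,
                "outliers_removed": fit.outliers_removed,
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    return rank_genes(table)


def interaction_scan(
    expr: pd.DataFrame, cohort: pd.DataFrame, design: DesignSpec
) -> pd.Series:
    """Pooled per-gene p-value for the sex x exposure product term."""
    if set(cohort["sex"].unique()) != {"M", "F"}:
        raise DesignError("interaction scan needs both sexes in the cohort")
    if np.ptp(cohort[design.exposure].to_numpy(float)) == 0.0:
        raise DesignError("exposure is constant; interaction term not identifiable")
    pooled = DesignSpec(
        exposure=design.exposure,
        covariates=design.covariates,
        stratum="pooled",
        outlier_threshold=design.outlier_threshold,
        increment=design.increment,
    )
    sub, X = build_design(cohort, pooled)
    if np.ptp(sub[design.exposure].to_numpy(float)) == 0.0:
        raise DesignError("exposure is constant; interaction term not identifiable")
    sex_m = (sub["sex"] == "M").astype(float)
    X = X.copy()
    X["sex[M]"] = sex_m
    X["sex_x_exposure"] = sex_m * sub[design.exposure].astype(float)
    _check_full_rank(X)

    Xv = X.to_numpy(float)
    j = X.columns.get_loc("sex_x_exposure")
    out = {}
    for gene in expr.index:
        yv = expr.loc[gene].reindex(sub["sample_id"]).astype(float)
        keep = yv.notna().to_numpy()
        res = sm.OLS(yv.to_numpy(float)[keep], Xv[keep]).fit()
        out[gene] = float(res.pvalues[j])
    return pd.Series(out, name="interaction_p")
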