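"""Exposure dichotomization and multi-gene ROC classification.

Participants are split at a percentile of the cohort's long-term exposure
(default: 75th, high = above the cutoff). A panel score is a standardized
logistic-regression combination of the panel genes' log2 expression values;
its discrimination is summarised by the ROC AUC (Mann-Whitney formulation,
ties counting one half), a DeLong 95% CI and a two-sided test against
chance (AUC = 0.5). In-sample AUC matches the usual reporting convention for
fitted panels and is optimistically biased; a stratified cross-validated AUC
is therefore reported alongside it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .errors import InputDataError

log = logging.getLogger(__name__)

#: fixed small ridge engaged only under perfect separation
_RIDGE_C = 1e3


@dataclass
class ExposureLabels:
    high: pd.Series  # boolean per sample
    cutoff: float
    percentile: float

    @property
    def n_high(self) -> int:
        return int(self.high.sum())

    @property
    def n_low(self) -> int:
        return int((~self.high).sum())


def dichotomize(exposures: pd.Series, percentile: float = 75.0) -> ExposureLabels:
    """Label samples high/low at a linear-interpolation percentile cutoff."""
    x = exposures.astype(float)
    if len(x) < 8:
        raise InputDataError("need at least 8 samples to dichotomize")
    if np.ptp(x.to_numpy()) == 0.0:
        raise InputDataError("exposure is constant; cannot dichotomize")
    cutoff = float(np.percentile(x.to_numpy(), percentile))
    high = x > cutoff
    if high.sum() == 0 or (~high).sum() == 0:
        raise InputDataError("degenerate split: one exposure class is empty")
    return ExposureLabels(high=high, cutoff=cutoff, percentile=percentile)


@dataclass
class PanelScoreModel:
    genes: list
    coef: np.ndarray
    intercept: float
    means: np.ndarray
    sds: np.ndarray
    ridge_used: bool = False
    dropped_genes: list = field(default_factory=list)

    def score(self, expr: pd.DataFrame) -> pd.Series:
        """Linear score (log-odds) for samples x genes log2 expression."""
        Z = (expr[self.genes].to_numpy(float) - self.means) / self.sds
        return pd.Series(Z @ self.coef + self.intercept, index=expr.index, name="score")


def fit_panel_score(expr: pd.DataFrame, labels: ExposureLabels) -> PanelScoreModel:
    """Maximum-likelihood logistic panel score on standardized genes.

    ``expr`` is samples x genes (log2 scale, complete). Zero-variance genes
    are dropped with a warning. A fixed small ridge penalty is engaged
    automatically only when perfect separation is detected (unbounded ML
    fit); the fit is deterministic either way.
    """
    if expr.isna().any().any():
        raise InputDataError("panel expression matrix contains missing values")
    y = labels.high.reindex(expr.index).to_numpy(bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise InputDataError("need at least 2 samples per exposure class")

    means = expr.mean(axis=0).to_numpy(float)
    sds = expr.std(axis=0, ddof=1).to_numpy(float)
    keep = sds > 0
    dropped = [g for g, k in zip(expr.columns, keep) if not k]
    if dropped:
        log.warning("fit_panel_score: dropping zero-variance genes %s", dropped)
    genes = [g for g, k in zip(expr.columns, keep) if k]
    if not genes:
        raise InputDataError("no gene with non-zero variance")
    Z = (expr[genes].to_numpy(float) - means[keep]) / sds[keep]

    def _fit(C):
        # C=inf is the plain maximum-likelihood fit; finite C adds the ridge
        clf = LogisticRegression(C=C, solver="lbfgs", max_iter=5000, tol=1e-10)
        clf.fit(Z, y)
        return clf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf = _fit(np.inf)
    scores = Z @ clf.coef_[0] + clf.intercept_[0]
    separated = (
        scores[y].min() > scores[~y].max() if y.any() and (~y).any() else False
    ) and np.abs(clf.coef_).max() > 15.0
    ridge_used = False
    if separated:
        log.warning("perfect separation detected; refitting with fixed ridge penalty")
        clf = _fit(_RIDGE_C)
        ridge_used = True
    return PanelScoreModel(
        genes=genes,
        coef=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        means=means[keep],
        sds=sds[keep],
        ridge_used=ridge_used,
        dropped_genes=dropped,
    )


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci: tuple = (np.nan, np.nan)
    p_vs_chance: float = np.nan


def roc_auc(scores: pd.Series, labels: ExposureLabels) -> RocResult:
    """ROC curve and AUC via the Mann-Whitney statistic (ties count 1/2)."""
    s = np.asarray(scores, float)
    y = labels.high.reindex(scores.index).to_numpy(bool) if isinstance(scores, pd.Series) else np.asarray(labels.high, bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise InputDataError("both exposure classes must be non-empty")
    r = rankdata(s)
    auc = (r[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    # curve over all thresholds, descending score
    order = np.argsort(-s, kind="mergesort")
    ys = y[order]
    distinct = np.r_[np.diff(s[order]) != 0, True]
    tps = np.cumsum(ys)[distinct]
    fps = np.cumsum(~ys)[distinct]
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n0]
    return RocResult(fpr=fpr, tpr=tpr, auc=float(auc))


def _delong_variance(scores: np.ndarray, y: np.ndarray):
    pos, neg = scores[y], scores[~y]
    m, n = len(pos), len(neg)
    r_all = rankdata(np.concatenate([pos, neg]))
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n  # placement of each positive among negatives
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), s10 / m + s01 / n


def auc_inference(scores: pd.Series, labels: ExposureLabels, n_perm: int = 10000, rng_seed: int = 0):
    """DeLong 95% CI (Wald, truncated to [0, 1]) and two-sided p vs AUC = 0.5.

    With fewer than 5 samples in either class the asymptotic variance is
    unreliable; an exact label-permutation p over at most ``n_perm``
    resamples is used instead and the CI is reported as NaN with a warning.
    """
    s = np.asarray(scores, float)
    y = labels.high.reindex(scores.index).to_numpy(bool) if isinstance(scores, pd.Series) else np.asarray(labels.high, bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    auc, var = _delong_variance(s, y)

    if min(n1, n0) < 5:
        log.warning("tiny class (%d vs %d): permutation p, no asymptotic CI", n1, n0)
        rng = np.random.default_rng(rng_seed)
        obs = abs(auc - 0.5)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(y)
            a, _ = _delong_variance(s, perm)
            if abs(a - 0.5) >= obs - 1e-12:
                hits += 1
        return (np.nan, np.nan), (hits + 1) / (n_perm + 1)

    sd = np.sqrt(var)
    if sd == 0.0:
        ci = (auc, auc)
        p = 1.0 if auc == 0.5 else 0.0
    else:
        half = norm.ppf(0.975) * sd
        ci = (max(0.0, auc - half), min(1.0, auc + half))
        p = float(2.0 * norm.sf(abs(auc - 0.5) / sd))
    return ci, p


def cross_validated_auc(
    expr: pd.DataFrame, labels: ExposureLabels, n_splits: int = 5, rng_seed: int = 0
) -> float:
    """Stratified k-fold out-of-fold AUC for a refitted panel score."""
    y = labels.high.reindex(expr.index).to_numpy(bool)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=rng_seed)
    oof = np.empty(len(y))
    for train, test in skf.split(expr, y):
        sub_labels = ExposureLabels(
            high=labels.high.reindex(expr.index).iloc[train],
            cutoff=labels.cutoff,
            percentile=labels.percentile,
        )
        model = fit_panel_score(expr.iloc[train], sub_labels)
        oof[test] = model.score(expr.iloc[test]).to_numpy()
    r = rankdata(oof)
    n1, n0 = int(y.sum()), int((~y).sum())
    return float((r[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))
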