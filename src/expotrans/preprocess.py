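"""Microarray preprocessing: probe intensities to a filtered gene x sample matrix.

The chain mirrors a standard one-colour array quality-control pipeline:

1. local background correction with flagging of bad spots and spots at or
   below background (``correct_and_flag``);
2. removal of rows with more than a configurable fraction of flagged data
   (``filter_flagged_rows``, default 30%);
3. quantile normalization across samples (``quantile_normalize``), run before
   imputation, with missing entries rank-interpolated against the pooled
   reference distribution;
4. merging replicate spots of the same probe by the per-sample median
   (``merge_replicate_probes``);
5. K-nearest-neighbour imputation of remaining missing values, K = 15 by
   default, gene-wise with distances over shared observed samples
   (``knn_impute``);
6. a flat-pattern filter removing rows whose mean-centred root-mean-square
   variation is below 0.25 log2 units (``flat_filter``);
7. selection of one probe per gene by highest interquartile range
   (``select_row_per_gene``).

Filter stages only delete rows; they never alter retained values. Boundary
conventions (strict comparisons, tie-breaks) are fixed and tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InputDataError
from .simulate import ProbeIntensityMatrix

log = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    flag_fraction_threshold: float = 0.30
    knn_k: int = 15
    flat_rms_threshold: float = 0.25
    #: diagnostic switch; quantile normalization is part of the default chain
    quantile_normalization: bool = True

    def validate(self) -> None:
        if not 0.0 < self.flag_fraction_threshold < 1.0:
            raise InputDataError("flag_fraction_threshold must lie in (0, 1)")
        if self.knn_k < 1:
            raise InputDataError("knn_k must be >= 1")
        if self.flat_rms_threshold < 0:
            raise InputDataError("flat_rms_threshold must be >= 0")


def correct_and_flag(raw: ProbeIntensityMatrix) -> pd.DataFrame:
    """log2(foreground - background) where the spot is usable, else missing.

    A cell is missing when it is flagged or when the background-corrected
    intensity is <= 0 (at or below background; log2 undefined).
    """
    fg = raw.foreground.to_numpy(float)
    bg = raw.background.to_numpy(float)
    if (fg < 0).any() or (bg < 0).any():
        raise InputDataError("negative intensities in probe matrix")
    net = fg - bg
    ok = (net > 0) & ~raw.flags.to_numpy(bool)
    values = np.where(ok, net, np.nan)
    with np.errstate(invalid="ignore"):
        values = np.log2(values)
    return pd.DataFrame(values, index=raw.foreground.index, columns=raw.foreground.columns)


def filter_flagged_rows(m: pd.DataFrame, threshold: float = 0.30) -> pd.DataFrame:
    """Drop rows whose missing fraction is strictly greater than ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise InputDataError("threshold must lie in (0, 1)")
    frac = m.isna().mean(axis=1)
    return m.loc[frac <= threshold]


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the pooled reference distribution, rank-preserving.

    The reference is the mean across columns of each column's empirical
    quantile function on a common grid of ``n_rows`` probabilities; with
    complete data this is exactly the classic sort / row-mean / unsort
    algorithm. Columns with missing entries are rank-interpolated over their
    observed values; tied values receive the mean of the reference values at
    their tied ranks.
    """
    if m.shape[1] < 2:
        raise InputDataError("quantile normalization needs at least 2 samples")
    X = m.to_numpy(float)
    n_rows = X.shape[0]
    grid = np.linspace(0.0, 1.0, n_rows) if n_rows > 1 else np.array([0.5])
    cols_q = []
    for j in range(X.shape[1]):
        obs = X[~np.isnan(X[:, j]), j]
        if obs.size == 0:
            raise InputDataError(f"column {m.columns[j]!r} is entirely missing")
        cols_q.append(np.quantile(obs, grid))
    ref = np.mean(cols_q, axis=0)

    out = np.full_like(X, np.nan)
    for j in range(X.shape[1]):
        mask = ~np.isnan(X[:, j])
        obs = X[mask, j]
        if obs.size == 1:
            out[mask, j] = np.interp(0.5, grid, ref)
            continue
        pos = (rankdata(obs, method="average") - 1.0) / (obs.size - 1.0)
        out[mask, j] = np.interp(pos, grid, ref)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def merge_replicate_probes(m: pd.DataFrame, probe_map: dict) -> pd.DataFrame:
    """Collapse replicate rows to one row per group via the per-sample median.

    ``probe_map`` maps group id (probe or gene) to the list of member row ids.
    The median skips missing values; an all-missing cell stays missing. For a
    group of even size the median is the mean of the two central values.
    """
    rows = []
    for group, members in probe_map.items():
        members = list(members)
        if not members:
            raise InputDataError(f"probe group {group!r} is empty")
        missing = [p for p in members if p not in m.index]
        if missing:
            raise InputDataError(f"probe group {group!r}: rows not in matrix: {missing}")
        rows.append(m.loc[members].median(axis=0, skipna=True))
    out = pd.DataFrame(rows, index=pd.Index(list(probe_map), name=m.index.name))
    out.columns = m.columns
    return out


def knn_impute(m: pd.DataFrame, k: int = 15) -> pd.DataFrame:
    """Gene-wise K-nearest-neighbour imputation.

    The distance between two rows is the Euclidean distance over samples
    observed in both, divided by the square root of the number of shared
    samples; neighbours must have the target sample observed. The imputed
    value is the unweighted mean over the k nearest eligible rows (all of
    them, with a warning, when fewer than k exist). Observed values are never
    altered.
    """
    if k < 1:
        raise InputDataError("k must be >= 1")
    X = m.to_numpy(float)
    obs = ~np.isnan(X)
    if not obs.any(axis=1).all():
        bad = m.index[~obs.any(axis=1)].tolist()
        raise InputDataError(f"rows entirely missing, cannot impute: {bad}")
    if not np.isnan(X).any():
        return m.copy()

    O = obs.astype(float)
    Xz = np.where(obs, X, 0.0)
    S2 = Xz ** 2
    cross = Xz @ Xz.T
    d2 = S2 @ O.T + O @ S2.T - 2.0 * cross
    nshared = O @ O.T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.sqrt(np.maximum(d2, 0.0) / nshared)
    dist[nshared == 0] = np.inf

    out = X.copy()
    n_rows = X.shape[0]
    warned = False
    for g in range(n_rows):
        missing_cols = np.nonzero(~obs[g])[0]
        if missing_cols.size == 0:
            continue
        order = np.lexsort((np.arange(n_rows), dist[g]))
        for s in missing_cols:
            eligible = order[(order != g) & obs[order, s] & np.isfinite(dist[g, order])]
            if eligible.size == 0:
                raise InputDataError(
                    f"no eligible neighbour for row {m.index[g]!r}, sample {m.columns[s]!r}"
                )
            if eligible.size < k and not warned:
                log.warning(
                    "knn_impute: only %d eligible neighbours (< k=%d); using all",
                    eligible.size,
                    k,
                )
                warned = True
            out[g, s] = X[eligible[:k], s].mean()
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def flat_filter(m: pd.DataFrame, rms_threshold: float = 0.25) -> pd.DataFrame:
    """Drop rows whose mean-centred RMS is strictly below the threshold."""
    if m.isna().any().any():
        raise InputDataError("flat_filter requires a complete matrix")
    X = m.to_numpy(float)
    centred = X - X.mean(axis=1, keepdims=True)
    rms = np.sqrt((centred ** 2).mean(axis=1))
    return m.loc[rms >= rms_threshold]


def select_row_per_gene(m: pd.DataFrame, annotation: dict) -> pd.DataFrame:
    """Keep, per gene, the row with the highest interquartile range.

    ``annotation`` maps row id to gene id; unannotated rows are dropped with a
    warning. IQR is Q3 - Q1 with linear-interpolation quantiles; ties go to
    the lexicographically smallest row id.
    """
    unannotated = [r for r in m.index if r not in annotation]
    if unannotated:
        log.warning("select_row_per_gene: dropping %d unannotated rows", len(unannotated))
    rows = [r for r in m.index if r in annotation]
    X = m.loc[rows].to_numpy(float)
    q1, q3 = np.nanpercentile(X, [25, 75], axis=1)
    iqr = dict(zip(rows, q3 - q1))

    best: dict = {}
    order: list = []
    for r in rows:
        gene = annotation[r]
        if gene not in best:
            best[gene] = r
            order.append(gene)
        else:
            cur = best[gene]
            if (iqr[r] > iqr[cur]) or (iqr[r] == iqr[cur] and str(r) < str(cur)):
                best[gene] = r
    out = m.loc[[best[g] for g in order]].copy()
    out.index = pd.Index(order, name="id")
    return out


def run_preprocessing(
    raw: ProbeIntensityMatrix,
    annotation: pd.DataFrame,
    params: PreprocessParams | None = None,
):
    """Full chain from probe intensities to one complete row per gene.

    ``annotation`` needs columns spot_id, probe_id, gene_id. Returns the gene
    matrix and a list of ``(stage, n_rows)`` pairs for the audit trail.
    """
    params = params or PreprocessParams()
    params.validate()
    probe_groups: dict = {}
    for spot, probe in zip(annotation["spot_id"], annotation["probe_id"]):
        probe_groups.setdefault(probe, []).append(spot)
    probe_to_gene = dict(zip(annotation["probe_id"], annotation["gene_id"]))

    stages = []
    m = correct_and_flag(raw)
    stages.append(("correct_and_flag", len(m)))
    m = filter_flagged_rows(m, params.flag_fraction_threshold)
    stages.append(("filter_flagged_rows", len(m)))
    if params.quantile_normalization:
        m = quantile_normalize(m)
        stages.append(("quantile_normalize", len(m)))
    groups = {p: [s for s in spots if s in m.index] for p, spots in probe_groups.items()}
    groups = {p: spots for p, spots in groups.items() if spots}
    m = merge_replicate_probes(m, groups)
    stages.append(("merge_replicate_probes", len(m)))
    m = knn_impute(m, params.knn_k)
    stages.append(("knn_impute", len(m)))
    m = flat_filter(m, params.flat_rms_threshold)
    stages.append(("flat_filter", len(m)))
    m = select_row_per_gene(m, probe_to_gene)
    stages.append(("select_row_per_gene", len(m)))
    for stage, n in stages:
        log.info("preprocess %-22s rows=%d", stage, n)
    return m, stages
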