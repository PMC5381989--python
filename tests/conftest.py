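import numpy as np
import pandas as pd
import pytest

from expotrans import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """60 men / 60 women discovery cohort used by regression tests."""
    cfg = simulate.SimulationConfig(n_men=60, n_women=60, seed=7)
    return simulate.generate_cohort(cfg)


@pytest.fixture
def random_matrix(rng):
    """Continuous-valued 20x10 matrix (ties almost surely absent)."""
    values = rng.normal(8.0, 1.0, size=(20, 10))
    return pd.DataFrame(
        values,
        index=[f"P{i:02d}" for i in range(20)],
        columns=[f"S{j:02d}" for j in range(10)],
    )


def brute_force_quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Independent oracle: sort each column, take row means, unsort by rank.

    Only valid for complete matrices without ties.
    """
    X = df.to_numpy(float)
    order = np.argsort(X, axis=0)
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[order[:, j], j] = ref
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def brute_force_knn_impute(df: pd.DataFrame, k: int) -> pd.DataFrame:
    """Independent oracle: exhaustive per-cell neighbour ranking with loops."""
    X = df.to_numpy(float)
    n_rows, n_cols = X.shape
    out = X.copy()
    for g in range(n_rows):
        for s in range(n_cols):
            if not np.isnan(X[g, s]):
                continue
            dists = []
            for j in range(n_rows):
                if j == g or np.isnan(X[j, s]):
                    continue
                shared = [
                    t
                    for t in range(n_cols)
                    if not np.isnan(X[g, t]) and not np.isnan(X[j, t])
                ]
                if not shared:
                    continue
                d = np.sqrt(
                    sum((X[g, t] - X[j, t]) ** 2 for t in shared) / len(shared)
                )
                dists.append((d, j))
            dists.sort(key=lambda pair: (pair[0], pair[1]))
            neigh = [j for _, j in dists[:k]]
            out[g, s] = np.mean([X[j, s] for j in neigh])
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def brute_force_bh(p):
    """Step-up definition applied literally."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, m * p[i] / (pos + 1))
        q[i] = min(running, 1.0)
    return q


def brute_force_signed_rank_p(values):
    """Exact two-sided p by enumerating all 2^n sign assignments."""
    from itertools import product

    from scipy.stats import rankdata

    v = np.asarray(values, float)
    v = v[v != 0]
    n = len(v)
    ranks = rankdata(np.abs(v))
    w_obs = ranks[v > 0].sum()
    mu = n * (n + 1) / 4.0
    dev = abs(w_obs - mu)
    count = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= dev - 1e-9:
            count += 1
    return count / 2 ** n


def brute_force_auc(scores, labels_bool):
    """Concordant-pair count with ties worth one half."""
    pos = [s for s, l in zip(scores, labels_bool) if l]
    neg = [s for s, l in zip(scores, labels_bool) if not l]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))
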