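"""Fold-change-based gene-set enrichment via the Wilcoxon signed-rank test.

For every gene set, the member genes' log2 fold changes (taken from the
per-gene association table, without any significance preselection) are tested
against the null hypothesis that they are distributed symmetrically around
zero. Sets are restricted to those with between 5 and 100 measured members
and p-values are Benjamini-Hochberg adjusted across the retained sets.

The signed-rank p-value is exact (full null enumeration via a convolution
over sign assignments, midranks for ties) for up to 25 non-zero members and
uses the tie-corrected, continuity-corrected normal approximation above that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import InputDataError
from .regression import bh_adjust

log = logging.getLogger(__name__)

EXACT_LIMIT = 25


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple

    def __post_init__(self):
        if not self.members:
            raise InputDataError(f"gene set {self.name!r} has no members")


def read_gmt(path) -> list:
    """Parse a GMT file: ``name <tab> description <tab> member...`` per line.

    Duplicate members within a line are dropped with a warning; a line with
    fewer than three fields raises an error naming the line number.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputDataError(f"malformed GMT line {lineno}: fewer than 3 fields")
            name, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            unique = tuple(dict.fromkeys(members))
            if len(unique) < len(members):
                log.warning("GMT set %r line %d: duplicate members dropped", name, lineno)
            sets.append(GeneSet(name, desc, unique))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def wilcoxon_set_test(member_log2fcs) -> float:
    """Two-sided signed-rank p that the values are symmetric about zero.

    Exact zeros are dropped before ranking (standard signed-rank convention);
    ties among absolute values share midranks. With no non-zero value left
    the test is degenerate and returns p = 1 with a warning.
    """
    v = np.asarray(member_log2fcs, float)
    if v.size == 0:
        raise InputDataError("empty fold-change vector")
    v = v[v != 0.0]
    if v.size == 0:
        log.warning("wilcoxon_set_test: all values exactly zero; degenerate p = 1")
        return 1.0
    n = v.size
    ranks = rankdata(np.abs(v))
    w = float(ranks[v > 0].sum())
    mu = n * (n + 1) / 4.0

    if n <= EXACT_LIMIT:
        # integer convolution over doubled midranks
        r2 = np.rint(2.0 * ranks).astype(int)
        total = int(r2.sum())
        pmf = np.zeros(total + 1)
        pmf[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(pmf)
            shifted[r:] = pmf[: total + 1 - r]
            pmf = pmf + shifted
        pmf /= 2.0 ** n
        # doubled statistic 2w has support 0..total with centre total/2 = 2*mu
        sums = np.arange(total + 1)
        dev = abs(2.0 * w - total / 2.0)
        p = float(pmf[np.abs(sums - total / 2.0) >= dev - 1e-9].sum())
        return min(1.0, p)

    # normal approximation with tie correction and continuity correction
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts.astype(float) ** 3 - counts).sum())) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return 1.0
    diff = w - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var) if diff != 0 else 0.0
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def enrich(
    fc_table: dict,
    sets,
    size_min: int = 5,
    size_max: int = 100,
) -> pd.DataFrame:
    """Per-set signed-rank enrichment over a gene -> log2FC mapping.

    Sets are filtered on the number of *measured* members (present in
    ``fc_table``); retained sets get a signed-rank p and a BH q across the
    retained family, sorted by ascending q then name.
    """
    if not fc_table:
        raise InputDataError("empty fold-change table")
    rows = []
    for s in sets:
        measured = [g for g in s.members if g in fc_table]
        if not size_min <= len(measured) <= size_max:
            continue
        p = wilcoxon_set_test([fc_table[g] for g in measured])
        rows.append(
            {
                "set": s.name,
                "n_measured": len(measured),
                "n_total": len(s.members),
                "p": p,
            }
        )
    if not rows:
        log.warning("enrich: no gene set within the size window [%d, %d]", size_min, size_max)
        return pd.DataFrame(columns=["set", "n_measured", "n_total", "p", "q"])
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["q", "set"], kind="mergesort").reset_index(drop=True)
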