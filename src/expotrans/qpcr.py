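"""Efficiency-corrected, multi-reference-gene qPCR quantification.

Triplicate Cq values per sample x assay are collapsed under a concordance
rule (replicates deviating >= 0.5 cycles from the triplicate median are
excluded; at least two concordant replicates are required), converted to
relative quantities ``RQ = E**(calibrator_cq - cq)`` with the per-assay mean
Cq across samples as calibrator, and normalized by the geometric mean of
three reference-gene relative quantities (the normalization factor NF):
``NRQ = RQ / NF``. ``log2 NRQ`` is the response fed to the validation
regression; the calibrator choice only shifts it by a per-assay constant and
cannot affect regression slopes.

Amplification efficiencies are accepted as percent (90-110) in input files
and converted to fold-per-cycle ``E = 1 + percent/100``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InputDataError

log = logging.getLogger(__name__)

REPLICATE_TOLERANCE = 0.5  # cycles
CQ_RANGE = (10.0, 40.0)


def collapse_replicates(cq_values, tol: float = REPLICATE_TOLERANCE):
    """Mean Cq of the concordant replicates, or None when fewer than 2 remain.

    Replicates whose deviation from the triplicate median is >= ``tol`` are
    excluded. Returns ``(mean_cq, n_used)``; ``(None, n_used)`` marks the
    well missing.
    """
    v = np.asarray(cq_values, float)
    if v.size != 3:
        raise InputDataError(f"expected 3 replicate Cq values, got {v.size}")
    med = float(np.median(v))
    keep = np.abs(v - med) < tol
    if keep.sum() < 2:
        return None, int(keep.sum())
    return float(v[keep].mean()), int(keep.sum())


def relative_quantity(cq: float, efficiency: float, calibrator_cq: float) -> float:
    """``RQ = E**(calibrator_cq - cq)``; one cycle below calibrator doubles RQ at E=2."""
    if efficiency <= 1.0:
        raise InputDataError("amplification efficiency must exceed 1 fold per cycle")
    return float(efficiency ** (calibrator_cq - cq))


def normalization_factor(ref_rqs) -> float:
    """Geometric mean of the reference-gene relative quantities for a sample."""
    v = np.asarray([r for r in ref_rqs if r is not None and np.isfinite(r)], float)
    if (v <= 0).any():
        raise InputDataError("reference relative quantities must be positive")
    if v.size < 2:
        raise InputDataError("need at least 2 reference genes for the normalization factor")
    return float(np.exp(np.log(v).mean()))


def normalize(rq: float, nf: float):
    """``NRQ = RQ / NF`` and its log2."""
    if nf <= 0:
        raise InputDataError("normalization factor must be positive")
    nrq = rq / nf
    return float(nrq), float(np.log2(nrq))


def _efficiency_from_percent(pct: float) -> float:
    e = 1.0 + pct / 100.0
    if not 1.9 <= e <= 2.1:
        raise InputDataError(
            f"amplification efficiency {pct}% outside the accepted 90-110% band"
        )
    return e


def process_cq_table(
    cq: pd.DataFrame, reference_genes, tol: float = REPLICATE_TOLERANCE
) -> pd.DataFrame:
    """Full chain: collapse triplicates, calibrate, reference-normalize.

    ``cq`` columns: sample_id, assay_id, rep1..rep3, efficiency_percent.
    Returns one row per retained sample x assay with rq, nf, nrq, log2_nrq
    and replicates_used. Samples with fewer than two usable reference genes
    are dropped with a warning.
    """
    reference_genes = list(reference_genes)
    required = {"sample_id", "assay_id", "rep1", "rep2", "rep3", "efficiency_percent"}
    missing_cols = required - set(cq.columns)
    if missing_cols:
        raise InputDataError(f"Cq table missing columns: {sorted(missing_cols)}")

    wells = []
    for _, row in cq.iterrows():
        mean_cq, n_used = collapse_replicates(
            [row["rep1"], row["rep2"], row["rep3"]], tol=tol
        )
        if mean_cq is None:
            log.warning(
                "discordant triplicate dropped: sample %s assay %s",
                row["sample_id"],
                row["assay_id"],
            )
        wells.append(
            {
                "sample_id": row["sample_id"],
                "assay_id": row["assay_id"],
                "efficiency": _efficiency_from_percent(float(row["efficiency_percent"])),
                "cq": mean_cq,
                "replicates_used": n_used,
            }
        )
    wells = pd.DataFrame(wells)

    # per-assay calibrator: mean collapsed Cq across samples
    calibrator = wells.dropna(subset=["cq"]).groupby("assay_id")["cq"].mean()
    wells["rq"] = [
        relative_quantity(row.cq, row.efficiency, calibrator[row.assay_id])
        if pd.notna(row.cq)
        else np.nan
        for row in wells.itertuples()
    ]

    # per-sample normalization factor from the reference assays
    nf_by_sample = {}
    for sid, grp in wells.groupby("sample_id"):
        refs = grp[grp["assay_id"].isin(reference_genes)].dropna(subset=["rq"])
        if len(refs) < len(reference_genes):
            log.warning("sample %s: only %d reference genes usable", sid, len(refs))
        if len(refs) < 2:
            log.warning("sample %s dropped: fewer than 2 reference genes", sid)
            continue
        nf_by_sample[sid] = normalization_factor(refs["rq"].to_numpy())

    wells["nf"] = wells["sample_id"].map(nf_by_sample)
    wells = wells[wells["nf"].notna() & wells["rq"].notna()].copy()
    wells["nrq"] = wells["rq"] / wells["nf"]
    wells["log2_nrq"] = np.log2(wells["nrq"])
    return wells[
        ["sample_id", "assay_id", "rq", "nf", "nrq", "log2_nrq", "replicates_used"]
    ].reset_index(drop=True)


def nrq_matrix(processed: pd.DataFrame, assays=None) -> pd.DataFrame:
    """Pivot processed wells to an assay x sample matrix of log2 NRQ."""
    wide = processed.pivot(index="assay_id", columns="sample_id", values="log2_nrq")
    if assays is not None:
        wide = wide.loc[[a for a in assays if a in wide.index]]
    wide.index.name = "id"
    return wide
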