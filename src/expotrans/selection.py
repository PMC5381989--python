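"""Meet-in-the-middle candidate selection and cross-cohort concordance.

The biomarker funnel intersects exposure-associated genes with
disease-associated genes: per sex, take the top-k genes by uncorrected
p-value from the discovery association table, keep those with a literature
link to an air-pollution-related disease (a controlled eight-term
vocabulary), and form a fixed-size candidate panel (default 8) from the
lowest-p annotated genes. Validation results are then judged per gene:
confirmed (significant, same direction as discovery), opposite_direction
(significant, direction flipped) or not_significant, with a borderline flag
for p just above the significance cut.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputDataError

log = logging.getLogger(__name__)

DISEASE_VOCABULARY = frozenset(
    {"allergy", "COPD", "asthma", "lung cancer", "CVD", "CeVD", "Alzheimer", "cognition"}
)


def read_disease_annotation(path) -> dict:
    """Gene -> disease-tag tuple from a TSV with columns gene_id, tags[, note].

    Tags are semicolon-separated and must come from the controlled vocabulary.
    """
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, row in df.iterrows():
        tags = tuple(t.strip() for t in str(row["tags"]).split(";") if t.strip())
        bad = set(tags) - DISEASE_VOCABULARY
        if bad:
            raise InputDataError(
                f"gene {row['gene_id']!r}: tags outside vocabulary: {sorted(bad)}"
            )
        out[str(row["gene_id"])] = tags
    return out


def bundled_annotation_path():
    """Path to the packaged example candidate-gene disease annotation."""
    return importlib.resources.files("expotrans.data") / "ap_disease_annotation.tsv"


def bundled_panels() -> pd.DataFrame:
    """Packaged example eight-gene panels with published discovery/validation
    fold changes per 5 ug/m3 and p-values (printed-input fixture)."""
    path = importlib.resources.files("expotrans.data") / "biomarker_panels.tsv"
    return pd.read_csv(path, sep="\t")


def top_k(results: pd.DataFrame, k: int = 50) -> pd.DataFrame:
    """First k genes of a ranked association table (ascending p).

    With fewer than k genes, all are returned with a warning.
    """
    ranked = results.sort_values("rank", kind="mergesort")
    if len(ranked) < k:
        log.warning("top_k: only %d genes available (k=%d); returning all", len(ranked), k)
        return ranked.reset_index(drop=True)
    return ranked.head(k).reset_index(drop=True)


@dataclass
class CandidatePanel:
    sex: str
    table: pd.DataFrame  # gene, fc5, p, rank, tags

    @property
    def genes(self) -> list:
        return self.table["gene"].tolist()


def select_panel(
    top: pd.DataFrame, annotation: dict, panel_size: int = 8, sex: str = ""
) -> CandidatePanel:
    """The ``panel_size`` disease-annotated genes with the smallest p-values.

    Raises when the top list contains fewer annotated genes than the panel
    needs, naming the shortfall.
    """
    annotated = top[top["gene"].isin(annotation)].copy()
    if len(annotated) < panel_size:
        raise InputDataError(
            f"only {len(annotated)} annotated genes in top list; "
            f"{panel_size - len(annotated)} short of panel size {panel_size}"
        )
    panel = annotated.sort_values("rank", kind="mergesort").head(panel_size).copy()
    panel["tags"] = [";".join(annotation[g]) for g in panel["gene"]]
    return CandidatePanel(sex=sex, table=panel.reset_index(drop=True))


@dataclass
class ConcordanceVerdict:
    gene: str
    status: str  # confirmed | opposite_direction | not_significant
    discovery_direction: str  # up | down | flat
    validation_direction: str
    validation_p: float
    borderline: bool


def _direction(fc5: float) -> str:
    if fc5 > 1.0:
        return "up"
    if fc5 < 1.0:
        return "down"
    return "flat"


def assess_concordance(
    gene: str,
    disc_fc5: float,
    val_fc5: float,
    val_p: float,
    alpha: float = 0.05,
    borderline: float = 0.10,
) -> ConcordanceVerdict:
    """Judge one gene's validation outcome against its discovery direction.

    confirmed: validation p < alpha and directions agree;
    opposite_direction: validation p < alpha and directions disagree;
    otherwise not_significant. A borderline flag marks
    alpha <= p < borderline; it never upgrades the verdict. A fold change of
    exactly 1 has no direction and yields not_significant with a warning.
    """
    d_disc = _direction(disc_fc5)
    d_val = _direction(val_fc5)
    flag = alpha <= val_p < borderline
    if d_disc == "flat" or d_val == "flat":
        log.warning("assess_concordance %s: fold change exactly 1; direction undefined", gene)
        return ConcordanceVerdict(gene, "not_significant", d_disc, d_val, val_p, flag)
    if val_p < alpha:
        status = "confirmed" if d_disc == d_val else "opposite_direction"
    else:
        status = "not_significant"
    return ConcordanceVerdict(gene, status, d_disc, d_val, val_p, flag)


def concordance_table(
    discovery: pd.DataFrame,
    validation: pd.DataFrame,
    alpha: float = 0.05,
    borderline: float = 0.10,
) -> pd.DataFrame:
    """Vectorised concordance report for genes present in both tables."""
    disc = discovery.set_index("gene")
    val = validation.set_index("gene")
    genes = [g for g in disc.index if g in val.index]
    rows = []
    for g in genes:
        v = assess_concordance(
            g,
            float(disc.loc[g, "fc5"]),
            float(val.loc[g, "fc5"]),
            float(val.loc[g, "p"]),
            alpha=alpha,
            borderline=borderline,
        )
        rows.append(
            {
                "gene": g,
                "status": v.status,
                "discovery_fc5": float(disc.loc[g, "fc5"]),
                "validation_fc5": float(val.loc[g, "fc5"]),
                "discovery_direction": v.discovery_direction,
                "validation_direction": v.validation_direction,
                "validation_p": v.validation_p,
                "borderline": v.borderline,
            }
        )
    return pd.DataFrame(rows)
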