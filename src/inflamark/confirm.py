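"""Literature confirmation scoring and the final biomarker report.

Each verified marker carries three curated literature conditions:
(i) a mechanistic rationale linking the marker to the tissue,
(ii) association with tissue-specific diseases (e.g. steatosis, obesity),
(iii) association with one or more metabolic disorders.
The confirmation level is 3 (confirmed) when all three hold, 2 (putative)
for any two, 1 (possible) when exactly one of (i)/(ii) holds, and 0 (not
confirmed) when none holds or only (iii) holds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .verify import ADIPOSE, BOTH, HEPATIC

LEVEL_UNKNOWN = -1
_TISSUE_ORDER = {HEPATIC: 0, ADIPOSE: 1, BOTH: 2}


def assign_confirmation_level(cond_mechanism: bool, cond_tissue_disease: bool, cond_metabolic: bool) -> int:
    """Confirmation level 0-3 from the three literature conditions."""
    n = int(cond_mechanism) + int(cond_tissue_disease) + int(cond_metabolic)
    if n == 3:
        return 3
    if n == 2:
        return 2
    if n == 1:
        return 1 if (cond_mechanism or cond_tissue_disease) else 0
    return 0


@dataclass(frozen=True)
class EvidenceRecord:
    """Curated literature evidence for one marker in one tissue."""

    gene: str
    tissue: str
    cond_mechanism: bool
    cond_tissue_disease: bool
    cond_metabolic: bool
    notes: str = ""

    @property
    def level(self) -> int:
        return assign_confirmation_level(
            self.cond_mechanism, self.cond_tissue_disease, self.cond_metabolic
        )


def tally_levels(levels: Sequence[int]) -> dict[int, int]:
    """Counts per confirmation level; always reports all four levels."""
    tally = {0: 0, 1: 0, 2: 0, 3: 0}
    for lv in levels:
        if lv not in tally:
            raise ValidationError(f"confirmation level must be 0-3, got {lv}")
        tally[lv] += 1
    return tally


def final_biomarker_report(
    classified: pd.DataFrame,
    evidence: Sequence[EvidenceRecord],
    function_categories: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Join tissue-classified markers with literature evidence.

    ``classified`` is the output of :func:`inflamark.verify.classify_markers`
    restricted to verified candidates. Rows with label "none" are dropped;
    "both" rows are kept in their own section after the per-tissue sections.
    A verified marker without an evidence record is reported with level
    ``-1`` (unknown), never dropped.
    """
    function_categories = {
        k.upper(): v for k, v in (function_categories or {}).items()
    }
    ev_by_gene: dict[str, EvidenceRecord] = {}
    for rec in evidence:
        ev_by_gene[rec.gene.upper()] = rec
    rows = []
    for gene, row in classified.iterrows():
        label = row["label"]
        if label not in _TISSUE_ORDER:
            continue
        rec = ev_by_gene.get(str(gene).upper())
        rho = row["rho_liver"] if label == HEPATIC else row["rho_wat"]
        if label == BOTH:
            rho = row["rho_liver"]
        rows.append(
            {
                "gene": str(gene).upper(),
                "tissue": label,
                "rho": rho,
                "rho_liver": row["rho_liver"],
                "rho_wat": row["rho_wat"],
                "level": rec.level if rec is not None else LEVEL_UNKNOWN,
                "function_category": function_categories.get(str(gene).upper(), ""),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["gene", "tissue", "rho", "rho_liver", "rho_wat", "level", "function_category"],
    )
    if len(frame):
        frame = frame.sort_values(
            by=["tissue", "gene"], key=lambda c: c.map(_TISSUE_ORDER) if c.name == "tissue" else c
        ).reset_index(drop=True)
    return frame


def marker_counts_by_tissue(report: pd.DataFrame) -> dict[str, int]:
    """Number of reported markers per tissue assignment."""
    out = {HEPATIC: 0, ADIPOSE: 0, BOTH: 0}
    for label in report["tissue"]:
        out[label] = out.get(label, 0) + 1
    return out
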