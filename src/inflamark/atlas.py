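"""Tissue-specificity classification of genes from a cross-tissue
expression atlas, and the unique immune-gene additions it contributes on
top of the ontology-derived gene sets.

A gene is *tissue-enriched* when its expression in one tissue is at least
``fold`` (default 4) times the level in every other tissue, and
*group-enriched* when a group of 2–5 tissues jointly clears the same bar
against all remaining tissues. Everything else is *not-specific*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import math

from .errors import ValidationError

TISSUE_ENRICHED = "tissue-enriched"
GROUP_ENRICHED = "group-enriched"
NOT_SPECIFIC = "not-specific"


@dataclass(frozen=True)
class TissueProfile:
    """Per-gene expression level (TPM-like, >= 0) across >= 2 tissues."""

    gene: str
    levels: Mapping[str, float] = field(default_factory=dict)
    uniprot: str | None = None

    def __post_init__(self):
        if len(self.levels) < 2:
            raise ValidationError(f"{self.gene}: profile needs >= 2 tissues")
        for tissue, level in self.levels.items():
            if not math.isfinite(level) or level < 0:
                raise ValidationError(
                    f"{self.gene}: level for {tissue!r} must be finite and >= 0, got {level}"
                )


@dataclass(frozen=True)
class SpecificityCall:
    """Classification of one gene; ``tissues`` is the enriched set (sorted)."""

    gene: str
    category: str
    tissues: tuple = ()

    def __post_init__(self):
        if self.category == TISSUE_ENRICHED and len(self.tissues) != 1:
            raise ValidationError("tissue-enriched call must name exactly one tissue")
        if self.category == GROUP_ENRICHED and not 2 <= len(self.tissues) <= 5:
            raise ValidationError("group-enriched call must name 2-5 tissues")
        if self.category == NOT_SPECIFIC and self.tissues:
            raise ValidationError("not-specific call must name no tissues")


def classify_gene_specificity(
    profile: TissueProfile,
    fold: float = 4.0,
    group_range: tuple[int, int] = (2, 5),
    denominator: str = "max",
) -> SpecificityCall:
    """Classify one expression profile.

    Tissues are sorted by descending level (name breaks ties); the single top
    tissue, then the smallest descending-prefix group of ``group_range``
    size, is tested against the non-member tissues. ``denominator`` selects
    the comparison level among the non-members: their maximum (strict rule,
    default) or their mean. The fold bar is inclusive ("at least").
    """
    if fold <= 1.0:
        raise ValidationError(f"fold must exceed 1, got {fold}")
    items = sorted(profile.levels.items(), key=lambda kv: (-kv[1], kv[0]))
    tissues = [t for t, _ in items]
    levels = [v for _, v in items]
    n = len(levels)
    if levels[0] <= 0.0:  # all-zero profile: nothing to divide by
        return SpecificityCall(profile.gene, NOT_SPECIFIC)

    def rest_level(k: int) -> float:
        rest = levels[k:]
        return max(rest) if denominator == "max" else sum(rest) / len(rest)

    if n >= 2 and levels[0] >= fold * rest_level(1):
        return SpecificityCall(profile.gene, TISSUE_ENRICHED, (tissues[0],))
    lo, hi = group_range
    for g in range(lo, min(hi, n - 1) + 1):
        if min(levels[:g]) > 0 and min(levels[:g]) >= fold * rest_level(g):
            return SpecificityCall(profile.gene, GROUP_ENRICHED, tuple(sorted(tissues[:g])))
    return SpecificityCall(profile.gene, NOT_SPECIFIC)


def classify_atlas(
    profiles: Iterable[TissueProfile],
    fold: float = 4.0,
    group_range: tuple[int, int] = (2, 5),
    denominator: str = "max",
) -> list[SpecificityCall]:
    return [
        classify_gene_specificity(p, fold=fold, group_range=group_range, denominator=denominator)
        for p in profiles
    ]


def atlas_tissue_specific_genes(
    profiles: Sequence[TissueProfile],
    tissue: str,
    fold: float = 4.0,
    group_range: tuple[int, int] = (2, 5),
    denominator: str = "max",
) -> set[str]:
    """Genes whose specificity call includes ``tissue`` in its enriched set."""
    known = set()
    for p in profiles:
        known |= set(p.levels)
    if tissue not in known:
        raise ValidationError(f"unknown atlas tissue {tissue!r}; have {sorted(known)}")
    calls = classify_atlas(profiles, fold=fold, group_range=group_range, denominator=denominator)
    return {c.gene.upper() for c in calls if tissue in c.tissues}


def unique_hpa_additions(
    atlas_genes: set[str], go_genes: set[str], immune_genes: set[str]
) -> set[str]:
    """Immune-related atlas-specific genes not already selected via ontology:
    ``(atlas ∩ immune) \\ go``. Symbols are upper-cased before set algebra."""
    up = lambda s: {g.upper() for g in s}
    return (up(atlas_genes) & up(immune_genes)) - up(go_genes)
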