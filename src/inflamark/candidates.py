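"""Candidate biomarker selection: filter tissue genes against a blood
protein-biomarker database, apply the novelty rubric, and assemble the
per-parent candidate table.

A gene qualifies as a candidate blood biomarker when the database holds at
least one record typed ``proteome`` with substrate plasma or serum and
evidence from human studies (early, late, or recommended/approved). The
novelty rubric asks three questions of a gene's qualifying records:
(i) described in a low-grade-inflammation related disease, (ii) commonly
analyzed in adults, (iii) used diagnostically in those diseases — a "no" to
any one marks the candidate potentially novel; three times "yes" marks it
curated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .config import (
    DEFAULT_ACCEPTED_EVIDENCE,
    DEFAULT_DISEASES,
    DEFAULT_SUBSTRATES,
)
from .errors import ValidationError
from .ontology import TermGeneSet

NOVEL = "novel"
CURATED = "curated"


@dataclass(frozen=True)
class BiomarkerRecord:
    """One record of the blood-biomarker knowledgebase."""

    gene: str
    uniprot: str | None
    marker_type: str
    substrate: str
    evidence: str
    conditions: frozenset = frozenset()
    commonly_analyzed: bool = False
    diagnostic_use: bool = False


@dataclass(frozen=True)
class CandidateBiomarker:
    """A selected candidate with its provenance.

    ``source_parents`` lists the ontology parents it came from (empty for
    atlas-only genes); ``hpa_specific`` marks genes that are tissue-specific
    in the expression atlas; ``immune`` marks membership of the
    immune-process gene set (carried as information — ontology-derived
    candidates are admitted per parent-term overlap, not per gene).
    """

    gene: str
    tissue: str
    source_parents: tuple = ()
    hpa_specific: bool = False
    immune: bool = False
    novelty: str = NOVEL

    def __post_init__(self):
        if not (self.source_parents or self.hpa_specific):
            raise ValidationError(
                f"{self.gene}: candidate must come from a parent term or the atlas"
            )
        if self.novelty not in (NOVEL, CURATED):
            raise ValidationError(f"bad novelty label {self.novelty!r}")


def filter_blood_protein_markers(
    genes: Iterable[str],
    records: Sequence[BiomarkerRecord],
    *,
    uniprot_by_gene: Mapping[str, str] | None = None,
    marker_type: str = "proteome",
    substrates: Sequence[str] = DEFAULT_SUBSTRATES,
    accepted_evidence: Sequence[str] = DEFAULT_ACCEPTED_EVIDENCE,
) -> set[str]:
    """Genes with >= 1 qualifying blood protein-biomarker record.

    Matching prefers the UniProt accession when both the gene list (via
    ``uniprot_by_gene``) and the record carry one, else the upper-cased
    symbol.
    """
    substrates = {s.lower() for s in substrates}
    accepted = {e.lower() for e in accepted_evidence}
    qualifying = [
        r
        for r in records
        if r.marker_type.lower() == marker_type.lower()
        and r.substrate.lower() in substrates
        and r.evidence.lower() in accepted
    ]
    by_symbol: dict[str, list[BiomarkerRecord]] = {}
    by_uniprot: dict[str, list[BiomarkerRecord]] = {}
    for r in qualifying:
        by_symbol.setdefault(r.gene.upper(), []).append(r)
        if r.uniprot:
            by_uniprot.setdefault(r.uniprot.upper(), []).append(r)
    uniprot_by_gene = {k.upper(): v.upper() for k, v in (uniprot_by_gene or {}).items()}
    kept = set()
    for gene in genes:
        g = gene.upper()
        acc = uniprot_by_gene.get(g)
        if acc is not None and acc in by_uniprot:
            kept.add(g)
        elif acc is None and g in by_symbol:
            kept.add(g)
        elif acc is not None and g in by_symbol and not any(r.uniprot for r in by_symbol[g]):
            # record side has no accession: fall back to the symbol
            kept.add(g)
    return kept


def matching_records(
    gene: str,
    records: Sequence[BiomarkerRecord],
    uniprot: str | None = None,
) -> list[BiomarkerRecord]:
    """Records matching a gene by accession (preferred) or symbol."""
    g = gene.upper()
    if uniprot:
        hits = [r for r in records if r.uniprot and r.uniprot.upper() == uniprot.upper()]
        if hits:
            return hits
    return [r for r in records if r.gene.upper() == g]


def novelty_from_flags(cond_disease: bool, cond_analyzed: bool, cond_diagnostic: bool) -> str:
    """Novelty is a pure function of the three criteria: curated iff all hold."""
    return CURATED if (cond_disease and cond_analyzed and cond_diagnostic) else NOVEL


def assign_novelty(
    records_for_gene: Sequence[BiomarkerRecord],
    diseases: Sequence[str] = DEFAULT_DISEASES,
) -> str:
    """Evaluate the three novelty criteria over a gene's records."""
    disease_set = {d.lower() for d in diseases}
    conds = lambda r: {c.lower() for c in r.conditions}
    cond_disease = any(conds(r) & disease_set for r in records_for_gene)
    cond_analyzed = any(r.commonly_analyzed for r in records_for_gene)
    cond_diagnostic = any(
        r.diagnostic_use and (conds(r) & disease_set) for r in records_for_gene
    )
    return novelty_from_flags(cond_disease, cond_analyzed, cond_diagnostic)


def dedup_candidates(per_parent_genes: Iterable[Sequence[str]]) -> set[str]:
    """Union of per-parent candidate lists; a gene listed under several
    parents counts once."""
    union: set[str] = set()
    for genes in per_parent_genes:
        union |= {g.upper() for g in genes}
    return union


@dataclass
class CandidateTable:
    """Per-parent candidate listing plus the deduplicated candidate set."""

    tissue: str
    per_parent: list = field(default_factory=list)  # (accession, name, tuple of genes)
    candidates: list = field(default_factory=list)  # CandidateBiomarker, deduplicated

    @property
    def n_unique(self) -> int:
        return len(self.candidates)


def assemble_candidate_table(
    tissue: str,
    term_gene_sets: Sequence[TermGeneSet],
    hpa_additions: set[str],
    blood_marker_genes: set[str],
    *,
    immune_genes: set[str] = frozenset(),
    hpa_specific_genes: set[str] = frozenset(),
    records: Sequence[BiomarkerRecord] = (),
    diseases: Sequence[str] = DEFAULT_DISEASES,
    parent_names: Mapping[str, str] | None = None,
) -> CandidateTable:
    """Cross the tissue gene pool with the blood-marker filter.

    Each retained parent term contributes the row of its candidates; atlas
    additions form one extra row. The deduplicated union defines the
    candidate count — a gene listed under several parents counts once.
    """
    parent_names = parent_names or {}
    blood = {g.upper() for g in blood_marker_genes}
    immune = {g.upper() for g in immune_genes}
    hpa_specific = {g.upper() for g in hpa_specific_genes}

    per_parent = []
    sources: dict[str, list[str]] = {}
    for tgs in sorted(term_gene_sets, key=lambda t: t.parent_id):
        hits = tuple(sorted({g.upper() for g in tgs.genes} & blood))
        per_parent.append((tgs.parent_id, parent_names.get(tgs.parent_id, tgs.parent_id), hits))
        for g in hits:
            sources.setdefault(g, []).append(tgs.parent_id)
    atlas_hits = tuple(sorted({g.upper() for g in hpa_additions} & blood))
    if hpa_additions or atlas_hits:
        per_parent.append(("HPA", "Additional from expression atlas", atlas_hits))

    by_record_symbol: dict[str, list[BiomarkerRecord]] = {}
    for r in records:
        by_record_symbol.setdefault(r.gene.upper(), []).append(r)

    candidates = []
    for g in sorted(set(sources) | set(atlas_hits)):
        candidates.append(
            CandidateBiomarker(
                gene=g,
                tissue=tissue,
                source_parents=tuple(sorted(sources.get(g, ()))),
                hpa_specific=g in hpa_specific or g in atlas_hits,
                immune=g in immune,
                novelty=assign_novelty(by_record_symbol.get(g, ()), diseases),
            )
        )
    return CandidateTable(tissue=tissue, per_parent=per_parent, candidates=candidates)
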