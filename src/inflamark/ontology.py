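"""Ontology term selection: keyword search, curation, descendant closure,
immune gene sets, and the per-parent selection summary.

The selection strategy mirrors a mechanism-first biomarker workflow: find
ontology terms whose names mention the tissue, keep a curated subset of
parent terms, expand each parent to its descendant ("child") terms, collect
the genes annotated to those terms, and retain only parents whose gene set
overlaps the immune-process gene set — the tissue processes plausibly
involved in low-grade inflammation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import ValidationError

log = logging.getLogger(__name__)


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves rounding up (38 from 37.5)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class OntologyTerm:
    """A single ontology term; ``parents`` holds is_a / part_of superterms."""

    id: str
    name: str
    namespace: str = "biological_process"
    parents: frozenset = frozenset()
    obsolete: bool = False


class Ontology:
    """Mapping of term id -> :class:`OntologyTerm` with an acyclic parent graph."""

    def __init__(self, terms: Iterable[OntologyTerm]):
        self.terms: dict[str, OntologyTerm] = {}
        for t in terms:
            if t.id in self.terms:
                raise ValidationError(f"duplicate term id {t.id}")
            self.terms[t.id] = t
        for t in self.terms.values():
            for p in t.parents:
                if p not in self.terms:
                    raise ValidationError(f"term {t.id} has unknown parent {p}")
        self._child_graph = nx.DiGraph()
        self._child_graph.add_nodes_from(self.terms)
        for t in self.terms.values():
            for p in t.parents:
                self._child_graph.add_edge(p, t.id)  # parent -> child
        if not nx.is_directed_acyclic_graph(self._child_graph):
            cycle = nx.find_cycle(self._child_graph)
            raise ValidationError(f"ontology parent graph contains a cycle: {cycle}")

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __getitem__(self, term_id: str) -> OntologyTerm:
        return self.terms[term_id]

    def __len__(self) -> int:
        return len(self.terms)

    def children_of(self, term_id: str) -> set[str]:
        return set(self._child_graph.successors(term_id))

    @property
    def child_graph(self) -> nx.DiGraph:
        """Directed graph with edges parent -> child."""
        return self._child_graph


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene-to-term annotation row (GAF-style)."""

    gene: str
    term_id: str
    uniprot: str | None = None
    taxon: str = "taxon:9606"
    object_type: str = "protein"
    evidence_code: str = "IEA"


@dataclass
class TermGeneSet:
    """A parent term, its descendant terms, and the genes annotated to them."""

    parent_id: str
    member_terms: set = field(default_factory=set)
    genes: set = field(default_factory=set)
    immune_genes: set = field(default_factory=set)

    def __post_init__(self):
        if not self.immune_genes <= self.genes:
            raise ValidationError(
                f"immune subset of {self.parent_id} is not contained in its gene set"
            )


@dataclass(frozen=True)
class SelectionSummaryRow:
    """One row of the selection summary (per parent term)."""

    tissue: str
    accession: str
    name: str
    n_children: int
    n_genes: int
    n_immune: int

    @property
    def pct_immune(self) -> int:
        return round_half_up(100.0 * self.n_immune / self.n_genes) if self.n_genes else 0


@dataclass(frozen=True)
class SelectionSummary:
    """Per-parent rows plus the tissue totals.

    ``total_genes`` is the sum of per-parent gene counts (a gene annotated to
    several parents is counted once per parent, not deduplicated) and the
    overall immune percentage is the immune sum over that same total.
    """

    tissue: str
    rows: tuple
    total_genes: int
    total_immune: int

    @property
    def pct_immune(self) -> int:
        return round_half_up(100.0 * self.total_immune / self.total_genes) if self.total_genes else 0


# ---------------------------------------------------------------------------
# operations


def find_terms_by_keyword(ontology: Ontology, keywords: Sequence[str]) -> set[str]:
    """Term ids whose name contains any keyword (case-insensitive substring)."""
    if not keywords:
        raise ValidationError("keyword list is empty")
    lowered = [k.lower() for k in keywords]
    return {
        t.id
        for t in ontology.terms.values()
        if not t.obsolete and any(k in t.name.lower() for k in lowered)
    }


def curate_terms(
    term_ids: Iterable[str], whitelist: Iterable[str], ontology: Ontology | None = None
) -> set[str]:
    """Intersect keyword hits with the curated whitelist of parent terms.

    The whitelist is the reproducible stand-in for manual curation (human,
    non-embryonic, endogenous, tissue-specific processes). Whitelist entries
    absent from the ontology are warned about, not fatal.
    """
    term_ids = set(term_ids)
    whitelist = set(whitelist)
    if ontology is not None:
        for missing in sorted(whitelist - set(ontology.terms)):
            log.warning("whitelist term %s not present in ontology", missing)
    kept = term_ids & whitelist
    for dropped in sorted(term_ids - kept):
        log.debug("curation dropped term %s", dropped)
    return kept


def descendant_closure(ontology: Ontology, term_ids: Iterable[str]) -> set[str]:
    """Reflexive transitive closure over child edges (each term once)."""
    term_ids = set(term_ids)
    for tid in term_ids:
        if tid not in ontology:
            raise ValidationError(f"unknown term id {tid}")
    closure = set(term_ids)
    for tid in term_ids:
        closure |= nx.descendants(ontology.child_graph, tid)
    return closure


def _filtered_annotations(
    annotations: Iterable[GeneAnnotation],
    species: str | None,
    object_type: str | None,
) -> list[GeneAnnotation]:
    out = []
    for a in annotations:
        if species is not None and a.taxon != species:
            continue
        if object_type is not None and a.object_type != object_type:
            continue
        out.append(a)
    return out


def build_immune_gene_set(
    ontology: Ontology,
    annotations: Iterable[GeneAnnotation],
    immune_roots: Sequence[str],
    *,
    species: str | None = None,
    object_type: str | None = None,
) -> set[str]:
    """Genes annotated (after species/type filtering) to the closure of the
    immune-process root terms. Symbols are upper-cased."""
    closure = descendant_closure(ontology, immune_roots)
    return {
        a.gene.upper()
        for a in _filtered_annotations(annotations, species, object_type)
        if a.term_id in closure
    }


def build_term_gene_sets(
    ontology: Ontology,
    annotations: Iterable[GeneAnnotation],
    parent_ids: Iterable[str],
    *,
    species: str | None = None,
    object_type: str | None = None,
) -> list[TermGeneSet]:
    """For each parent, collect its descendant terms and annotated genes."""
    filtered = _filtered_annotations(annotations, species, object_type)
    by_term: dict[str, set[str]] = {}
    for a in filtered:
        by_term.setdefault(a.term_id, set()).add(a.gene.upper())
    sets = []
    for pid in sorted(set(parent_ids)):
        members = descendant_closure(ontology, [pid])
        genes: set[str] = set()
        for tid in members:
            genes |= by_term.get(tid, set())
        sets.append(TermGeneSet(parent_id=pid, member_terms=members, genes=genes))
    return sets


def filter_tissue_terms_by_immune_overlap(
    term_gene_sets: Iterable[TermGeneSet], immune_genes: set[str]
) -> list[TermGeneSet]:
    """Retain parents whose gene set shares >= 1 gene with the immune set."""
    retained = []
    for tgs in term_gene_sets:
        overlap = tgs.genes & immune_genes
        if overlap:
            retained.append(replace(tgs, immune_genes=overlap))
        else:
            log.debug("parent %s dropped: no immune overlap", tgs.parent_id)
    return retained


def summarize_counts(
    tissue: str, rows: Sequence[SelectionSummaryRow]
) -> SelectionSummary:
    """Totals over per-parent rows: gene/immune sums and overall percentage."""
    for r in rows:
        if r.n_immune > r.n_genes:
            raise ValidationError(
                f"row {r.accession}: immune count {r.n_immune} exceeds gene count {r.n_genes}"
            )
    return SelectionSummary(
        tissue=tissue,
        rows=tuple(rows),
        total_genes=sum(r.n_genes for r in rows),
        total_immune=sum(r.n_immune for r in rows),
    )


def summarize_selection(
    tissue: str, retained: Sequence[TermGeneSet], ontology: Ontology
) -> SelectionSummary:
    """Per-parent summary rows plus tissue totals for retained term sets."""
    rows = [
        SelectionSummaryRow(
            tissue=tissue,
            accession=tgs.parent_id,
            name=ontology[tgs.parent_id].name if tgs.parent_id in ontology else tgs.parent_id,
            n_children=len(tgs.member_terms) - 1,
            n_genes=len(tgs.genes),
            n_immune=len(tgs.immune_genes),
        )
        for tgs in sorted(retained, key=lambda t: t.parent_id)
    ]
    return summarize_counts(tissue, rows)
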