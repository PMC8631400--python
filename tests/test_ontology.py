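"""Ontology selection: keyword search, curation, closure, immune overlap,
and the per-parent selection summary arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from inflamark.errors import ValidationError
from inflamark.ontology import (
    GeneAnnotation,
    Ontology,
    OntologyTerm,
    SelectionSummaryRow,
    build_immune_gene_set,
    build_term_gene_sets,
    curate_terms,
    descendant_closure,
    filter_tissue_terms_by_immune_overlap,
    find_terms_by_keyword,
    round_half_up,
    summarize_counts,
)
from inflamark.reference_tables import selection_summary_rows

from .oracles import bfs_closure


def make_ontology(edges, names=None):
    """Ontology from (child, parent) edges; names default to ids."""
    nodes = {n for e in edges for n in e}
    parents = {}
    for child, parent in edges:
        parents.setdefault(child, set()).add(parent)
    names = names or {}
    return Ontology(
        OntologyTerm(n, names.get(n, n), parents=frozenset(parents.get(n, ())))
        for n in sorted(nodes)
    )


@pytest.fixture
def diamond():
    # d is a child of both b and c, which are children of a
    return make_ontology([("b", "a"), ("c", "a"), ("d", "b"), ("d", "c")])


class TestKeywordSearch:
    def test_substring_match(self):
        onto = make_ontology([("x", "r")], names={"r": "adipose tissue development", "x": "other"})
        assert find_terms_by_keyword(onto, ["adipose"]) == {"r"}

    def test_case_insensitive(self):
        onto = make_ontology([("x", "r")], names={"r": "liver development", "x": "other"})
        assert find_terms_by_keyword(onto, ["LIVER"]) == {"r"}

    def test_no_match_empty(self):
        onto = make_ontology([("x", "r")], names={"r": "kidney development", "x": "other"})
        assert find_terms_by_keyword(onto, ["adipose", "adipocyte"]) == set()

    def test_obsolete_excluded(self):
        onto = Ontology(
            [
                OntologyTerm("a", "adipose process"),
                OntologyTerm("b", "adipose process obsolete", obsolete=True),
            ]
        )
        assert find_terms_by_keyword(onto, ["adipose"]) == {"a"}


class TestCuration:
    def test_whitelist_intersection(self, diamond):
        hits = {"a", "b", "c", "d"}
        assert curate_terms(hits, {"a", "b"}, diamond) == {"a", "b"}

    def test_empty_whitelist(self, diamond):
        assert curate_terms({"a", "b"}, set(), diamond) == set()

    def test_superset_whitelist_identity(self, diamond):
        assert curate_terms({"a", "b"}, {"a", "b", "c", "zz"}, diamond) == {"a", "b"}


class TestClosure:
    def test_chain(self):
        onto = make_ontology([("b", "a"), ("c", "b")])
        assert descendant_closure(onto, {"a"}) == {"a", "b", "c"}

    def test_leaf_is_itself(self, diamond):
        assert descendant_closure(diamond, {"d"}) == {"d"}

    def test_diamond_counts_once(self, diamond):
        closure = descendant_closure(diamond, {"a"})
        assert closure == {"a", "b", "c", "d"}
        assert len(closure) == 4  # set semantics, not path enumeration

    def test_unknown_id_raises(self, diamond):
        with pytest.raises(ValidationError, match="nope"):
            descendant_closure(diamond, {"nope"})

    def test_idempotent_and_monotone(self, diamond):
        c1 = descendant_closure(diamond, {"b"})
        assert descendant_closure(diamond, c1) == c1
        assert descendant_closure(diamond, {"b"}) <= descendant_closure(diamond, {"a", "b"})

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.data())
    def test_matches_bfs_oracle_on_random_dags(self, data):
        """Closure equals plain BFS on random DAGs of up to 50 nodes."""
        n = data.draw(st.integers(2, 50))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        edges = []
        for child in range(1, n):
            for parent in rng.choice(child, size=min(child, 2), replace=False):
                if rng.random() < 0.7:
                    edges.append((f"t{child}", f"t{int(parent)}"))
        if not edges:
            edges = [("t1", "t0")]
        onto = make_ontology(edges)
        children = {}
        for child, parent in edges:
            children.setdefault(parent, set()).add(child)
        seeds = set(
            data.draw(
                st.lists(st.sampled_from(sorted(onto.terms)), min_size=1, max_size=3)
            )
        )
        assert descendant_closure(onto, seeds) == bfs_closure(children, seeds)


class TestImmuneGeneSet:
    @pytest.fixture
    def setting(self):
        onto = make_ontology(
            [("infl", "immune"), ("sub", "infl"), ("fat", "root"), ("immune", "root")]
        )
        anns = [
            GeneAnnotation("deep", "sub"),  # grandchild of the immune root
            GeneAnnotation("tissue_only", "fat"),
            GeneAnnotation("mouse", "sub", taxon="taxon:10090"),
        ]
        return onto, anns

    def test_grandchild_annotation_included(self, setting):
        onto, anns = setting
        genes = build_immune_gene_set(onto, anns, ["immune"], species="taxon:9606")
        assert "DEEP" in genes

    def test_non_immune_term_excluded(self, setting):
        onto, anns = setting
        genes = build_immune_gene_set(onto, anns, ["immune"], species="taxon:9606")
        assert "TISSUE_ONLY" not in genes

    def test_wrong_taxon_excluded(self, setting):
        onto, anns = setting
        genes = build_immune_gene_set(onto, anns, ["immune"], species="taxon:9606")
        assert "MOUSE" not in genes


class TestImmuneOverlapFilter:
    def test_full_overlap_retained(self, diamond):
        sets = build_term_gene_sets(
            diamond, [GeneAnnotation("g1", "d")], ["b"]
        )
        kept = filter_tissue_terms_by_immune_overlap(sets, {"G1"})
        assert len(kept) == 1
        assert kept[0].immune_genes == {"G1"}

    def test_no_overlap_dropped(self, diamond):
        sets = build_term_gene_sets(diamond, [GeneAnnotation("g1", "d")], ["b"])
        assert filter_tissue_terms_by_immune_overlap(sets, {"OTHER"}) == []

    def test_immune_subset_recomputable(self, diamond):
        anns = [GeneAnnotation(g, t) for g, t in [("g1", "b"), ("g2", "d"), ("g3", "d")]]
        sets = build_term_gene_sets(diamond, anns, ["a", "b"])
        immune = {"G1", "G3"}
        for tgs in filter_tissue_terms_by_immune_overlap(sets, immune):
            assert tgs.immune_genes == tgs.genes & immune


class TestSummaryArithmetic:
    def test_adipose_reference_totals(self):
        """The transcribed adipose parent counts sum to 375 genes, 43% immune."""
        summary = summarize_counts("adipose", selection_summary_rows("adipose"))
        assert summary.total_genes == 375
        assert summary.pct_immune == 43

    def test_liver_reference_totals(self):
        summary = summarize_counts("liver", selection_summary_rows("liver"))
        assert summary.total_genes == 174
        assert summary.pct_immune == 45

    def test_row_percentages_match_reference(self):
        printed = {"GO:0005901": 36, "GO:0045444": 44, "GO:0034382": 38, "GO:0044321": 46}
        for tissue in ("adipose", "liver"):
            for row in selection_summary_rows(tissue):
                if row.accession in printed:
                    assert row.pct_immune == printed[row.accession]

    def test_immune_exceeding_genes_rejected(self):
        bad = [SelectionSummaryRow("t", "GO:1", "x", 1, 2, 3)]
        with pytest.raises(ValidationError):
            summarize_counts("t", bad)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(0, 500)).map(
                lambda t: (max(t), min(t))
            ),
            min_size=1,
            max_size=10,
        )
    )
    def test_totals_are_row_sums_and_pct_bounded(self, pairs):
        rows = [
            SelectionSummaryRow("t", f"GO:{i}", "x", 1, genes, immune)
            for i, (genes, immune) in enumerate(pairs)
        ]
        summary = summarize_counts("t", rows)
        assert summary.total_genes == sum(g for g, _ in pairs)
        assert summary.total_immune == sum(i for _, i in pairs)
        assert 0 <= summary.pct_immune <= 100
        assert all(0 <= r.pct_immune <= 100 for r in rows)


def test_round_half_up_halves_go_up():
    assert round_half_up(37.5) == 38
    assert round_half_up(42.4) == 42
    assert round_half_up(45.5) == 46
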