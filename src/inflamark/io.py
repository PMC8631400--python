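"""Readers and writers for every external representation the pipeline
consumes or produces: OBO ontologies, GAF gene annotations, and the TSV
tables for the expression atlas, the biomarker database, count matrices,
sample metadata, evidence records, and reports.

All tabular formats are tab-separated with a header row; reader/writer
pairs round-trip losslessly.
"""

from __future__ import annotations

import csv
import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import obonet
import pandas as pd

from .atlas import TissueProfile
from .candidates import BiomarkerRecord
from .confirm import EvidenceRecord
from .errors import ParseError, ValidationError
from .ontology import GeneAnnotation, Ontology, OntologyTerm
from .verify import CohortSample, CountMatrix

log = logging.getLogger(__name__)

#: parent-edge relationship types honoured when reading OBO files
OBO_EDGE_TYPES = ("is_a", "part_of")

_GAF_COLUMNS = 17
_TAG_RE = re.compile(r"^[A-Za-z_][\w-]*:\s?.*$")


# ---------------------------------------------------------------------------
# ontology (OBO 1.2)


def _prevalidate_obo(path) -> None:
    """Light line-level scan so malformed stanzas fail with a line number."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("!", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                continue
            if not _TAG_RE.match(line):
                raise ParseError(f"{path}: malformed line {lineno}: {raw.strip()!r}")


def read_obo(path) -> Ontology:
    """Read an OBO 1.2 file into an :class:`~inflamark.ontology.Ontology`.

    Obsolete terms are excluded; parent edges come from ``is_a`` and
    ``relationship: part_of`` tags, other relationship types are ignored
    with a warning. A cyclic parent graph is a validation error.
    """
    _prevalidate_obo(path)
    graph = obonet.read_obo(path, ignore_obsolete=True)
    terms = []
    for node, data in graph.nodes(data=True):
        parents = set()
        for _, parent, key in graph.out_edges(node, keys=True):
            if key in OBO_EDGE_TYPES:
                parents.add(parent)
            else:
                log.warning("ignoring %s edge %s -> %s", key, node, parent)
        terms.append(
            OntologyTerm(
                id=node,
                name=data.get("name", node),
                namespace=data.get("namespace", "biological_process"),
                parents=frozenset(p for p in parents if p in graph),
            )
        )
    return Ontology(terms)


def write_obo(ontology: Ontology, path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: syn\n")
        for tid in sorted(ontology.terms):
            t = ontology[tid]
            fh.write("\n[Term]\n")
            fh.write(f"id: {t.id}\n")
            fh.write(f"name: {t.name}\n")
            fh.write(f"namespace: {t.namespace}\n")
            for p in sorted(t.parents):
                fh.write(f"is_a: {p} ! {ontology[p].name}\n")


# ---------------------------------------------------------------------------
# gene annotations (GAF 2.2)


def read_gaf(path) -> list[GeneAnnotation]:
    """Read a GAF 2.2 file; no filtering is applied at read time."""
    annotations = []
    with open(path) as fh:
        for rowno, line in enumerate(fh, start=1):
            if line.startswith("!") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != _GAF_COLUMNS:
                raise ParseError(
                    f"{path}: row {rowno}: expected {_GAF_COLUMNS} columns, got {len(fields)}"
                )
            annotations.append(
                GeneAnnotation(
                    gene=fields[2],
                    uniprot=fields[1] or None,
                    term_id=fields[4],
                    taxon=fields[12],
                    object_type=fields[11],
                    evidence_code=fields[6],
                )
            )
    return annotations


def write_gaf(annotations: Iterable[GeneAnnotation], path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("!gaf-version: 2.2\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for a in annotations:
            row = [""] * _GAF_COLUMNS
            row[0] = "SYN"
            row[1] = a.uniprot or ""
            row[2] = a.gene
            row[3] = "involved_in"
            row[4] = a.term_id
            row[5] = "SYN:0000001"
            row[6] = a.evidence_code
            row[8] = "P"
            row[11] = a.object_type
            row[12] = a.taxon
            row[13] = "20200901"
            row[14] = "SYN"
            writer.writerow(row)


# ---------------------------------------------------------------------------
# atlas table


def read_atlas_table(path) -> list[TissueProfile]:
    """Atlas TSV: gene, uniprot, then one expression column per tissue."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "uniprot": str})
    if "gene" not in df.columns:
        raise ParseError(f"{path}: missing 'gene' column")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValidationError(f"{path}: duplicate gene id {dup!r}")
    tissue_cols = [c for c in df.columns if c not in ("gene", "uniprot")]
    profiles = []
    for _, row in df.iterrows():
        uniprot = row.get("uniprot")
        profiles.append(
            TissueProfile(
                gene=row["gene"],
                uniprot=None if pd.isna(uniprot) else str(uniprot),
                levels={t: float(row[t]) for t in tissue_cols},
            )
        )
    return profiles


def write_atlas_table(profiles: Sequence[TissueProfile], path) -> None:
    tissues = sorted({t for p in profiles for t in p.levels})
    rows = [
        {"gene": p.gene, "uniprot": p.uniprot or "", **{t: p.levels[t] for t in tissues}}
        for p in sorted(profiles, key=lambda p: p.gene)
    ]
    pd.DataFrame(rows, columns=["gene", "uniprot", *tissues]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# biomarker database table


def read_biomarker_table(path) -> list[BiomarkerRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {
        "gene",
        "uniprot",
        "marker_type",
        "substrate",
        "evidence",
        "conditions",
        "commonly_analyzed",
        "diagnostic_use",
    }
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        conditions = frozenset(c.strip() for c in row["conditions"].split(";") if c.strip())
        records.append(
            BiomarkerRecord(
                gene=row["gene"],
                uniprot=row["uniprot"] or None,
                marker_type=row["marker_type"],
                substrate=row["substrate"],
                evidence=row["evidence"],
                conditions=conditions,
                commonly_analyzed=row["commonly_analyzed"].lower() == "true",
                diagnostic_use=row["diagnostic_use"].lower() == "true",
            )
        )
    return records


def write_biomarker_table(records: Sequence[BiomarkerRecord], path) -> None:
    rows = [
        {
            "gene": r.gene,
            "uniprot": r.uniprot or "",
            "marker_type": r.marker_type,
            "substrate": r.substrate,
            "evidence": r.evidence,
            "conditions": ";".join(sorted(r.conditions)),
            "commonly_analyzed": str(r.commonly_analyzed),
            "diagnostic_use": str(r.diagnostic_use),
        }
        for r in sorted(records, key=lambda r: (r.gene, r.substrate, r.evidence))
    ]
    cols = [
        "gene",
        "uniprot",
        "marker_type",
        "substrate",
        "evidence",
        "conditions",
        "commonly_analyzed",
        "diagnostic_use",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# counts and sample metadata


def read_counts_table(path, tissue: str) -> CountMatrix:
    """Counts TSV: first column gene id, one column per sample."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):  # read_csv would silently mangle these
        dup = next(s for s in samples if samples.count(s) > 1)
        raise ValidationError(f"{path}: duplicate sample id {dup!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative count")
    return CountMatrix(counts=df, tissue=tissue)


def write_counts_table(matrix: CountMatrix, path) -> None:
    out = matrix.counts.astype(int)
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_sample_metadata(path) -> list[CohortSample]:
    """Metadata TSV: sample_id, group, tissue, histology_score, plasma_* columns."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str, "tissue": str})
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate sample id {dup!r}")
    plasma_cols = [c for c in df.columns if c.startswith("plasma_")]
    samples = []
    for _, row in df.iterrows():
        samples.append(
            CohortSample(
                sample_id=row["sample_id"],
                group=row["group"],
                tissue=row["tissue"],
                histology_score=float(row["histology_score"]),
                plasma={c[len("plasma_"):]: float(row[c]) for c in plasma_cols},
            )
        )
    return samples


def write_sample_metadata(samples: Sequence[CohortSample], path) -> None:
    analytes = sorted({a for s in samples for a in s.plasma})
    rows = [
        {
            "sample_id": s.sample_id,
            "group": s.group,
            "tissue": s.tissue,
            "histology_score": s.histology_score,
            **{f"plasma_{a}": s.plasma.get(a, float("nan")) for a in analytes},
        }
        for s in sorted(samples, key=lambda s: (s.tissue, s.sample_id))
    ]
    cols = ["sample_id", "group", "tissue", "histology_score"] + [f"plasma_{a}" for a in analytes]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# evidence table


def read_evidence_table(path) -> list[EvidenceRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    as_bool = lambda v: str(v).lower() == "true"
    for _, row in df.iterrows():
        records.append(
            EvidenceRecord(
                gene=row["gene"],
                tissue=row["tissue"],
                cond_mechanism=as_bool(row["cond_i"]),
                cond_tissue_disease=as_bool(row["cond_ii"]),
                cond_metabolic=as_bool(row["cond_iii"]),
                notes=row.get("notes", ""),
            )
        )
    return records


def write_evidence_table(records: Sequence[EvidenceRecord], path) -> None:
    rows = [
        {
            "gene": r.gene,
            "tissue": r.tissue,
            "cond_i": str(r.cond_mechanism),
            "cond_ii": str(r.cond_tissue_disease),
            "cond_iii": str(r.cond_metabolic),
            "notes": r.notes,
        }
        for r in sorted(records, key=lambda r: (r.tissue, r.gene))
    ]
    pd.DataFrame(rows, columns=["gene", "tissue", "cond_i", "cond_ii", "cond_iii", "notes"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# generic report writer


def write_tsv_report(rows: pd.DataFrame, path, sort_by: Sequence[str] | None = None) -> None:
    """Write a report TSV with deterministic column and row order.

    Rows are sorted by ``sort_by`` when given, else by tissue then gene when
    those columns exist, else by all columns left to right.
    """
    df = rows.copy()
    if sort_by is None:
        preferred = [c for c in ("tissue", "gene") if c in df.columns]
        sort_by = preferred or list(df.columns)
    if len(df):
        df = df.sort_values(by=list(sort_by), kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_tsv_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
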