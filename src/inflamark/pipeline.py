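"""End-to-end orchestration of the biomarker workflow.

Stages (mirroring the CLI): ``simulate`` writes every synthetic input,
``select`` runs the ontology term/gene selection, ``atlas`` the
tissue-specificity calls and unique additions, ``candidates`` the
blood-marker filtering and novelty rubric, ``verify`` the cohort
differential-expression and correlation analysis, ``confirm`` the
literature-level report. ``run_all`` chains everything and is byte-for-byte
deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import io
from .atlas import atlas_tissue_specific_genes, classify_atlas
from .candidates import assemble_candidate_table, filter_blood_protein_markers
from .config import RunConfig
from .confirm import final_biomarker_report, marker_counts_by_tissue, tally_levels
from .de import estimate_dispersions, nb_wald_test, normalize_counts, size_factors
from .ontology import (
    build_immune_gene_set,
    build_term_gene_sets,
    curate_terms,
    descendant_closure,
    filter_tissue_terms_by_immune_overlap,
    find_terms_by_keyword,
    summarize_selection,
)
from .simulate import (
    SynthConfig,
    gen_biomarker_db,
    gen_cohort,
    gen_evidence,
    gen_ontology_and_annotations,
    gen_tissue_atlas,
    ground_truth_table,
    run_config_for,
)
from .verify import (
    classify_markers,
    cohort_statistics,
    correlate_expression_to_histology,
    select_verified_candidates,
)

INPUT_FILES = {
    "ontology": "ontology.obo",
    "annotations": "annotations.gaf",
    "atlas": "atlas.tsv",
    "biomarkers": "biomarkers.tsv",
    "counts_liver": "counts_liver.tsv",
    "counts_wat": "counts_wat.tsv",
    "samples": "samples.tsv",
    "evidence": "evidence.tsv",
    "ground_truth": "ground_truth.tsv",
    "run_config": "run_config.yaml",
}


def simulate_inputs(cfg: SynthConfig, outdir) -> dict[str, Path]:
    """Generate and write every pipeline input; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ontology, annotations, truth = gen_ontology_and_annotations(cfg)
    atlas = gen_tissue_atlas(cfg, truth)
    db = gen_biomarker_db(cfg, truth)
    matrices, samples = gen_cohort(cfg, truth)
    evidence = gen_evidence(cfg, truth)

    paths = {k: outdir / v for k, v in INPUT_FILES.items()}
    io.write_obo(ontology, paths["ontology"])
    io.write_gaf(annotations, paths["annotations"])
    io.write_atlas_table(atlas, paths["atlas"])
    io.write_biomarker_table(db, paths["biomarkers"])
    io.write_counts_table(matrices["liver"], paths["counts_liver"])
    io.write_counts_table(matrices["WAT"], paths["counts_wat"])
    io.write_sample_metadata(samples, paths["samples"])
    io.write_evidence_table(evidence, paths["evidence"])
    io.write_tsv_report(ground_truth_table(truth), paths["ground_truth"], sort_by=["gene"])
    run_config_for(cfg, truth).to_yaml(paths["run_config"])
    return paths


def run_selection(config: RunConfig, ontology, annotations) -> dict:
    """Ontology branch: keyword search, curation, closure, immune overlap."""
    immune = build_immune_gene_set(
        ontology,
        annotations,
        config.immune_roots,
        species=config.species,
        object_type=config.object_type,
    )
    out: dict = {"immune_genes": immune, "tissues": {}}
    for tissue, keywords in config.keywords.items():
        hits = find_terms_by_keyword(ontology, keywords)
        parents = curate_terms(hits, config.whitelist.get(tissue, ()), ontology)
        term_sets = build_term_gene_sets(
            ontology,
            annotations,
            parents,
            species=config.species,
            object_type=config.object_type,
        )
        retained = filter_tissue_terms_by_immune_overlap(term_sets, immune)
        summary = summarize_selection(tissue, retained, ontology)
        genes = set()
        for tgs in retained:
            genes |= tgs.genes
        out["tissues"][tissue] = {
            "keyword_hits": hits,
            "parents": parents,
            "term_sets": retained,
            "summary": summary,
            "genes": genes,
        }
    return out


def run_atlas(config: RunConfig, profiles, selection: dict) -> dict:
    """Atlas branch: specificity calls and unique immune additions."""
    thr = config.thresholds
    calls = classify_atlas(
        profiles,
        fold=thr.fold_specificity,
        group_range=(thr.group_size_min, thr.group_size_max),
        denominator=config.specificity_denominator,
    )
    out: dict = {"calls": calls, "tissues": {}}
    immune = selection["immune_genes"]
    for tissue in config.keywords:
        atlas_label = config.atlas_tissue_labels[tissue]
        specific = atlas_tissue_specific_genes(
            profiles,
            atlas_label,
            fold=thr.fold_specificity,
            group_range=(thr.group_size_min, thr.group_size_max),
            denominator=config.specificity_denominator,
        )
        go_genes = selection["tissues"][tissue]["genes"]
        from .atlas import unique_hpa_additions

        additions = unique_hpa_additions(specific, go_genes, immune)
        out["tissues"][tissue] = {"specific": specific, "additions": additions}
    return out


def run_candidates(config: RunConfig, selection: dict, atlas_out: dict, records) -> dict:
    """Candidate branch: blood-marker filter, novelty, per-parent table."""
    immune = selection["immune_genes"]
    out: dict = {"tissues": {}}
    for tissue in config.keywords:
        go_genes = selection["tissues"][tissue]["genes"]
        additions = atlas_out["tissues"][tissue]["additions"]
        pool = {g.upper() for g in go_genes} | additions
        blood = filter_blood_protein_markers(
            pool,
            records,
            marker_type=config.marker_type,
            substrates=config.substrates,
            accepted_evidence=config.accepted_evidence,
        )
        # parent term names come from the ontology-derived selection
        parent_names = {}
        table = assemble_candidate_table(
            tissue,
            selection["tissues"][tissue]["term_sets"],
            additions,
            blood,
            immune_genes=immune,
            hpa_specific_genes=atlas_out["tissues"][tissue]["specific"],
            records=records,
            diseases=config.diseases,
            parent_names=parent_names,
        )
        out["tissues"][tissue] = {"pool": pool, "blood": blood, "table": table}
    return out


def run_verification(config: RunConfig, matrices, samples, candidates_out: dict) -> dict:
    """Cohort branch: DE per tissue, criteria a-c, correlation, classification."""
    thr = config.thresholds
    de_results, normalized = {}, {}
    for tissue, matrix in matrices.items():
        meta = {
            s.sample_id: s.group for s in samples if s.tissue == tissue
        }
        cols = [c for c in matrix.counts.columns if c in meta]
        counts = matrix.counts[cols]
        groups = [meta[c] for c in cols]
        factors = size_factors(counts)
        dispersions = estimate_dispersions(counts, factors, groups)
        de_results[tissue] = nb_wald_test(counts, groups, factors, dispersions)
        normalized[tissue] = normalize_counts(counts, factors)

    out: dict = {"de": de_results, "normalized": normalized, "tissues": {}}
    correlations = {
        tissue: correlate_expression_to_histology(
            normalized[tissue],
            samples,
            tissue,
            rho_cutoff=thr.rho_cutoff,
            subset=config.correlation_samples,
        )
        for tissue in matrices
    }
    out["correlations"] = correlations
    classified = classify_markers(correlations["liver"], correlations["WAT"])
    out["classified"] = classified

    for tissue_label in config.keywords:
        cohort_tissue = config.cohort_tissue_labels[tissue_label]
        table = candidates_out["tissues"][tissue_label]["table"]
        candidate_genes = {
            c.gene
            for c in table.candidates
            if config.verify_novel or c.novelty == "curated"
        }
        verified = select_verified_candidates(
            de_results,
            normalized,
            samples,
            candidate_genes,
            cohort_tissue,
            fdr_cutoff=thr.fdr_cutoff,
            detect_min_norm_count=thr.detect_min_norm_count,
            criterion_c_samples=config.criterion_c_samples,
        )
        out["tissues"][tissue_label] = {"verified": verified}
    out["cohort_stats"] = cohort_statistics(samples)
    return out


def run_confirmation(config: RunConfig, verification: dict, evidence) -> dict:
    """Confirmation branch: join verified markers with literature evidence."""
    verified_all = set()
    for tissue in verification["tissues"].values():
        verified_all |= tissue["verified"]
    classified = verification["classified"]
    classified = classified.loc[[g for g in classified.index if g in verified_all]]
    report = final_biomarker_report(classified, evidence, config.function_categories)
    return {
        "report": report,
        "tally": tally_levels([lv for lv in report["level"] if lv >= 0]),
        "counts": marker_counts_by_tissue(report),
    }


# ---------------------------------------------------------------------------
# file-level orchestration


def _summary_frame(selection: dict) -> pd.DataFrame:
    rows = []
    for tissue, data in selection["tissues"].items():
        summary = data["summary"]
        for r in summary.rows:
            rows.append(
                {
                    "tissue": r.tissue,
                    "accession": r.accession,
                    "parent_name": r.name,
                    "n_children": r.n_children,
                    "n_genes": r.n_genes,
                    "n_immune": r.n_immune,
                    "pct_immune": r.pct_immune,
                }
            )
        rows.append(
            {
                "tissue": tissue,
                "accession": "TOTAL",
                "parent_name": "total",
                "n_children": sum(r.n_children for r in summary.rows),
                "n_genes": summary.total_genes,
                "n_immune": summary.total_immune,
                "pct_immune": summary.pct_immune,
            }
        )
    return pd.DataFrame(rows)


def run_all(cfg: SynthConfig, outdir) -> dict:
    """Simulate inputs, run every stage, write all reports; returns results."""
    outdir = Path(outdir)
    inputs_dir = outdir / "inputs"
    results_dir = outdir / "outputs"
    results_dir.mkdir(parents=True, exist_ok=True)
    paths = simulate_inputs(cfg, inputs_dir)

    config = RunConfig.from_yaml(paths["run_config"])
    ontology = io.read_obo(paths["ontology"])
    annotations = io.read_gaf(paths["annotations"])
    profiles = io.read_atlas_table(paths["atlas"])
    records = io.read_biomarker_table(paths["biomarkers"])
    matrices = {
        "liver": io.read_counts_table(paths["counts_liver"], "liver"),
        "WAT": io.read_counts_table(paths["counts_wat"], "WAT"),
    }
    samples = io.read_sample_metadata(paths["samples"])
    evidence = io.read_evidence_table(paths["evidence"])

    selection = run_selection(config, ontology, annotations)
    atlas_out = run_atlas(config, profiles, selection)
    candidates_out = run_candidates(config, selection, atlas_out, records)
    verification = run_verification(config, matrices, samples, candidates_out)
    confirmation = run_confirmation(config, verification, evidence)

    # reports
    io.write_tsv_report(_summary_frame(selection), results_dir / "selection_summary.tsv",
                        sort_by=["tissue", "accession"])
    atlas_rows = pd.DataFrame(
        [
            {"gene": c.gene, "class": c.category, "enriched_tissues": ",".join(c.tissues)}
            for c in atlas_out["calls"]
        ]
    )
    io.write_tsv_report(atlas_rows, results_dir / "atlas_calls.tsv", sort_by=["gene"])
    cand_rows = []
    for tissue, data in candidates_out["tissues"].items():
        table = data["table"]
        for acc, name, genes in table.per_parent:
            cand_rows.append(
                {
                    "tissue": tissue,
                    "parent_accession": acc,
                    "parent_name": name,
                    "n_candidates": len(genes),
                    "candidates": ",".join(genes),
                }
            )
        cand_rows.append(
            {
                "tissue": tissue,
                "parent_accession": "TOTAL",
                "parent_name": "deduplicated",
                "n_candidates": table.n_unique,
                "candidates": "",
            }
        )
    io.write_tsv_report(pd.DataFrame(cand_rows), results_dir / "candidates.tsv",
                        sort_by=["tissue", "parent_accession"])
    de_frames = []
    for tissue, de in verification["de"].items():
        frame = de.reset_index(names="gene")
        frame.insert(1, "tissue", tissue)
        de_frames.append(frame)
    io.write_tsv_report(pd.concat(de_frames, ignore_index=True), results_dir / "de.tsv")
    corr_frames = []
    for tissue, corr in verification["correlations"].items():
        frame = corr.reset_index(names="gene")
        corr_frames.append(frame)
    io.write_tsv_report(pd.concat(corr_frames, ignore_index=True),
                        results_dir / "correlation.tsv")
    verified_rows = [
        {"tissue": tissue, "gene": g}
        for tissue, data in verification["tissues"].items()
        for g in sorted(data["verified"])
    ]
    io.write_tsv_report(pd.DataFrame(verified_rows, columns=["tissue", "gene"]),
                        results_dir / "verified.tsv")
    io.write_tsv_report(
        verification["cohort_stats"].reset_index(), results_dir / "cohort_stats.tsv",
        sort_by=["tissue"],
    )
    io.write_tsv_report(confirmation["report"], results_dir / "final_report.tsv",
                        sort_by=["tissue", "gene"])
    with open(results_dir / "level_tally.json", "w") as fh:
        json.dump({str(k): v for k, v in sorted(confirmation["tally"].items())}, fh, indent=2)
        fh.write("\n")

    return {
        "config": config,
        "selection": selection,
        "atlas": atlas_out,
        "candidates": candidates_out,
        "verification": verification,
        "confirmation": confirmation,
        "paths": paths,
        "results_dir": results_dir,
    }
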