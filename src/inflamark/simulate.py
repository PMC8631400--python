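"""Synthetic stand-ins for every external input the pipeline consumes.

The generators emulate the study conditions of a diet-induced inflammation
cohort and its knowledgebases with planted ground truth:

* an acyclic ontology whose tissue parents carry keyword names and whose
  gene sets overlap the immune-process gene set at a configured fraction
  (default 0.44, the overall overlap observed in the real term selection);
* a cross-tissue expression atlas with planted tissue-enriched genes
  clearing the four-fold specificity rule and background genes violating it;
* a blood-biomarker database in which planted markers always hold a
  qualifying record, decoys hold disqualifying ones, and novelty criteria
  are planted;
* a cohort of 10 chow and 17 high-fat-diet animals with lognormal histology
  scores (liver effect 31.6-fold, WAT effect 9.1-fold), NB-distributed
  counts with sample depth heterogeneity, planted markers whose log-mean is
  an affine function of the animal's histology score calibrated to a target
  Spearman correlation, and a plasma analyte tracking liver histology;
* the curated literature-evidence booleans for the planted markers.

One integer seed drives independent sub-streams per generator, so
regenerating one input never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .atlas import TissueProfile
from .candidates import BiomarkerRecord
from .config import DEFAULT_DISEASES, DEFAULT_IMMUNE_ROOTS, RunConfig, Thresholds
from .confirm import EvidenceRecord
from .errors import ValidationError
from .ontology import GeneAnnotation, Ontology, OntologyTerm
from .verify import CohortSample, CountMatrix

TISSUE_LABELS = ("adipose", "liver")
COHORT_TISSUE = {"adipose": "WAT", "liver": "liver"}
ATLAS_TISSUE = {"adipose": "adipose tissue", "liver": "liver"}

# fixed sub-stream ids per generator
_STREAM_ONTOLOGY = 1
_STREAM_ATLAS = 2
_STREAM_BIOMARKER = 3
_STREAM_COHORT = 4
_STREAM_EVIDENCE = 5

_PARENT_NOUNS = [
    "tissue development",
    "cell differentiation",
    "tissue remodeling",
    "cell proliferation",
    "tissue morphogenesis",
    "cell apoptotic process",
    "tissue homeostasis",
    "cell migration",
]

_IMMUNE_ROOT_NAMES = {
    DEFAULT_IMMUNE_ROOTS[0]: "immune system process",
    DEFAULT_IMMUNE_ROOTS[1]: "inflammatory response",
    DEFAULT_IMMUNE_ROOTS[2]: "cytokine production",
}


@dataclass
class SynthConfig:
    """Knobs of the synthetic study; defaults are the reference conditions."""

    seed: int = 0
    n_genes: int = 2000
    # ontology
    n_tissue_parents: int = 6          # whitelisted parents per tissue
    n_decoy_parents: int = 2           # keyword-matching parents excluded by curation
    ontology_branching: int = 2
    ontology_depth: int = 2
    n_immune_children: int = 3         # children per immune root
    immune_overlap: float = 0.44       # fraction of tissue genes also immune
    n_tissue_genes: int = 300          # annotated genes per tissue
    n_immune_only_genes: int = 200
    # atlas
    n_atlas_tissues: int = 6
    n_planted_enriched: int = 20       # planted tissue-enriched genes per tissue
    atlas_fold_margin: float = 5.0     # planted separation (>= 4-fold rule)
    atlas_noise_sd: float = 0.25       # lognormal sd of background levels
    # biomarker database
    db_coverage: float = 0.8           # fraction of pool genes with a qualifying record
    n_decoy_records: int = 50
    # cohort
    n_chow: int = 10
    n_hfd: int = 17
    liver_effect: float = 31.6         # histology fold change HFD/chow
    wat_effect: float = 9.1
    histology_noise_sd: float = 0.15   # lognormal within-group sd
    n_markers_per_tissue: int = 10     # planted expression markers
    target_rho: float = 0.8            # planted |Spearman| to histology
    nb_dispersion: float = 0.1
    depth_sd: float = 0.2              # lognormal sd of sample depth factors
    marker_base_mean: float = 200.0    # target-tissue baseline of planted markers
    plasma_target_r2: float = 0.68     # planted plasma-histology squared correlation
    count_noise: bool = True           # False: deterministic counts (noise off)

    def validate(self) -> "SynthConfig":
        if not 0.0 < self.immune_overlap <= 1.0:
            raise ValidationError(f"immune_overlap must be in (0, 1], got {self.immune_overlap}")
        if not 0.0 < self.db_coverage <= 1.0:
            raise ValidationError(f"db_coverage must be in (0, 1], got {self.db_coverage}")
        if self.liver_effect <= 1.0 or self.wat_effect <= 1.0:
            raise ValidationError("histology effects must exceed 1")
        if min(self.n_chow, self.n_hfd) < 3:
            raise ValidationError("group sizes must be >= 3")
        if not 0.0 < self.target_rho < 1.0:
            raise ValidationError("target_rho must be in (0, 1)")
        return self


@dataclass
class PlantedTruth:
    """Ground-truth labels for every synthetic gene."""

    genes: list = field(default_factory=list)
    uniprot: dict = field(default_factory=dict)            # gene -> accession
    tissue_genes: dict = field(default_factory=dict)       # tissue -> set of genes
    immune_genes: set = field(default_factory=set)
    enriched_tissue: dict = field(default_factory=dict)    # gene -> atlas tissue label
    marker_tissue: dict = field(default_factory=dict)      # gene -> tissue label
    marker_direction: dict = field(default_factory=dict)   # gene -> +1 / -1
    novelty: dict = field(default_factory=dict)            # gene -> novel/curated
    evidence_level: dict = field(default_factory=dict)     # gene -> 0..3
    whitelist: dict = field(default_factory=dict)          # tissue -> parent ids
    plasma_marker: str | None = None

    def markers(self, tissue: str) -> list[str]:
        return sorted(g for g, t in self.marker_tissue.items() if t == tissue)


def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(cfg.seed), spawn_key=(stream,)))


def _gene_names(cfg: SynthConfig) -> tuple[list[str], dict[str, str]]:
    """Deterministic gene universe with role-revealing marker names."""
    names = []
    for tissue in TISSUE_LABELS:
        prefix = "ADIMK" if tissue == "adipose" else "LIVMK"
        names += [f"{prefix}{i:02d}" for i in range(1, cfg.n_markers_per_tissue + 1)]
    n_bg = cfg.n_genes - len(names)
    names += [f"GENE{i:04d}" for i in range(1, n_bg + 1)]
    uniprot = {g: f"Q{i:06d}" for i, g in enumerate(names, start=1)}
    return names, uniprot


# ---------------------------------------------------------------------------
# ontology + annotations


def gen_ontology_and_annotations(
    cfg: SynthConfig,
) -> tuple[Ontology, list[GeneAnnotation], PlantedTruth]:
    """Acyclic DAG with keyword-named tissue parents, immune roots, and
    gene-term annotations with the configured immune overlap."""
    cfg.validate()
    rng = _rng(cfg, _STREAM_ONTOLOGY)
    truth = PlantedTruth()
    truth.genes, truth.uniprot = _gene_names(cfg)

    terms: list[OntologyTerm] = [OntologyTerm("GO:8000000", "biological_process")]
    root = "GO:8000000"
    next_id = [8000001]

    def new_term(name: str, parents) -> str:
        tid = f"GO:{next_id[0]:07d}"
        next_id[0] += 1
        terms.append(OntologyTerm(tid, name, parents=frozenset(parents)))
        return tid

    # immune roots with children
    immune_term_ids: list[str] = []
    for rid, rname in _IMMUNE_ROOT_NAMES.items():
        terms.append(OntologyTerm(rid, rname, parents=frozenset({root})))
        immune_term_ids.append(rid)
        for j in range(cfg.n_immune_children):
            immune_term_ids.append(new_term(f"{rname} subprocess {j + 1}", {rid}))

    # tissue parents + descendants; decoys match keywords but are not curated
    tissue_term_ids: dict[str, list[str]] = {}
    keyword_word = {"adipose": ["adipose", "adipocyte"], "liver": ["liver", "hepatic", "hepatocyte"]}
    for tissue in TISSUE_LABELS:
        words = keyword_word[tissue]
        parent_ids = []
        member_ids: list[str] = []
        for i in range(cfg.n_tissue_parents):
            word = words[i % len(words)]
            noun = _PARENT_NOUNS[i % len(_PARENT_NOUNS)]
            pid = new_term(f"{word} {noun}", {root})
            parent_ids.append(pid)
            member_ids.append(pid)
            level = [pid]
            for depth in range(cfg.ontology_depth):
                nxt = []
                for parent in level:
                    for b in range(cfg.ontology_branching):
                        cid = new_term(
                            f"{word} {noun} subprocess {depth + 1}.{b + 1}", {parent}
                        )
                        nxt.append(cid)
                        member_ids.append(cid)
                level = nxt
        for i in range(cfg.n_decoy_parents):
            new_term(f"embryonic {words[0]} {_PARENT_NOUNS[i]}", {root})
        truth.whitelist[tissue] = parent_ids
        tissue_term_ids[tissue] = member_ids
    # a couple of non-matching terms
    new_term("kidney development", {root})
    new_term("neuron differentiation", {root})

    ontology = Ontology(terms)

    # gene assignment
    pool = [g for g in truth.genes]
    markers = {t: [g for g in pool if g.startswith("ADIMK" if t == "adipose" else "LIVMK")]
               for t in TISSUE_LABELS}
    background = [g for g in pool if g.startswith("GENE")]
    n_extra = cfg.n_tissue_genes - cfg.n_markers_per_tissue
    if 2 * n_extra + cfg.n_immune_only_genes > len(background):
        raise ValidationError("n_genes too small for the requested tissue/immune pools")
    picks = rng.choice(len(background), size=2 * n_extra + cfg.n_immune_only_genes, replace=False)
    adipose_extra = [background[i] for i in picks[:n_extra]]
    liver_extra = [background[i] for i in picks[n_extra: 2 * n_extra]]
    immune_only = [background[i] for i in picks[2 * n_extra:]]

    annotations: list[GeneAnnotation] = []

    def annotate(gene: str, term: str, taxon: str = "taxon:9606") -> None:
        annotations.append(
            GeneAnnotation(gene=gene, term_id=term, uniprot=truth.uniprot[gene], taxon=taxon)
        )

    for tissue in TISSUE_LABELS:
        members = tissue_term_ids[tissue]
        genes = markers[tissue] + (adipose_extra if tissue == "adipose" else liver_extra)
        truth.tissue_genes[tissue] = set(genes)
        for gene in genes:
            n_terms = int(rng.integers(1, 4))
            for tid in rng.choice(members, size=min(n_terms, len(members)), replace=False):
                annotate(gene, str(tid))
            is_marker = gene in markers[tissue]
            if is_marker or rng.random() < cfg.immune_overlap:
                annotate(gene, str(rng.choice(immune_term_ids)))
                truth.immune_genes.add(gene)

    for gene in immune_only:
        annotate(gene, str(rng.choice(immune_term_ids)))
        truth.immune_genes.add(gene)

    # decoy annotations of the wrong taxon, filtered downstream
    for gene in background[:5]:
        annotate(gene, str(rng.choice(tissue_term_ids["liver"])), taxon="taxon:10090")

    for tissue in TISSUE_LABELS:
        for gene in markers[tissue]:
            truth.marker_tissue[gene] = tissue

    annotations.sort(key=lambda a: (a.gene, a.term_id, a.taxon))
    return ontology, annotations, truth


# ---------------------------------------------------------------------------
# atlas


def gen_tissue_atlas(cfg: SynthConfig, truth: PlantedTruth) -> list[TissueProfile]:
    """Cross-tissue expression table with planted enriched genes.

    Planted genes get at least ``atlas_fold_margin`` separation in their
    tissue; background profiles are compressed toward their geometric mean
    whenever random noise would let them clear the four-fold rule, so
    precision and recall of the planted set are exactly 1 at the default
    margin.
    """
    cfg.validate()
    rng = _rng(cfg, _STREAM_ATLAS)
    all_tissues = ["liver", "adipose tissue", "brain", "kidney", "heart", "lung"]
    tissues = all_tissues[: cfg.n_atlas_tissues]

    # choose planted enriched genes: markers first, then immune-only genes
    # (unique-addition material), then plain background
    planted: dict[str, list[str]] = {}
    immune_pool = sorted(
        truth.immune_genes - set(truth.marker_tissue) -
        truth.tissue_genes.get("adipose", set()) - truth.tissue_genes.get("liver", set())
    )
    bg_pool = sorted(
        set(truth.genes) - truth.immune_genes - set(truth.marker_tissue)
        - truth.tissue_genes.get("adipose", set()) - truth.tissue_genes.get("liver", set())
    )
    offset = 0
    for tissue in TISSUE_LABELS:
        n_rest = max(cfg.n_planted_enriched - cfg.n_markers_per_tissue, 0)
        n_imm = n_rest // 2
        n_bg = n_rest - n_imm
        chosen = (
            truth.markers(tissue)
            + immune_pool[offset: offset + n_imm]
            + bg_pool[offset: offset + n_bg]
        )
        offset += max(n_imm, n_bg)
        planted[tissue] = chosen
        for g in chosen:
            truth.enriched_tissue[g] = ATLAS_TISSUE[tissue]

    profiles = []
    for gene in truth.genes:
        base = float(np.exp(rng.normal(math.log(20.0), 0.5)))
        levels = {t: base * float(np.exp(rng.normal(0.0, cfg.atlas_noise_sd))) for t in tissues}
        target = truth.enriched_tissue.get(gene)
        if target is not None:
            others_max = max(v for t, v in levels.items() if t != target)
            levels[target] = cfg.atlas_fold_margin * others_max
        else:
            # compress so no single/group split can clear the fold rule
            vals = np.array(list(levels.values()))
            ratio = vals.max() / max(vals.min(), 1e-12)
            limit = 0.9 * 4.0
            if ratio >= limit:
                gm = float(np.exp(np.log(vals).mean()))
                c = math.log(limit) / math.log(ratio)
                levels = {t: gm * (v / gm) ** c for t, v in levels.items()}
        profiles.append(TissueProfile(gene=gene, uniprot=truth.uniprot[gene], levels=levels))
    return profiles


# ---------------------------------------------------------------------------
# biomarker database


_NOVELTY_PATTERNS = [
    (True, True, True),    # curated
    (True, True, False),   # novel
    (True, False, False),
    (False, False, False),
]

_OTHER_CONDITIONS = ("rheumatoid arthritis", "sepsis", "asthma")


def gen_biomarker_db(cfg: SynthConfig, truth: PlantedTruth) -> list[BiomarkerRecord]:
    """Blood-biomarker records: planted markers always qualify; a random
    fraction of the remaining pool genes qualifies; decoys carry a
    disqualifying substrate or evidence label."""
    cfg.validate()
    rng = _rng(cfg, _STREAM_BIOMARKER)
    records: list[BiomarkerRecord] = []
    diseases = list(DEFAULT_DISEASES)

    def qualifying(gene: str, pattern) -> BiomarkerRecord:
        cond_disease, analyzed, diagnostic = pattern
        conditions = set()
        if cond_disease:
            conditions |= {diseases[i] for i in rng.choice(len(diseases), size=2, replace=False)}
        else:
            conditions.add(_OTHER_CONDITIONS[int(rng.integers(len(_OTHER_CONDITIONS)))])
        evidence = ("early human studies", "late human studies", "recommended/approved")[
            int(rng.integers(3))
        ]
        substrate = ("plasma", "serum")[int(rng.integers(2))]
        return BiomarkerRecord(
            gene=gene,
            uniprot=truth.uniprot[gene],
            marker_type="proteome",
            substrate=substrate,
            evidence=evidence,
            conditions=frozenset(conditions),
            commonly_analyzed=analyzed,
            diagnostic_use=diagnostic,
        )

    markers = sorted(truth.marker_tissue)
    for i, gene in enumerate(markers):
        pattern = _NOVELTY_PATTERNS[i % 2]  # alternate curated / novel
        truth.novelty[gene] = "curated" if all(pattern) else "novel"
        records.append(qualifying(gene, pattern))

    pool = sorted(
        (truth.tissue_genes.get("adipose", set()) | truth.tissue_genes.get("liver", set())
         | truth.immune_genes) - set(markers)
    )
    for gene in pool:
        if rng.random() < cfg.db_coverage:
            pattern = _NOVELTY_PATTERNS[int(rng.integers(len(_NOVELTY_PATTERNS)))]
            truth.novelty[gene] = "curated" if all(pattern) else "novel"
            records.append(qualifying(gene, pattern))

    decoy_pool = [g for g in truth.genes if g not in truth.novelty]
    for gene in decoy_pool[: cfg.n_decoy_records]:
        bad = int(rng.integers(2))
        records.append(
            BiomarkerRecord(
                gene=gene,
                uniprot=truth.uniprot[gene],
                marker_type="proteome",
                substrate="urine" if bad == 0 else "plasma",
                evidence="preclinical studies" if bad == 1 else "early human studies",
                conditions=frozenset({_OTHER_CONDITIONS[0]}),
                commonly_analyzed=False,
                diagnostic_use=False,
            )
        )
    records.sort(key=lambda r: (r.gene, r.substrate, r.evidence))
    return records


# ---------------------------------------------------------------------------
# cohort


def _marker_slope(cfg: SynthConfig, effect: float) -> float:
    """Log-scale slope giving the target expression-histology Spearman.

    Planted log expression is (slope * z) + noise, with z the standardized
    log histology score and noise the log-scale NB sampling deviation
    ``sqrt(alpha + 1/mu)``. Because the cohort's histology scores form two
    well-separated diet clusters, ranks across clusters are always correct
    and the pooled Spearman is ``1 - K (1 - rho_within)`` with
    ``K = sum m(m^2-1) / (n(n^2-1))`` over the cluster sizes. The slope is
    therefore solved for the within-cluster correlation that makes the
    pooled Spearman hit the target, converting the Spearman target to a
    Pearson one with the Gaussian grade relation rho_s = (6/pi) asin(r/2).
    """
    n0, n1 = cfg.n_chow, cfg.n_hfd
    n = n0 + n1
    L = math.log(effect)
    p = n1 / n
    sd_total = math.sqrt(p * (1 - p) * L**2 + cfg.histology_noise_sd**2)
    z_within = cfg.histology_noise_sd / sd_total
    K = (n0 * (n0**2 - 1) + n1 * (n1**2 - 1)) / (n * (n**2 - 1))
    rho_within_s = 1.0 - (1.0 - cfg.target_rho) / K
    if rho_within_s <= 0.0:
        # separation alone already exceeds the target; pooled mapping fallback
        rho = cfg.target_rho
        sigma = math.sqrt(cfg.nb_dispersion + 1.0 / cfg.marker_base_mean)
        return sigma * rho / math.sqrt(1.0 - rho**2)
    rho_within_p = 2.0 * math.sin(math.pi * rho_within_s / 6.0)
    sigma = math.sqrt(cfg.nb_dispersion + 1.0 / cfg.marker_base_mean)
    return sigma * rho_within_p / math.sqrt(1.0 - rho_within_p**2) / z_within


def gen_cohort(
    cfg: SynthConfig, truth: PlantedTruth
) -> tuple[dict[str, CountMatrix], list[CohortSample]]:
    """Counts per tissue plus per-animal metadata/histology/plasma."""
    cfg.validate()
    rng = _rng(cfg, _STREAM_COHORT)
    n = cfg.n_chow + cfg.n_hfd
    groups = np.array(["chow"] * cfg.n_chow + ["HFD"] * cfg.n_hfd)
    animals = [f"{g.lower()}{i + 1:02d}" for i, g in enumerate(groups)]

    effects = {"liver": cfg.liver_effect, "WAT": cfg.wat_effect}
    baselines = {"liver": 1.0, "WAT": 2.0}
    histology = {}
    for tissue in ("liver", "WAT"):
        noise = rng.normal(0.0, cfg.histology_noise_sd, size=n)
        scores = baselines[tissue] * np.exp(noise)
        scores[groups == "HFD"] *= effects[tissue]
        histology[tissue] = scores

    alpha = cfg.nb_dispersion
    gene_base = np.exp(rng.normal(math.log(100.0), 1.0, size=len(truth.genes)))
    gene_index = {g: i for i, g in enumerate(truth.genes)}

    matrices: dict[str, CountMatrix] = {}
    for tissue in ("liver", "WAT"):
        tissue_label = "liver" if tissue == "liver" else "adipose"
        slope = _marker_slope(cfg, effects[tissue])
        if cfg.count_noise:
            depth = np.exp(rng.normal(0.0, cfg.depth_sd, size=n))
        else:
            depth = np.ones(n)
        z = np.log(histology[tissue])
        z = (z - z.mean()) / z.std()
        mu = np.outer(gene_base, depth)
        for gene, t in truth.marker_tissue.items():
            i = gene_index[gene]
            direction = truth.marker_direction.setdefault(
                gene, 1 if (int(gene[-2:]) % 2 == 1) else -1
            )
            if t == tissue_label:
                mu[i] = cfg.marker_base_mean * depth * np.exp(direction * slope * z)
            else:
                mu[i] = (cfg.marker_base_mean / 10.0) * depth  # flat in the other tissue
        if cfg.count_noise:
            p = 1.0 / (1.0 + alpha * mu)
            counts = rng.negative_binomial(1.0 / alpha, p)
        else:
            # noise off: counts follow the mean exactly (x1024 keeps the
            # monotone link intact through integer storage)
            counts = np.rint(mu * 1024.0).astype(np.int64)
        cols = [f"{a}_{tissue}" for a in animals]
        matrices[tissue] = CountMatrix(
            counts=pd.DataFrame(counts, index=list(truth.genes), columns=cols), tissue=tissue
        )

    # plasma analyte tracking liver histology linearly on the raw scale;
    # the noise variance is set from the realized signal variance so the
    # squared correlation lands on the configured target in expectation
    liver_markers = truth.markers("liver")
    truth.plasma_marker = liver_markers[0] if liver_markers else "SAA"
    hist = histology["liver"]
    signal = 10.0 * hist
    r2 = cfg.plasma_target_r2
    sigma_eps = float(signal.std()) * math.sqrt((1.0 - r2) / r2)
    plasma = 300.0 + signal + rng.normal(0.0, sigma_eps, size=n)
    plasma = np.clip(plasma, 0.0, None)

    samples = []
    for tissue in ("liver", "WAT"):
        for j, animal in enumerate(animals):
            samples.append(
                CohortSample(
                    sample_id=f"{animal}_{tissue}",
                    group=str(groups[j]),
                    tissue=tissue,
                    histology_score=float(histology[tissue][j]),
                    plasma={"inflammarker": float(plasma[j])},
                )
            )
    return matrices, samples


# ---------------------------------------------------------------------------
# evidence


def gen_evidence(cfg: SynthConfig, truth: PlantedTruth) -> list[EvidenceRecord]:
    """Literature-evidence booleans for the planted markers.

    The pattern cycles confirmed / confirmed / putative / possible, echoing
    the preponderance of fully confirmed markers in curated literature."""
    patterns = [
        (True, True, True),
        (True, True, True),
        (True, True, False),
        (True, False, False),
    ]
    records = []
    for tissue in TISSUE_LABELS:
        for i, gene in enumerate(truth.markers(tissue)):
            ci, cii, ciii = patterns[i % len(patterns)]
            rec = EvidenceRecord(
                gene=gene,
                tissue=tissue,
                cond_mechanism=ci,
                cond_tissue_disease=cii,
                cond_metabolic=ciii,
                notes="synthetic curation",
            )
            truth.evidence_level[gene] = rec.level
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# truth table + run config


def ground_truth_table(truth: PlantedTruth) -> pd.DataFrame:
    """One row per gene with every planted label, deterministically ordered."""
    rows = []
    for gene in truth.genes:
        rows.append(
            {
                "gene": gene,
                "uniprot": truth.uniprot[gene],
                "adipose_gene": gene in truth.tissue_genes.get("adipose", set()),
                "liver_gene": gene in truth.tissue_genes.get("liver", set()),
                "immune": gene in truth.immune_genes,
                "enriched_tissue": truth.enriched_tissue.get(gene, ""),
                "marker_tissue": truth.marker_tissue.get(gene, ""),
                "marker_direction": truth.marker_direction.get(gene, 0),
                "novelty": truth.novelty.get(gene, ""),
                "evidence_level": truth.evidence_level.get(gene, -1),
            }
        )
    return pd.DataFrame(rows)


def run_config_for(cfg: SynthConfig, truth: PlantedTruth) -> RunConfig:
    """RunConfig matching the generated inputs (whitelist from truth)."""
    return RunConfig(
        whitelist={t: list(truth.whitelist.get(t, [])) for t in TISSUE_LABELS},
        seed=cfg.seed,
        thresholds=Thresholds(),
    ).validate()
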