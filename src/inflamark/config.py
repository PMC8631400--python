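"""Run configuration and decision thresholds.

Every tunable of the pipeline lives here: keyword lists used to find
tissue-related ontology terms, the identifiers of the immune-process root
terms, the whitelist that stands in for manual curation, the species/object
filters applied to gene annotations, and the numeric thresholds (FDR cutoff,
Spearman cutoff, tissue-specificity fold, detection floor).

Configuration round-trips through a flat YAML document so a run is fully
described by one file plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml

from .errors import ValidationError

#: GO accessions of the immune-process roots: immune system process,
#: inflammatory response, cytokine production.
DEFAULT_IMMUNE_ROOTS = ("GO:0002376", "GO:0006954", "GO:0001816")

#: Low-grade-inflammation related diseases/conditions used by the novelty
#: rubric and by the diagnostic-use criterion.
DEFAULT_DISEASES = (
    "metabolic syndrome",
    "type 2 diabetes",
    "hyperglycemia",
    "prediabetes",
    "insulin resistance",
    "glucose intolerance",
    "dyslipidemia",
    "hyperlipidemia",
    "hypertriglyceridemia",
    "atherosclerosis",
)

DEFAULT_KEYWORDS = {
    "adipose": ("adipose", "adipocyte"),
    "liver": ("liver", "hepatic", "hepatocyte"),
}

#: Evidence labels in the biomarker database that qualify a record as a
#: human blood protein biomarker.
DEFAULT_ACCEPTED_EVIDENCE = (
    "early human studies",
    "late human studies",
    "recommended/approved",
)

DEFAULT_SUBSTRATES = ("plasma", "serum")


@dataclass
class Thresholds:
    """Numeric decision thresholds applied across the pipeline.

    fdr_cutoff
        Benjamini–Hochberg adjusted p-value below which a gene counts as
        differentially expressed (default 0.01).
    rho_cutoff
        Spearman correlation magnitude that must be strictly exceeded for an
        expression–histology relation to count (default 0.60; the closed
        range [-0.60, 0.60] is "no relation").
    fold_specificity
        Minimum fold separation for a tissue-enriched/group-enriched call in
        the expression atlas (default 4.0, inclusive).
    group_size_min, group_size_max
        Allowed size of a group-enriched tissue set (default 2..5).
    detect_min_norm_count
        Mean normalized count a gene must reach in at least one diet group of
        the target tissue to count as detected (default 1.0).
    """

    fdr_cutoff: float = 0.01
    rho_cutoff: float = 0.60
    fold_specificity: float = 4.0
    group_size_min: int = 2
    group_size_max: int = 5
    detect_min_norm_count: float = 1.0

    def validate(self) -> "Thresholds":
        if not 0.0 < self.fdr_cutoff < 1.0:
            raise ValidationError(f"fdr_cutoff must be in (0, 1), got {self.fdr_cutoff}")
        if not 0.0 < self.rho_cutoff < 1.0:
            raise ValidationError(f"rho_cutoff must be in (0, 1), got {self.rho_cutoff}")
        if not self.fold_specificity > 1.0:
            raise ValidationError(
                f"fold_specificity must exceed 1, got {self.fold_specificity}"
            )
        if not 2 <= self.group_size_min <= self.group_size_max <= 5:
            raise ValidationError(
                "group size range must lie within 2..5, got "
                f"{self.group_size_min}..{self.group_size_max}"
            )
        if self.detect_min_norm_count < 0:
            raise ValidationError("detect_min_norm_count must be >= 0")
        return self


@dataclass
class RunConfig:
    """Full description of a pipeline run.

    ``keywords`` maps a tissue label to the search words matched against
    ontology term names; ``whitelist`` maps a tissue label to the curated
    parent-term accessions (the reproducible stand-in for manual curation).
    """

    keywords: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_KEYWORDS.items()}
    )
    immune_roots: Sequence[str] = field(default_factory=lambda: list(DEFAULT_IMMUNE_ROOTS))
    whitelist: Mapping[str, Sequence[str]] = field(default_factory=dict)
    species: str = "taxon:9606"
    object_type: str = "protein"
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    diseases: Sequence[str] = field(default_factory=lambda: list(DEFAULT_DISEASES))
    accepted_evidence: Sequence[str] = field(
        default_factory=lambda: list(DEFAULT_ACCEPTED_EVIDENCE)
    )
    marker_type: str = "proteome"
    substrates: Sequence[str] = field(default_factory=lambda: list(DEFAULT_SUBSTRATES))
    # "max": compare against the highest non-group tissue (strict rule);
    # "mean": compare against the average of the other tissues.
    specificity_denominator: str = "max"
    # Which samples enter the target-vs-other-tissue expression comparison.
    criterion_c_samples: str = "hfd"  # or "all"
    # Which animals enter the expression-histology correlation.
    correlation_samples: str = "pooled"  # or "hfd"
    # Whether potentially novel candidates proceed to verification.
    verify_novel: bool = True
    # Atlas column name per tissue label.
    atlas_tissue_labels: Mapping[str, str] = field(
        default_factory=lambda: {"adipose": "adipose tissue", "liver": "liver"}
    )
    # Cohort tissue code per tissue label.
    cohort_tissue_labels: Mapping[str, str] = field(
        default_factory=lambda: {"adipose": "WAT", "liver": "liver"}
    )
    # Optional gene -> biological-function-category mapping for the report.
    function_categories: Mapping[str, str] = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        for tissue, words in self.keywords.items():
            if not words:
                raise ValidationError(f"keyword list for {tissue!r} is empty")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ValidationError(f"seed must be a non-negative integer, got {self.seed!r}")
        if self.specificity_denominator not in ("max", "mean"):
            raise ValidationError("specificity_denominator must be 'max' or 'mean'")
        if self.criterion_c_samples not in ("hfd", "all"):
            raise ValidationError("criterion_c_samples must be 'hfd' or 'all'")
        if self.correlation_samples not in ("pooled", "hfd"):
            raise ValidationError("correlation_samples must be 'pooled' or 'hfd'")
        self.thresholds.validate()
        return self

    # -- YAML round trip ---------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        thr = Thresholds(**doc.pop("thresholds", {}))
        cfg = cls(thresholds=thr, **doc)
        return cfg.validate()
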