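"""Cohort verification of candidate biomarkers.

Given per-tissue count matrices and per-animal histology scores from a
chow vs high-fat-diet cohort, a candidate passes verification in its target
tissue when (a) it is detected (mean normalized count above a floor in at
least one diet group of the target tissue), (b) it is differentially
expressed between diets at the FDR cutoff, and (c) its expression is higher
in the target tissue than in the other tissue. Verified candidates are then
correlated (Spearman) per animal against the tissue's histological
inflammation score, and assigned to a tissue when the correlation passes
the cutoff in that tissue only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .de import normalize_counts, size_factors
from .errors import ValidationError

GROUPS = ("chow", "HFD")
TISSUES = ("liver", "WAT")

HEPATIC = "hepatic"
ADIPOSE = "adipose"
BOTH = "both"
NONE = "none"


@dataclass
class CountMatrix:
    """Gene x sample raw counts for one tissue."""

    counts: pd.DataFrame
    tissue: str

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in count matrix")
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValidationError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValidationError("counts must be integers")


@dataclass
class CohortSample:
    """One tissue sample of one animal, with its histology score.

    The histology score is inflammatory aggregates per mm^2 for liver and
    crown-like structures per 1000 adipocytes for WAT. ``plasma`` maps
    analyte name to the animal's plasma concentration.
    """

    sample_id: str
    group: str
    tissue: str
    histology_score: float
    plasma: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValidationError(
                f"{self.sample_id}: unknown group {self.group!r}; expected one of {GROUPS}"
            )
        if self.tissue not in TISSUES:
            raise ValidationError(
                f"{self.sample_id}: unknown tissue {self.tissue!r}; expected one of {TISSUES}"
            )
        if self.histology_score < 0:
            raise ValidationError(f"{self.sample_id}: histology score must be >= 0")


def _samples_frame(samples: Sequence[CohortSample], tissue: str) -> pd.DataFrame:
    rows = [
        {"sample_id": s.sample_id, "group": s.group, "histology_score": s.histology_score}
        for s in samples
        if s.tissue == tissue
    ]
    if not rows:
        raise ValidationError(f"no samples for tissue {tissue!r}")
    return pd.DataFrame(rows).set_index("sample_id")


def select_verified_candidates(
    de_results: Mapping[str, pd.DataFrame],
    normalized: Mapping[str, pd.DataFrame],
    samples: Sequence[CohortSample],
    candidate_genes: set[str],
    target_tissue: str,
    *,
    fdr_cutoff: float = 0.01,
    detect_min_norm_count: float = 1.0,
    criterion_c_samples: str = "hfd",
) -> set[str]:
    """Candidates passing criteria (a)-(c) for ``target_tissue``.

    ``de_results`` and ``normalized`` are keyed by cohort tissue ("liver",
    "WAT"); criterion (c) compares mean normalized expression in the target
    vs the non-target tissue over the inflamed (HFD) animals by default,
    each tissue normalized independently.
    """
    if target_tissue not in normalized or target_tissue not in de_results:
        raise ValidationError(f"tissue {target_tissue!r} missing from cohort data")
    other = [t for t in TISSUES if t != target_tissue][0]
    meta_t = _samples_frame(samples, target_tissue)
    q_t = normalized[target_tissue]
    de_t = de_results[target_tissue]

    if criterion_c_samples == "hfd":
        cols_t = [c for c in q_t.columns if meta_t.loc[c, "group"] == "HFD"]
    else:
        cols_t = list(q_t.columns)

    kept = set()
    for gene in sorted(candidate_genes):
        g = gene.upper()
        if g not in q_t.index:
            continue  # no murine analog detected in the target tissue
        row = q_t.loc[g]
        # (a) detected in >= 1 diet group of the target tissue
        group_means = row.groupby(meta_t.loc[row.index, "group"].values).mean()
        if not (group_means >= detect_min_norm_count).any():
            continue
        # (b) differentially expressed at the FDR cutoff
        padj = de_t.loc[g, "padj"] if g in de_t.index else np.nan
        if not (np.isfinite(padj) and padj < fdr_cutoff):
            continue
        # (c) higher expression in the target than the non-target tissue
        target_mean = q_t.loc[g, cols_t].mean()
        if other in normalized and g in normalized[other].index:
            q_o = normalized[other]
            meta_o = _samples_frame(samples, other)
            if criterion_c_samples == "hfd":
                cols_o = [c for c in q_o.columns if meta_o.loc[c, "group"] == "HFD"]
            else:
                cols_o = list(q_o.columns)
            other_mean = q_o.loc[g, cols_o].mean()
        else:
            other_mean = 0.0
        if target_mean > other_mean:
            kept.add(g)
    return kept


def correlate_expression_to_histology(
    normalized: pd.DataFrame,
    samples: Sequence[CohortSample],
    tissue: str,
    *,
    rho_cutoff: float = 0.60,
    subset: str = "pooled",
) -> pd.DataFrame:
    """Per-gene Spearman correlation of normalized expression with the
    tissue's histology score across animals (both diet groups pooled by
    default). ``passes`` is strict: |rho| > cutoff.

    Genes with constant expression get NaN rho and do not pass.
    """
    meta = _samples_frame(samples, tissue)
    cols = [c for c in normalized.columns if c in meta.index]
    if subset == "hfd":
        cols = [c for c in cols if meta.loc[c, "group"] == "HFD"]
    if len(cols) < 3:
        raise ValidationError(f"need >= 3 paired animals, got {len(cols)}")
    expr = normalized[cols].to_numpy(dtype=float)
    scores = meta.loc[cols, "histology_score"].to_numpy(dtype=float)
    if np.all(scores == scores[0]):
        raise ValidationError("histology scores are constant; correlation undefined")

    score_ranks = sps.rankdata(scores)
    expr_ranks = sps.rankdata(expr, axis=1)
    er = expr_ranks - expr_ranks.mean(axis=1, keepdims=True)
    sr = score_ranks - score_ranks.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (er @ sr) / np.sqrt((er**2).sum(axis=1) * (sr**2).sum())
    constant = np.all(expr == expr[:, :1], axis=1)
    rho = np.where(constant, np.nan, rho)
    passes = np.where(np.isfinite(rho), np.abs(rho) > rho_cutoff, False)
    return pd.DataFrame(
        {
            "tissue": tissue,
            "rho": rho,
            "n": len(cols),
            "passes": passes.astype(bool),
        },
        index=normalized.index,
    )


def classify_tissue_marker(liver_passes: bool, wat_passes: bool) -> str:
    """Tissue assignment from the two correlation outcomes."""
    if liver_passes and not wat_passes:
        return HEPATIC
    if wat_passes and not liver_passes:
        return ADIPOSE
    if liver_passes and wat_passes:
        return BOTH
    return NONE


def classify_markers(
    corr_liver: pd.DataFrame, corr_wat: pd.DataFrame
) -> pd.DataFrame:
    """Join the per-tissue correlation tables and classify each gene."""
    genes = corr_liver.index.union(corr_wat.index)
    rows = []
    for g in genes:
        lp = bool(corr_liver.loc[g, "passes"]) if g in corr_liver.index else False
        wp = bool(corr_wat.loc[g, "passes"]) if g in corr_wat.index else False
        rows.append(
            {
                "gene": g,
                "rho_liver": corr_liver.loc[g, "rho"] if g in corr_liver.index else np.nan,
                "rho_wat": corr_wat.loc[g, "rho"] if g in corr_wat.index else np.nan,
                "label": classify_tissue_marker(lp, wp),
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def cohort_statistics(samples: Sequence[CohortSample]) -> pd.DataFrame:
    """Histology fold changes (HFD over chow) and group tests per tissue."""
    from .stats import group_fold_change, mann_whitney_u

    rows = []
    for tissue in TISSUES:
        meta = _samples_frame(samples, tissue)
        scores = meta["histology_score"].to_numpy(dtype=float)
        groups = meta["group"].to_numpy()
        fc = group_fold_change(scores, groups)
        _, p = mann_whitney_u(scores[groups == "HFD"], scores[groups == "chow"])
        rows.append(
            {
                "tissue": tissue,
                "n_chow": int((groups == "chow").sum()),
                "n_hfd": int((groups == "HFD").sum()),
                "fold_change": fc,
                "mwu_p": p,
            }
        )
    return pd.DataFrame(rows).set_index("tissue")


__all__ = [
    "CountMatrix",
    "CohortSample",
    "select_verified_candidates",
    "correlate_expression_to_histology",
    "classify_tissue_marker",
    "classify_markers",
    "cohort_statistics",
    "normalize_counts",
    "size_factors",
]
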