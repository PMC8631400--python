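"""Rank statistics and cohort summary statistics.

Thin, contract-enforcing wrappers around scipy/statsmodels: Spearman rank
correlation (mean ranks for ties), Benjamini–Hochberg adjustment,
Mann–Whitney U (exact for small samples, tie/continuity-corrected normal
approximation otherwise), group fold change of means, and squared Pearson
correlation for plasma-marker/histology relations.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConstantInputError, ValidationError

#: sample-size bound below which the Mann-Whitney p-value is computed by
#: exact enumeration of rank configurations
EXACT_MWU_MAX_N = 12


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d and of equal length")
    if x.size < 3:
        raise ValidationError(f"need n >= 3 pairs, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("spearman correlation is undefined for a constant vector")
    return float(sps.spearmanr(x, y).statistic)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Returns ``(U, p)`` where U counts pairs won by ``x``. The p-value is by
    exact enumeration when ``len(x) + len(y) <= 12``, else by the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if x.size + y.size <= EXACT_MWU_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def group_fold_change(values: Sequence[float], groups: Sequence[str]) -> float:
    """Ratio of group means, HFD over chow."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    chow = values[groups == "chow"]
    hfd = values[groups == "HFD"]
    if chow.size == 0 or hfd.size == 0:
        raise ValidationError("need both chow and HFD values")
    if chow.mean() <= 0:
        raise ValidationError("fold change undefined: chow mean is not positive")
    return float(hfd.mean() / chow.mean())


def plasma_marker_r2(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Squared Pearson correlation with its two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need paired values with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("pearson correlation is undefined for a constant vector")
    res = sps.pearsonr(x, y)
    return float(res.statistic**2), float(res.pvalue)
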