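"""Group statistics: Wilcoxon rank-sum comparisons, Bonferroni and
Benjamini-Hochberg corrections, and two-step trial-to-subject averaging."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "TwoStepAverage",
    "two_step_average",
    "ranksum_compare",
    "bonferroni",
    "fdr_bh",
]


@dataclass
class GroupComparison:
    """One two-group comparison with raw and (optionally) corrected inference."""

    label_a: str
    label_b: str
    statistic: float
    p_raw: float
    n_a: int
    n_b: int
    p_adjusted: float | None = None
    reject: bool | None = None
    method: str = "ranksum"


@dataclass
class TwoStepAverage:
    subject_means: pd.Series
    group_mean: float


def two_step_average(values, subjects) -> TwoStepAverage:
    """Average across trials per subject, then across subjects.

    Subjects are weighted equally regardless of their trial counts.  Subjects
    whose values are all missing are excluded with a warning.
    """
    s = pd.Series(np.asarray(values, dtype=float),
                  index=pd.Index(subjects, name="subject"))
    means = s.groupby(level="subject").mean()
    empty = means[means.isna()].index.tolist()
    if empty:
        warnings.warn(f"excluding subjects with no valid trials: {empty}")
        means = means.dropna()
    if means.empty:
        raise ValueError("no subject with valid trials")
    return TwoStepAverage(subject_means=means, group_mean=float(means.mean()))


def ranksum_compare(
    group_a,
    group_b,
    label_a: str = "a",
    label_b: str = "b",
    exact_max_n: int = 25,
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test.

    Uses the exact null distribution for small samples (both groups at most
    ``exact_max_n`` and no ties), otherwise the tie-corrected normal
    approximation.  The statistic reported is the rank sum W of group a.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations tied; p = 1")
        w = float(sp_stats.rankdata(pooled)[: len(a)].sum())
        return GroupComparison(label_a, label_b, w, 1.0, len(a), len(b))
    method = "exact" if (max(len(a), len(b)) <= exact_max_n and not has_ties) else "asymptotic"
    res = sp_stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    w = float(res.statistic + len(a) * (len(a) + 1) / 2.0)  # U -> rank sum
    return GroupComparison(label_a, label_b, w, float(res.pvalue),
                           len(a), len(b))


def bonferroni(pvals, alpha: float = 0.05, k: int | None = None) -> np.ndarray:
    """Reject where p < alpha / k (k defaults to the number of tests)."""
    p = np.asarray(pvals, dtype=float)
    if k is None:
        k = len(p)
    if k < 1:
        raise ValueError("k must be >= 1")
    return p < alpha / k


def fdr_bh(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns (reject flags, adjusted p-values).  The boundary case
    p(i) == i*q/m is rejected (the step-up uses <=).
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj
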