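"""Cohort-level statistics: rank tests, Pearson correlation, linear fits.

Two-sided nonparametric tests throughout — the Wilcoxon rank-sum
(Mann-Whitney) test for independent cohorts and the Wilcoxon signed-rank
test for paired measures on the same rosettes — plus Pearson correlation
and ordinary least-squares fits with vertical signed residuals
(positive residual = measure larger than the reference fit predicts;
for RS, reduced radial organization).
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats as sps


@dataclasses.dataclass
class LinearModel:
    slope: float
    intercept: float
    fitted_on: str = ""

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclasses.dataclass
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    fold_change: float | None = None


def linear_fit(x, y, fitted_on: str = "") -> LinearModel:
    """Ordinary least-squares line y = slope * x + intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(np.unique(x)) < 2:
        raise ValueError("linear fit needs >= 2 points with distinct x")
    res = sps.linregress(x, y)
    return LinearModel(slope=float(res.slope), intercept=float(res.intercept),
                       fitted_on=fitted_on)


def signed_residuals(x, y, model: LinearModel) -> np.ndarray:
    """Vertical signed distances y - (slope * x + intercept).

    Zero means a perfect fit; for RS vs rosette size, positive values
    indicate reduced radial organization relative to the reference group.
    """
    return np.asarray(y, dtype=float) - model.predict(x)


def rank_sum_test(a, b) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact null distribution for small tie-free samples, normal
    approximation with midranks and tie correction otherwise.  The fold
    change is mean(a) / mean(b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups need >= 1 value")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    fold = float(a.mean() / b.mean()) if b.mean() != 0 else None
    return GroupComparison("wilcoxon_rank_sum", float(res.statistic),
                           float(res.pvalue), fold)


def sign_rank_test(paired_a, paired_b) -> GroupComparison:
    """Two-sided Wilcoxon signed-rank test on paired measures."""
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("paired samples need equal length >= 1")
    diff = a - b
    fold = float(a.mean() / b.mean()) if b.mean() != 0 else None
    if np.all(diff == 0):  # no information against the null
        return GroupComparison("wilcoxon_sign_rank", 0.0, 1.0, fold)
    res = sps.wilcoxon(a, b, alternative="two-sided")
    return GroupComparison("wilcoxon_sign_rank", float(res.statistic),
                           float(res.pvalue), fold)


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation and its two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("pearson needs >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson undefined for constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
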