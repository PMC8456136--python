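"""Scalar group comparisons used across treatments and behaviours.

Thin, uniformly-typed wrappers around the standard tests — Kruskal–
Wallis with Dunn's post hoc, Brown–Forsythe, paired t, Spearman,
Pearson chi-square independence — plus Bonferroni correction.  Every
result comes back as a :class:`TestResult` so downstream tables carry
the statistic, df, p and adjusted p in one schema.  Most of the data
these tests meet (activity levels, period samples) are non-normal with
unequal variances, hence the rank-based defaults and median-centred
variance test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "brown_forsythe",
    "paired_t",
    "spearman",
    "chi_square_independence",
    "bonferroni",
    "bonferroni_alpha",
    "lower_median",
]


@dataclass(frozen=True)
class TestResult:
    statistic_name: str
    value: float
    df: float | tuple
    p: float
    adjusted_p: float | None = None
    n: tuple | None = None
    comparison: str | None = None


def lower_median(values) -> float:
    """Exact order-statistic median: the lower of the two middle values
    for even n (no interpolation ambiguity)."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    return float(v[(v.size - 1) // 2])


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal–Wallis H test (midranks, tie-corrected), chi-square p."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(gs)
    if pooled.size < 3:
        raise ValueError("need total n >= 3")
    if np.ptp(pooled) == 0:
        return TestResult("H", 0.0, len(gs) - 1, 1.0, n=tuple(g.size for g in gs))
    h, p = stats.kruskal(*gs)
    return TestResult("H", float(h), len(gs) - 1, float(p), n=tuple(g.size for g in gs))


def dunn_posthoc(
    groups: Sequence, adjustment: str = "bonferroni", labels=None
) -> list[TestResult]:
    """Dunn's pairwise post hoc comparisons after a Kruskal–Wallis test.

    Pairwise z statistics from pooled midranks with the tie correction
    ``1 - sum(t^3 - t) / (N^3 - N)``; p-values are two-sided normal and
    adjusted with Bonferroni (default) or left raw ("none").
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    k = len(gs)
    if k < 2:
        raise ValueError("need at least two groups")
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    pooled = np.concatenate(gs)
    n_total = pooled.size
    ranks = stats.rankdata(pooled, method="average")
    mean_ranks = []
    start = 0
    for g in gs:
        mean_ranks.append(ranks[start : start + g.size].mean())
        start += g.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (n_total - 1)) / 12.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    m = k * (k - 1) // 2
    out: list[TestResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(base_var * (1.0 / gs[i].size + 1.0 / gs[j].size))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            adj = p if adjustment == "none" else min(1.0, m * p)
            out.append(
                TestResult(
                    "z_Dunn",
                    float(z),
                    np.inf,
                    float(p),
                    adjusted_p=float(adj),
                    n=(gs[i].size, gs[j].size),
                    comparison=f"{labels[i]} vs {labels[j]}",
                )
            )
    return out


def brown_forsythe(*groups) -> TestResult:
    """Brown–Forsythe equality-of-variance test (ANOVA on |x - median|)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with n >= 2 each")
    f, p = stats.levene(*gs, center="median")
    df = (len(gs) - 1, sum(g.size for g in gs) - len(gs))
    return TestResult(
        "F_BrownForsythe", float(f), df, float(p), n=tuple(g.size for g in gs)
    )


def paired_t(x, y) -> TestResult:
    """Paired t-test on within-individual differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need equal-length samples with n >= 2")
    d = x - y
    if np.ptp(d) == 0:
        # zero variance of differences: identical vectors are a clean null,
        # a constant nonzero shift is evidence beyond any finite t
        if d[0] == 0:
            return TestResult("t_paired", 0.0, x.size - 1, 1.0, n=(x.size,))
        return TestResult(
            "t_paired", np.inf if d[0] > 0 else -np.inf, x.size - 1, 0.0, n=(x.size,)
        )
    t, p = stats.ttest_rel(x, y)
    return TestResult("t_paired", float(t), x.size - 1, float(p), n=(x.size,))


def spearman(x, y) -> TestResult:
    """Spearman rank-order correlation (midranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need equal-length samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank correlation undefined")
    r, p = stats.spearmanr(x, y)
    return TestResult("r_s", float(r), x.size - 2, float(p), n=(x.size,))


def chi_square_independence(table) -> TestResult:
    """Pearson chi-square test of independence on a 2-D count table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("need a 2-D count table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal: expected counts undefined")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return TestResult("chi2", float(chi2), int(df), float(p))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, m * p)."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * p)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Family-wise alpha split across m comparisons."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
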