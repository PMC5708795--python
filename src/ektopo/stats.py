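"""The study's statistical battery.

Nonparametric two-group and paired comparisons (Mann-Whitney U, Wilcoxon
signed rank), the k-group Kruskal-Wallis test with Dunn's multiple
comparisons, Pearson's chi-square for contingency tables, and Pearson
correlation. Standard tests delegate to scipy.stats; Dunn's post hoc is
implemented here (rank-based z statistics with tie correction, optional
Bonferroni adjustment capped at 1, matching how published pairwise p-values
of 1.000 arise).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "CorrelationResult",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "kruskal_wallis",
    "dunn_posthoc",
    "chi2_test",
    "pearson_r",
]

EXACT_MWU_MAX_N = 8  # exact null enumeration up to this per-group size
EXACT_WILCOXON_MAX_N = 12


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    group_labels: tuple[str, ...]
    n: tuple[int, ...]
    adjusted: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        if any(k < 1 for k in self.n):
            raise ValueError("each group must have n >= 1")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between two variables."""

    variable_pair: tuple[str, str]
    r: float
    p_value: float
    n: int = 0

    def __post_init__(self) -> None:
        if abs(self.r) > 1.0 + 1e-12:
            raise ValueError("|r| must be <= 1")


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    return x


def mann_whitney_u(x, y, labels: tuple[str, str] = ("x", "y")) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when both groups have at most 8 observations
    and there are no ties; otherwise the normal approximation with tie
    correction (and continuity correction).
    """
    x, y = _clean(x), _clean(y)
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (len(x) <= EXACT_MWU_MAX_N and len(y) <= EXACT_MWU_MAX_N and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return ComparisonResult(
        test_name="mann-whitney-u",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        group_labels=labels,
        n=(len(x), len(y)),
    )


def wilcoxon_signed_rank(pre, post, labels: tuple[str, str] = ("pre", "post")) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon's original convention); exact
    p for at most 12 nonzero differences without ties, else the normal
    approximation.
    """
    pre, post = _clean(pre), _clean(post)
    if len(pre) != len(post):
        raise ValueError("paired samples must have equal length")
    diff = post - pre
    nz = diff[diff != 0]
    if nz.size == 0:
        raise ValueError("degenerate: all paired differences are zero")
    no_ties = np.unique(np.abs(nz)).size == nz.size
    method = "exact" if (nz.size <= EXACT_WILCOXON_MAX_N and no_ties) else "approx"
    res = sps.wilcoxon(pre, post, zero_method="wilcox", method=method)
    return ComparisonResult(
        test_name="wilcoxon-signed-rank",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        group_labels=labels,
        n=(len(pre), len(post)),
    )


def kruskal_wallis(groups, labels: tuple[str, ...] | None = None) -> ComparisonResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square p on k-1 df)."""
    groups = [_clean(g) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = labels or tuple(f"g{i}" for i in range(len(groups)))
    res = sps.kruskal(*groups)
    return ComparisonResult(
        test_name="kruskal-wallis",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_labels=labels,
        n=tuple(len(g) for g in groups),
    )


def dunn_posthoc(
    groups, labels: tuple[str, ...] | None = None, adjust: str = "bonferroni"
) -> list[ComparisonResult]:
    """Dunn's pairwise multiple-comparison test after Kruskal-Wallis.

    For groups i, j with mean ranks Ri, Rj over the pooled ranking of all
    N observations: ``z = (Ri - Rj) / sqrt((N(N+1)/12 - T)(1/ni + 1/nj))``
    where ``T = sum(t^3 - t) / (12 (N - 1))`` corrects for ties. Two-sided
    normal p-values, optionally Bonferroni-multiplied by the number of
    pairs and capped at 1.
    """
    if adjust not in ("none", "bonferroni"):
        raise ValueError("adjust must be 'none' or 'bonferroni'")
    groups = [_clean(g) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = labels or tuple(f"g{i}" for i in range(len(groups)))
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    offsets = np.cumsum([0] + [len(g) for g in groups])
    mean_ranks = [ranks[offsets[i]: offsets[i + 1]].mean() for i in range(len(groups))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    variance = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(groups) * (len(groups) - 1) // 2
    out = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        ni, nj = len(groups[i]), len(groups[j])
        se = np.sqrt(variance * (1.0 / ni + 1.0 / nj))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * n_pairs)
        out.append(
            ComparisonResult(
                test_name="dunn",
                statistic=float(z),
                p_value=float(p),
                group_labels=(labels[i], labels[j]),
                n=(ni, nj),
                adjusted=adjust != "none",
            )
        )
    return out


def chi2_test(table, labels: tuple[str, ...] = ("rows", "cols")) -> ComparisonResult:
    """Pearson chi-square test of independence, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    res = sps.chi2_contingency(table, correction=False)
    return ComparisonResult(
        test_name="chi2",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_labels=labels,
        n=tuple(int(c) for c in table.sum(axis=1)),
    )


def pearson_r(x, y, pair: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Pearson correlation with a two-sided t-based p-value."""
    x, y = _clean(x), _clean(y)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    res = sps.pearsonr(x, y)
    return CorrelationResult(
        variable_pair=pair, r=float(res.statistic), p_value=float(res.pvalue), n=len(x)
    )
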