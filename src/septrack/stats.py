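"""Nonparametric inference layer: Kruskal-Wallis with effect size, Dunn's
pairwise post-hoc test, Wilcoxon/Mann-Whitney rank-sum, Shapiro-Wilk
normality, and the Vargha-Delaney A effect size.

These are the tests used throughout comparisons of cell morphometrics and
single-molecule statistics, where the underlying distributions are rarely
normal.  Dunn's test and Vargha-Delaney's A are implemented from their rank
definitions (with tie corrections); Kruskal-Wallis, the rank-sum test, and
Shapiro-Wilk delegate to scipy's vetted implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "vargha_delaney_a",
    "dunn_test",
    "kruskal_wallis",
    "wilcoxon_rank_sum",
    "shapiro_wilk",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    effect_size: float | None = None
    groups: tuple[str, ...] | None = None
    n: tuple[int, ...] | None = None
    p_raw: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p_value must be in [0, 1]")


def vargha_delaney_a(x, y) -> float:
    """Vargha-Delaney A: P(X > Y) + 0.5 P(X = Y).

    A = 0.5 means stochastic equality; 1.0 means complete dominance of x.
    Computed from joint mid-ranks, equivalent to pairwise counting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[:nx].sum()
    return float((r1 / nx - (nx + 1) / 2.0) / ny)


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def dunn_test(
    groups: dict[str, np.ndarray] | list[np.ndarray],
    adjust: str = "holm",
) -> list[TestResult]:
    """Dunn's pairwise multiple-comparison test on pooled mid-ranks.

    For each pair (i, j):
        z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with tie correction T = sum(t³ - t); two-sided p from the standard
    normal, then adjusted for multiplicity (``none``, ``bonferroni``,
    ``holm`` or ``BH``).  ``p_value`` holds the adjusted p, ``p_raw`` the
    unadjusted one.
    """
    if isinstance(groups, dict):
        labels = list(groups.keys())
        data = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        labels = [f"group{i}" for i in range(len(groups))]
        data = [np.asarray(g, dtype=float) for g in groups]
    if len(data) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in data):
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate(data)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    variance_core = N * (N + 1) / 12.0 - _tie_term(pooled) / (12.0 * (N - 1))
    if variance_core <= 0:
        raise ValueError("zero rank variance (all pooled values identical)")
    mean_ranks = []
    start = 0
    for g in data:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)

    pairs = [(i, j) for i in range(len(data)) for j in range(i + 1, len(data))]
    zs, ps = [], []
    for i, j in pairs:
        se = np.sqrt(variance_core * (1.0 / len(data[i]) + 1.0 / len(data[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        zs.append(z)
        ps.append(2.0 * sps.norm.sf(abs(z)))
    adjust = adjust.lower()
    if adjust == "none":
        p_adj = list(ps)
    else:
        method = {"bonferroni": "bonferroni", "holm": "holm", "bh": "fdr_bh"}.get(adjust)
        if method is None:
            raise ValueError(f"unknown adjustment '{adjust}'")
        p_adj = list(multipletests(ps, method=method)[1])
    results = []
    for (i, j), z, p, pa in zip(pairs, zs, ps, p_adj):
        results.append(
            TestResult(
                statistic=float(z),
                p_value=float(min(pa, 1.0)),
                p_raw=float(p),
                groups=(labels[i], labels[j]),
                n=(len(data[i]), len(data[j])),
            )
        )
    return results


def kruskal_wallis(groups: dict[str, np.ndarray] | list[np.ndarray]) -> TestResult:
    """Kruskal-Wallis rank-sum test with the epsilon-squared effect size.

    ``effect_size`` is eps² = (H - k + 1)/(N - k), clipped below at 0 so it
    stays in [0, 1] (the raw expression is negative whenever H < k - 1).
    All-identical data give H = 0, p = 1.
    """
    if isinstance(groups, dict):
        labels = tuple(groups.keys())
        data = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        labels = tuple(f"group{i}" for i in range(len(groups)))
        data = [np.asarray(g, dtype=float) for g in groups]
    if len(data) < 2:
        raise ValueError("need at least 2 groups")
    k = len(data)
    N = sum(len(g) for g in data)
    pooled = np.concatenate(data)
    if np.ptp(pooled) == 0:
        H, p = 0.0, 1.0  # all values identical
    else:
        H, p = sps.kruskal(*data)
    eps2 = (H - k + 1) / (N - k) if N > k else np.nan
    eps2 = float(np.clip(eps2, 0.0, 1.0)) if np.isfinite(eps2) else eps2
    return TestResult(
        statistic=float(H), p_value=float(p), effect_size=eps2,
        groups=labels, n=tuple(len(g) for g in data),
    )


def wilcoxon_rank_sum(x, y, exact_limit: int = 400) -> TestResult:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test.

    Uses exact enumeration when ``n_x * n_y <= exact_limit`` and there are no
    ties, otherwise the normal approximation with tie and continuity
    corrections.  ``effect_size`` is the Vargha-Delaney A of x over y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) * len(y) <= exact_limit and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        effect_size=vargha_delaney_a(x, y), n=(len(x), len(y)),
    )


def shapiro_wilk(x) -> TestResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000, non-constant data)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant data: zero variance")
    W, p = sps.shapiro(x)
    return TestResult(statistic=float(W), p_value=float(p), n=(len(x),))
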