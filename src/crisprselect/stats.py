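"""Statistical primitives implemented from first principles.

Each test here is written against its defining formula and validated in
the test suite against brute-force enumeration oracles (and, where
available, independent library implementations). Only special functions
(log-gamma, incomplete gamma, normal and t distribution functions) are
taken from :mod:`scipy.special`.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, lgamma, sqrt
from typing import Sequence

import numpy as np
from scipy import special

__all__ = [
    "TestResult",
    "fisher_exact_2x2",
    "chi_square_gof",
    "wilcoxon_rank_sum",
    "adjust_pvalues",
    "poisson_binomial_cdf",
    "t_test_paired",
    "t_test_welch",
]

#: relative tolerance guarding floating-point ties in the Fisher
#: probability-mass comparison
FISHER_REL_TOL = 1e-7

#: exact Wilcoxon enumeration up to this combined sample size
WILCOXON_EXACT_MAX_N = 20


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    method: str
    df: float | None = None
    sided: str = "two-sided"

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise AssertionError(f"p-value {self.p} outside [0,1]")

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "method": self.method,
            "sided": self.sided,
        }


def _log_hypergeom_pmf(a: int, r1: int, r2: int, c1: int) -> float:
    """log P(A = a) for a 2x2 table with margins (r1, r2) x (c1, .)."""
    n = r1 + r2

    def lchoose(n_, k_):
        return lgamma(n_ + 1) - lgamma(k_ + 1) - lgamma(n_ - k_ + 1)

    return lchoose(r1, a) + lchoose(r2, c1 - a) - lchoose(n, c1)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    The two-sided p-value is the total hypergeometric probability of all
    tables (with the observed margins) whose probability does not exceed
    that of the observed table (probability-mass method).
    """
    (a, b), (c, d) = table
    cells = [a, b, c, d]
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError("table cells must be nonnegative integers")
    a, b, c, d = (int(x) for x in cells)
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or b + d == 0:
        return TestResult(statistic=float("nan"), p=1.0, method="fisher_exact")

    lo, hi = max(0, c1 - r2), min(r1, c1)
    log_obs = _log_hypergeom_pmf(a, r1, r2, c1)
    cutoff = log_obs + np.log1p(FISHER_REL_TOL)
    p = 0.0
    for x in range(lo, hi + 1):
        lp = _log_hypergeom_pmf(x, r1, r2, c1)
        if lp <= cutoff:
            p += exp(lp)
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return TestResult(statistic=odds, p=min(p, 1.0), method="fisher_exact")


def chi_square_gof(
    observed: Sequence[float], expected_proportions: Sequence[float]
) -> TestResult:
    """Chi-square goodness of fit: chi2 = sum (O-E)^2/E, df = k-1."""
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.shape != props.shape or obs.ndim != 1:
        raise ValueError("observed and expected proportions must match in length")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"expected proportions sum to {props.sum()}, not 1")
    if obs.sum() <= 0:
        raise ValueError("observed counts must sum to a positive total")
    expected = props * obs.sum()
    if np.any(expected == 0):
        raise ValueError("zero expected cell")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    p = float(special.gammaincc(df / 2.0, chi2 / 2.0))
    return TestResult(statistic=chi2, df=df, p=p, method="chi_square_gof", sided="upper")


def _rank_sum_exact_cdf(n_x: int, n_total: int) -> np.ndarray:
    """counts[w] = number of n_x-subsets of ranks 1..n_total summing to w."""
    max_sum = n_total * (n_total + 1) // 2
    counts = np.zeros((n_x + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in range(1, n_total + 1):
        for k in range(min(r, n_x), 0, -1):
            counts[k, r:] += counts[k - 1, :-r] if r > 0 else counts[k - 1]
    return counts[n_x]


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null enumeration of the rank-sum distribution when the
    combined sample size is at most 20 and there are no ties; otherwise
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    n_x, n = x.size, pooled.size
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n, dtype=float)
    # midranks for ties
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    w = float(ranks[:n_x].sum())
    has_ties = np.unique(pooled).size < n

    if n <= WILCOXON_EXACT_MAX_N and not has_ties:
        counts = _rank_sum_exact_cdf(n_x, n)
        total = counts.sum()
        wi = int(round(w))
        lower = counts[: wi + 1].sum() / total
        upper = counts[wi:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        return TestResult(statistic=w, p=p, method="wilcoxon_exact")

    mean_w = n_x * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var_w = n_x * (n - n_x) / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w == 0:
        return TestResult(statistic=w, p=1.0, method="wilcoxon_normal")
    z = (w - mean_w - 0.5 * np.sign(w - mean_w)) / sqrt(var_w)
    p = float(2.0 * special.ndtr(-abs(z)))
    return TestResult(statistic=w, p=min(p, 1.0), method="wilcoxon_normal")


def adjust_pvalues(pvals: Sequence[float], method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment, order-preserving.

    ``BH``: Benjamini-Hochberg step-up; ``holm``: Holm step-down. Both
    enforce monotonicity and cap at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m, dtype=float)
    if method.upper() == "BH":
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adjusted[order] = np.minimum(ranked, 1.0)
    elif method.lower() == "holm":
        ranked = p[order] * (m - np.arange(m))
        ranked = np.maximum.accumulate(ranked)
        adjusted[order] = np.minimum(ranked, 1.0)
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return adjusted


def poisson_binomial_cdf(probs: Sequence[float], k: int) -> tuple[float, float]:
    """(P(X <= k), P(X >= k)) for X a sum of independent Bernoullis.

    Exact dynamic-programming convolution of the success probabilities.
    """
    p = np.asarray(probs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0,1]")
    dist = np.zeros(p.size + 1)
    dist[0] = 1.0
    for i, pi in enumerate(p):
        dist[1 : i + 2] = dist[1 : i + 2] * (1 - pi) + dist[: i + 1] * pi
        dist[0] *= 1 - pi
    k = int(k)
    lower = float(dist[: max(k + 1, 0)].sum()) if k >= 0 else 0.0
    upper = float(dist[max(k, 0) :].sum()) if k <= p.size else 0.0
    return min(lower, 1.0), min(upper, 1.0)


def t_test_paired(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided paired t-test on within-pair differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if np.allclose(d, d[0]):
        if d[0] == 0:
            return TestResult(statistic=0.0, df=d.size - 1, p=1.0, method="t_paired")
        raise ValueError("degenerate data: constant nonzero difference, zero variance")
    t = float(d.mean() / (sd / sqrt(d.size)))
    df = d.size - 1
    p = float(2.0 * special.stdtr(df, -abs(t)))
    return TestResult(statistic=t, df=df, p=p, method="t_paired")


def t_test_welch(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Welch unpaired t-test (unequal variances)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return TestResult(statistic=0.0, df=x.size + y.size - 2, p=1.0, method="t_welch")
        raise ValueError("degenerate data: zero variance in both groups")
    se2 = vx / x.size + vy / y.size
    t = float((x.mean() - y.mean()) / sqrt(se2))
    df = se2**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    p = float(2.0 * special.stdtr(df, -abs(t)))
    return TestResult(statistic=t, df=float(df), p=p, method="t_welch")
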