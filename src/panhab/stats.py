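"""Statistical tests used throughout the pipeline.

The Mann-Whitney U test and the two-sided Fisher probability-mass rule are
implemented directly so their small-sample behaviour is fully specified
(exact enumeration below the size switch, tie- and continuity-corrected
normal approximation above it); tail masses come from scipy distributions.
The Poisson observed-vs-expected group test takes each group's expectation
from the *other* group's rate, evaluates both one-sided inclusive tails,
and reports the smaller — a symmetric construction for comparing the number
of genomes carrying a feature between two groups of unequal size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALTERNATIVES = ("two_sided", "greater", "less")

#: per-group size at or below which the Mann-Whitney p is computed by exact
#: enumeration (only when there are no ties)
MANN_WHITNEY_EXACT_MAX_N = 8


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    alternative: str = "two_sided"
    method: str = ""

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def _check_alternative(alternative: str) -> str:
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    return alternative


# ------------------------------------------------------------ Mann-Whitney

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x: number of (x_i, y_j) pairs with x_i > y_j (+0.5 per tie)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _exact_mw_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Exact p by enumerating all C(n+m, n) label assignments (no ties)."""
    pooled = np.concatenate([x, y])
    n = len(x)
    u_obs = _u_statistic(x, y)
    idx = range(len(pooled))
    us = []
    for comb in combinations(idx, n):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(comb)] = True
        us.append(_u_statistic(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    mu = n * len(y) / 2.0
    eps = 1e-9
    if alternative == "greater":
        return float(np.mean(us >= u_obs - eps))
    if alternative == "less":
        return float(np.mean(us <= u_obs + eps))
    return float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - eps))


def mann_whitney(x, y, alternative: str = "two_sided") -> TestResult:
    """Mann-Whitney U test of two independent samples.

    Exact p by full enumeration when both groups have <= 8 observations and
    the pooled sample has no ties; otherwise the normal approximation with
    tie correction and continuity correction.
    """
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires non-empty groups")
    u = _u_statistic(x, y)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if n <= MANN_WHITNEY_EXACT_MAX_N and m <= MANN_WHITNEY_EXACT_MAX_N and not has_ties:
        p = _exact_mw_p(x, y, alternative)
        return TestResult(u, min(p, 1.0), alternative, "mann_whitney_exact")
    mu = n * m / 2.0
    nt = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (nt * (nt - 1.0))
    var = n * m / 12.0 * (nt + 1.0 - tie_term)
    if var <= 0:  # all observations identical
        return TestResult(u, 1.0, alternative, "mann_whitney_normal")
    sd = math.sqrt(var)
    if alternative == "greater":
        z = (u - mu - 0.5) / sd
        p = sps.norm.sf(z)
    elif alternative == "less":
        z = (u - mu + 0.5) / sd
        p = sps.norm.cdf(z)
    else:
        z = (abs(u - mu) - 0.5) / sd
        p = 2.0 * sps.norm.sf(max(z, 0.0))
    return TestResult(u, float(min(max(p, 0.0), 1.0)), alternative, "mann_whitney_normal")


# ------------------------------------------------------------ Fisher exact

def fisher_exact_2x2(a: int, b: int, c: int, d: int, alternative: str = "two_sided") -> TestResult:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    The statistic is the sample odds ratio ad/bc (inf when bc = 0 and
    ad > 0; nan when both numerator and denominator vanish). The two-sided
    p is the probability-mass rule: the sum of hypergeometric probabilities
    of tables no more probable than the observed one.
    """
    _check_alternative(alternative)
    counts = (a, b, c, d)
    if any(int(v) != v or v < 0 for v in counts):
        raise ValueError("fisher_exact_2x2 requires non-negative integer counts")
    a, b, c, d = (int(v) for v in counts)
    if a + b + c + d == 0:
        raise ValueError("fisher_exact_2x2 requires at least one positive margin")
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    N, K, n = a + b + c + d, a + b, a + c
    rv = sps.hypergeom(N, K, n)
    lo, hi = max(0, K + n - N), min(K, n)
    if alternative == "greater":
        p = float(rv.sf(a - 1))
    elif alternative == "less":
        p = float(rv.cdf(a))
    else:
        support = np.arange(lo, hi + 1)
        pmf = rv.pmf(support)
        p_obs = rv.pmf(a)
        p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return TestResult(odds, min(max(p, 0.0), 1.0), alternative, "fisher_exact")


# --------------------------------------------------------------------- BH

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ----------------------------------------------------- Poisson group test

def poisson_group_test(k_a: int, n_a: int, k_b: int, n_b: int) -> dict:
    """Observed-vs-expected Poisson comparison of two group proportions.

    ``k_g`` of ``n_g`` genomes in group g carry the feature. Each group's
    expected count lambda_g is the other group's rate times n_g; the
    one-sided inclusive exact Poisson tail (upper if observed >= expected,
    lower otherwise) is evaluated in both directions and the smaller tail
    is reported. direction = the group with the higher rate.
    """
    for k, n in ((k_a, n_a), (k_b, n_b)):
        if n < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0 <= k <= n:
            raise ValueError(f"count {k} outside [0, {n}]")
    rate_a, rate_b = k_a / n_a, k_b / n_b
    lam_a, lam_b = rate_b * n_a, rate_a * n_b

    def tail(k: int, lam: float) -> float:
        if lam == 0.0:
            return 1.0 if k == 0 else 0.0
        if k >= lam:
            return float(sps.poisson.sf(k - 1, lam))
        return float(sps.poisson.cdf(k, lam))

    p_a, p_b = tail(k_a, lam_a), tail(k_b, lam_b)
    if rate_a > rate_b:
        direction = "A"
    elif rate_b > rate_a:
        direction = "B"
    else:
        direction = "none"
    return {
        "p": min(p_a, p_b),
        "direction": direction,
        "lambda_a": lam_a,
        "lambda_b": lam_b,
        "p_a": p_a,
        "p_b": p_b,
    }


# --------------------------------------------------------- binomial sign

def binomial_sign_test(k: int, n: int) -> TestResult:
    """Two-sided exact binomial test of k successes in n trials vs 0.5."""
    if not 0 <= k <= n:
        raise ValueError(f"count {k} outside [0, {n}]")
    if n == 0:
        return TestResult(float("nan"), 1.0, "two_sided", "binomial_sign")
    p = sps.binomtest(k, n, 0.5, alternative="two-sided").pvalue
    return TestResult(float(k), float(min(p, 1.0)), "two_sided", "binomial_sign")
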