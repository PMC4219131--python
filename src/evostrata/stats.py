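"""Shared statistical primitives.

scipy covers the 2x2 Fisher test, the hypergeometric distribution, the
chi-square contingency test and the asymptotic Mann-Whitney U test. What it
does not provide — and what the analyses here need — are an exact (or
Monte-Carlo) Fisher test on 2xK tables, an exact tie-aware two-tailed
Mann-Whitney for small samples, and a distribution-free (order-statistic)
confidence interval for a median. Those are implemented here and
cross-checked against enumeration oracles in the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "hypergeom_over_p",
    "chi2_two_sample",
    "fisher_2xk_p",
    "mann_whitney",
    "median_ci",
    "MedianCI",
]


def hypergeom_over_p(k: int, M: int, K: int, N: int) -> float:
    """One-tailed hypergeometric p for over-representation.

    Probability of drawing >= ``k`` successes in ``N`` draws from a
    population of ``M`` containing ``K`` successes.
    """
    return float(sps.hypergeom.sf(k - 1, M, K, N))


def chi2_two_sample(counts_a, counts_b, *, return_df: bool = False):
    """Two-sample chi-square homogeneity statistic on a 2xK count table.

    Bins empty in both rows are dropped (reducing the degrees of freedom
    accordingly); no continuity correction is applied.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must have equal length")
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("a sample with zero total has no distribution to test")
    table = np.vstack([a, b])
    if table.shape[1] < 2:
        stat, p, df = 0.0, 1.0, 0
    else:
        stat, p, df, _ = sps.chi2_contingency(table, correction=False)
    if return_df:
        return float(stat), float(p), int(df)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Exact / Monte-Carlo Fisher test on 2xK tables
# ---------------------------------------------------------------------------

def _log_table_prob(row, colsums, n1, N):
    """log multivariate-hypergeometric pmf of a first row given margins."""
    row = np.asarray(row)
    colsums = np.asarray(colsums)
    return float(
        np.sum(gammaln(colsums + 1) - gammaln(row + 1) - gammaln(colsums - row + 1))
        - (gammaln(N + 1) - gammaln(n1 + 1) - gammaln(N - n1 + 1))
    )


def _enumeration_bound(colsums, n1) -> float:
    bound = 1.0
    for c in colsums:
        bound *= min(c, n1) + 1
    return bound


def _fisher_2xk_exact(row1, colsums) -> float:
    n1 = int(sum(row1))
    N = int(sum(colsums))
    log_obs = _log_table_prob(row1, colsums, n1, N)
    k = len(colsums)
    colsums = [int(c) for c in colsums]
    suffix = [0] * (k + 1)
    for j in range(k - 1, -1, -1):
        suffix[j] = suffix[j + 1] + colsums[j]
    acc: list[float] = []
    base = -(gammaln(N + 1) - gammaln(n1 + 1) - gammaln(N - n1 + 1))

    def log_choose(c, a):
        return gammaln(c + 1) - gammaln(a + 1) - gammaln(c - a + 1)

    def recurse(j, remaining, logp_partial):
        if j == k - 1:
            a = remaining
            if 0 <= a <= colsums[j]:
                logp = logp_partial + log_choose(colsums[j], a)
                if logp <= log_obs + 1e-7:
                    acc.append(logp)
            return
        lo = max(0, remaining - suffix[j + 1])
        hi = min(colsums[j], remaining)
        for a in range(lo, hi + 1):
            recurse(j + 1, remaining - a, logp_partial + log_choose(colsums[j], a))

    recurse(0, n1, base)
    if not acc:
        return 1.0
    return min(1.0, float(np.exp(np.asarray(acc)).sum()))


def _fisher_2xk_montecarlo(row1, colsums, reps, rng) -> float:
    n1 = int(sum(row1))
    N = int(sum(colsums))
    log_obs = _log_table_prob(row1, colsums, n1, N)
    draws = rng.multivariate_hypergeometric(list(map(int, colsums)), n1, size=reps)
    colsums = np.asarray(colsums, dtype=float)
    logp = (
        gammaln(colsums + 1) - gammaln(draws + 1) - gammaln(colsums - draws + 1)
    ).sum(axis=1) - (gammaln(N + 1) - gammaln(n1 + 1) - gammaln(N - n1 + 1))
    hits = int(np.sum(logp <= log_obs + 1e-7))
    return (hits + 1) / (reps + 1)  # add-one estimator


def fisher_2xk_p(
    table,
    *,
    max_enum_total: int = 200,
    max_enum_tables: float = 5e5,
    mc_reps: int = 100_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, str]:
    """Fisher exact test p-value on a 2xK contingency table.

    Exact full enumeration (conditional on both margins, summing the
    probability of every table no more probable than the observed one) is
    used when the table total is <= ``max_enum_total`` and the feasible-table
    bound is small enough; otherwise a Monte-Carlo estimate conditional on
    margins with the add-one estimator. Returns ``(p, method)`` where method
    is ``"exact"`` or ``"montecarlo"``.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("expected a 2xK table")
    if (t < 0).any():
        raise ValueError("negative counts")
    keep = t.sum(axis=0) > 0
    t = t[:, keep]
    if t.shape[1] == 0 or t.sum() == 0:
        raise ValueError("empty table")
    if t[0].sum() == 0 or t[1].sum() == 0:
        raise ValueError("a row with zero total has no distribution to test")
    colsums = t.sum(axis=0)
    N = int(t.sum())
    n1 = int(t[0].sum())
    if N <= max_enum_total and _enumeration_bound(colsums, n1) <= max_enum_tables:
        return _fisher_2xk_exact(t[0], colsums), "exact"
    if rng is None:
        rng = np.random.default_rng(0)
    return _fisher_2xk_montecarlo(t[0], colsums, mc_reps, rng), "montecarlo"


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(ranks_x, n_x, n_y):
    r1 = float(np.sum(ranks_x))
    return r1 - n_x * (n_x + 1) / 2.0


def _mwu_exact_two_tailed(x, y) -> tuple[float, float]:
    """Exact two-tailed Mann-Whitney p by full enumeration (tie-aware).

    Enumerates every assignment of the pooled values to the two groups
    (conditioning on the observed pooled multiset, which handles ties via
    midranks) and doubles the smaller tail, capped at 1.
    """
    pooled = np.concatenate([x, y])
    n_x, n_y = len(x), len(y)
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n_x], n_x, n_y)
    n = n_x + n_y
    us = []
    for idx in itertools.combinations(range(n), n_x):
        us.append(_u_statistic(ranks[list(idx)], n_x, n_y))
    us = np.asarray(us)
    eps = 1e-9
    p_low = float(np.mean(us <= u_obs + eps))
    p_high = float(np.mean(us >= u_obs - eps))
    return u_obs, min(1.0, 2.0 * min(p_low, p_high))


def mann_whitney(x, y, *, exact_max_n: int = 8) -> tuple[float, float, str]:
    """Two-tailed Mann-Whitney U test.

    Exact enumeration (tie-aware) when both samples have at most
    ``exact_max_n`` observations; otherwise the normal approximation with
    tie correction. Returns ``(U, p, method)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if len(x) <= exact_max_n and len(y) <= exact_max_n:
        u, p = _mwu_exact_two_tailed(x, y)
        return u, p, "exact"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(res.statistic), float(res.pvalue), "asymptotic"


# ---------------------------------------------------------------------------
# Median with distribution-free confidence interval
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MedianCI:
    median: float
    ci_low: float
    ci_high: float
    level: float
    approximate: bool  # True when n is too small for the nominal level


def median_ci(values, level: float = 0.95) -> MedianCI:
    """Sample median with an order-statistic confidence interval.

    The interval [x_(l), x_(n+1-l)] uses the largest ``l`` with
    ``P(Binom(n, 1/2) < l) <= (1 - level)/2``, giving coverage at least
    ``level``. For n < 6 no such interval exists at 95%; the full data range
    is returned and flagged approximate.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("median of empty sample")
    med = float(np.median(x))
    alpha = 1.0 - level
    if n < 6:
        return MedianCI(med, float(x[0]), float(x[-1]), level, True)
    l = int(sps.binom.ppf(alpha / 2.0, n, 0.5))
    while l > 0 and sps.binom.cdf(l - 1, n, 0.5) > alpha / 2.0:
        l -= 1
    l = max(l, 1)
    u = n + 1 - l
    return MedianCI(med, float(x[l - 1]), float(x[u - 1]), level, False)
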