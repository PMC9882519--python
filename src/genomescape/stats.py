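"""Exact and rank-based cohort statistics.

The 2x2 exact machinery (two-sided Fisher p, conditional maximum-likelihood
odds ratio, exact conditional confidence interval) is implemented from first
principles on the noncentral hypergeometric likelihood, matching the
convention of R's ``fisher.test``: the two-sided p-value sums the
probabilities of all tables no more likely than the observed one, the OR
estimate solves E[a | psi] = a_obs, and the CI inverts the one-sided exact
conditional tests at alpha/2 per tail.

Rank-sum and t statistics are standard; the Wilcoxon test enumerates its
exact null distribution (mid-ranks for ties) for small samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "Fisher2x2Result", "fisher_exact_2x2", "wilcoxon_rank_sum",
    "t_tests", "bh_adjust",
]


@dataclass(frozen=True)
class Fisher2x2Result:
    table: tuple[int, int, int, int]  # (a, b, c, d)
    or_mle: float                     # conditional MLE odds ratio
    ci_low: float
    ci_high: float
    p_two_sided: float


def _log_pmf_terms(n1: int, n2: int, m1: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and log C(n1,k)*C(n2,m1-k) for the conditional 2x2 likelihood."""
    lo, hi = max(0, m1 - n2), min(m1, n1)
    ks = np.arange(lo, hi + 1)
    logc = (special.gammaln(n1 + 1) - special.gammaln(ks + 1)
            - special.gammaln(n1 - ks + 1)
            + special.gammaln(n2 + 1) - special.gammaln(m1 - ks + 1)
            - special.gammaln(n2 - (m1 - ks) + 1))
    return ks, logc


def _cond_dist(ks: np.ndarray, logc: np.ndarray, log_psi: float) -> np.ndarray:
    logw = logc + ks * log_psi
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def fisher_exact_2x2(a: int, b: int, c: int, d: int, *,
                     alpha: float = 0.05,
                     two_sided_rule: str = "minlike") -> Fisher2x2Result:
    """Exact conditional inference for the 2x2 table [[a, b], [c, d]].

    ``two_sided_rule``: 'minlike' (default; sum of tables with probability
    <= the observed table's) or 'double' (twice the smaller one-sided tail,
    capped at 1).
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    n1, n2, m1 = a + b, c + d, a + c
    ks, logc = _log_pmf_terms(n1, n2, m1)
    # central (psi=1) hypergeometric pmf
    logp = logc - special.gammaln(n1 + n2 + 1) + special.gammaln(m1 + 1) \
        + special.gammaln(n1 + n2 - m1 + 1)
    pmf = np.exp(logp)
    pmf = pmf / pmf.sum()  # guard rounding
    idx = int(a - ks[0])

    p_upper = float(pmf[idx:].sum())
    p_lower = float(pmf[: idx + 1].sum())
    if two_sided_rule == "minlike":
        p_two = float(pmf[pmf <= pmf[idx] * (1 + 1e-7)].sum())
    elif two_sided_rule == "double":
        p_two = min(1.0, 2.0 * min(p_upper, p_lower))
    else:
        raise ValueError(f"unknown two_sided_rule {two_sided_rule!r}")
    p_two = min(1.0, p_two)

    lo, hi = ks[0], ks[-1]

    def expect(log_psi: float) -> float:
        return float((_cond_dist(ks, logc, log_psi) * ks).sum())

    # conditional MLE: E[a | psi] = a ; 0 / inf at the support boundary
    if a == lo == hi:
        or_mle = 1.0
    elif a == lo:
        or_mle = 0.0
    elif a == hi:
        or_mle = math.inf
    else:
        sol = optimize.brentq(lambda t: expect(t) - a, -50, 50, xtol=1e-12,
                              rtol=8.881784197001252e-16)
        or_mle = math.exp(sol)
        # polish to relative tolerance 1e-8 via monotonicity of expect
        assert abs(expect(math.log(or_mle)) - a) < 1e-6

    def tail_upper(log_psi: float) -> float:  # P(A >= a | psi)
        return float(_cond_dist(ks, logc, log_psi)[idx:].sum())

    def tail_lower(log_psi: float) -> float:  # P(A <= a | psi)
        return float(_cond_dist(ks, logc, log_psi)[: idx + 1].sum())

    half = alpha / 2.0
    if a == lo:
        ci_low = 0.0
    else:
        ci_low = math.exp(optimize.brentq(
            lambda t: tail_upper(t) - half, -80, 80, xtol=1e-12))
    if a == hi:
        ci_high = math.inf
    else:
        ci_high = math.exp(optimize.brentq(
            lambda t: tail_lower(t) - half, -80, 80, xtol=1e-12))

    return Fisher2x2Result(table=(a, b, c, d), or_mle=or_mle,
                           ci_low=ci_low, ci_high=ci_high, p_two_sided=p_two)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum of x (mid-ranks)
    p_two_sided: float
    exact: bool


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float], *,
                      exact_max_n: int = 25) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact null distribution (enumerated by dynamic programming over subset
    rank sums, mid-ranks for ties) when len(x)+len(y) <= ``exact_max_n``;
    normal approximation with tie correction and continuity correction
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n, m = len(x), len(y)
    ranks = _midranks(np.concatenate([x, y]))
    w = float(ranks[:n].sum())
    if n + m <= exact_max_n:
        p = _exact_ranksum_p(ranks, n, w)
        return RankSumResult(statistic=w, p_two_sided=p, exact=True)
    # normal approximation
    N = n + m
    mu = n * (N + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float((counts ** 3 - counts).sum())
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var == 0:
        return RankSumResult(statistic=w, p_two_sided=1.0, exact=False)
    z = (w - mu - math.copysign(0.5, w - mu)) / math.sqrt(var) if w != mu else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return RankSumResult(statistic=w, p_two_sided=min(1.0, p), exact=False)


def _exact_ranksum_p(ranks: np.ndarray, n: int, w_obs: float) -> float:
    """P(|W - mu| >= |w_obs - mu|) by DP over doubled (integer) mid-ranks."""
    r2 = np.round(ranks * 2).astype(int)
    N = len(r2)
    total = r2.sum()
    # dp[k][s] = number of k-subsets with doubled-rank sum s
    dp = [np.zeros(total + 1, dtype=float) for _ in range(n + 1)]
    dp[0][0] = 1.0
    for r in r2:
        for k in range(min(n, N) - 1, -1, -1):
            src = dp[k]
            if src.any():
                dp[k + 1][r:] += src[: total + 1 - r]
    counts = dp[n]
    n_total = counts.sum()
    sums = np.arange(total + 1)
    w2 = np.round(w_obs * 2)
    mu2 = float(sums @ counts) / n_total
    dev = abs(w2 - mu2)
    mask = np.abs(sums - mu2) >= dev - 1e-9
    return float(counts[mask].sum() / n_total)


# ---------------------------------------------------------------------------
# t tests and multiple-testing adjustment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_two_sided: float
    paired: bool


def t_tests(x: Sequence[float], y: Sequence[float], *,
            paired: bool = False, equal_var: bool = False) -> TTestResult:
    """Two-sided t test: paired, or two-sample (Welch by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test requires equal-length samples")
        if np.allclose(x, y):
            return TTestResult(statistic=0.0, p_two_sided=1.0, paired=True)
        res = stats.ttest_rel(x, y)
    else:
        res = stats.ttest_ind(x, y, equal_var=equal_var)
    return TTestResult(statistic=float(res.statistic),
                       p_two_sided=float(res.pvalue), paired=paired)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return stats.false_discovery_control(np.asarray(pvals, dtype=float),
                                         method="bh")
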