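"""Statistical primitives shared by every analysis module.

Thin, uniformly-shaped wrappers over scipy.stats plus the small pieces scipy
does not provide in the needed form: an exact-permutation Spearman p-value
for very small n, a summary-statistic Welch t-test entry point, rank-
transformed one-way ANOVA, and Bonferroni adjustment.

All tests are two-sided.  p-values are never reported as exactly zero; they
are floored at the smallest positive double so that downstream log/compare
operations stay defined.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

P_FLOOR = 5e-324  # smallest subnormal double

#: n at or below which Spearman uses the exact permutation distribution
SPEARMAN_EXACT_N = 9
#: combined sample size at or below which the MWU uses the exact distribution
MWU_EXACT_N = 12


@dataclass(frozen=True)
class TestResult:
    """Uniform container for a two-sample or correlation test."""

    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str
    flagged: bool = False  # degenerate input (constant vector, zero variance...)

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n1": self.n1,
            "n2": self.n2,
            "method": self.method,
            "flagged": self.flagged,
        }


def _floor_p(p: float) -> float:
    if not np.isfinite(p):
        return float("nan")
    return float(min(max(p, P_FLOOR), 1.0))


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with average ranks for ties.

    rho is the Pearson correlation of the two rank vectors.  The p-value is
    from the exact permutation distribution for n <= 9 and from the usual
    t-approximation with n - 2 degrees of freedom otherwise.  A constant
    input vector leaves rho undefined (NaN, flagged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spearman requires two equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(float("nan"), float("nan"), n, n, "spearman", flagged=True)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= SPEARMAN_EXACT_N:
        p = _spearman_exact_p(rx, ry, rho)
    else:
        # t-approximation; guard |rho| = 1
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return TestResult(rho, _floor_p(p), n, n, "spearman")


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all pairings of y-ranks to x-ranks."""
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = math.sqrt(float(rx_c @ rx_c)) * np.sqrt((ry_c * ry_c).sum(axis=1))
    rhos = (ry_c @ rx_c) / denom
    tol = 1e-12
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - tol))


def mann_whitney_u(a, b, use_continuity: bool = True) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when n1 + n2 <= 12 and the pooled data are
    tie-free; otherwise the normal approximation with tie correction and
    (optionally) continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("mann_whitney_u requires >= 2 observations per group")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if a.size + b.size <= MWU_EXACT_N and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method,
        use_continuity=use_continuity,
    )
    return TestResult(
        float(res.statistic), _floor_p(float(res.pvalue)),
        a.size, b.size, f"mwu_{method}",
    )


def welch_t(a, b) -> TestResult:
    """Welch two-sample t-test (unequal variances), two-tailed."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t requires >= 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0, a.size, b.size, "welch_t", flagged=True)
        return TestResult(math.inf, P_FLOOR, a.size, b.size, "welch_t", flagged=True)
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(
        float(res.statistic), _floor_p(float(res.pvalue)), a.size, b.size, "welch_t"
    )


def welch_t_from_summary(
    m1: float, se1: float, n1: int, m2: float, se2: float, n2: int
) -> TestResult:
    """Welch t-test from group means and standard errors of the mean."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    sd1 = se1 * math.sqrt(n1)
    sd2 = se2 * math.sqrt(n2)
    res = sps.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2, equal_var=False)
    return TestResult(
        float(res.statistic), _floor_p(float(res.pvalue)), n1, n2, "welch_t_summary"
    )


def student_t(a, b) -> TestResult:
    """Pooled-variance Student t-test (available behind a flag upstream)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(
        float(res.statistic), _floor_p(float(res.pvalue)), a.size, b.size, "student_t"
    )


def rank_anova(groups, kruskal: bool = False) -> TestResult:
    """One-way ANOVA on rank-transformed pooled data (or Kruskal-Wallis).

    The default statistic is F computed on the pooled average ranks; with
    ``kruskal=True`` the H statistic with its chi-square approximation is
    returned instead.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("rank_anova requires >= 2 groups with >= 2 members each")
    pooled = np.concatenate(groups)
    n1 = groups[0].size
    n2 = int(pooled.size - n1)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, n1, n2, "rank_anova", flagged=True)
    if kruskal:
        res = sps.kruskal(*groups)
        return TestResult(float(res.statistic), _floor_p(float(res.pvalue)),
                          n1, n2, "kruskal")
    ranks = sps.rankdata(pooled)
    split = np.split(ranks, np.cumsum([g.size for g in groups])[:-1])
    res = sps.f_oneway(*split)
    return TestResult(float(res.statistic), _floor_p(float(res.pvalue)),
                      n1, n2, "rank_anova")


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni adjustment: p * m clipped at 1 (m = number of tests)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)
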