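"""Oracle and calibration tests for the statistical primitives."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codonopt import stat_core as sc


# ---------------------------------------------------------------------------
# independent oracles (deliberately re-derived from first principles)


def rank_average_ties(values):
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i: j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """rho by explicit rank-then-Pearson; p by full permutation enumeration."""
    rx, ry = rank_average_ties(x), rank_average_ties(y)
    def pearson(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / math.sqrt((a @ a) * (b @ b)))
    rho = pearson(rx, ry)
    count = 0
    total = 0
    for perm in itertools.permutations(range(len(y))):
        r = pearson(rx, ry[list(perm)])
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
        total += 1
    return rho, count / total


def mwu_oracle(a, b):
    """Exact two-sided MWU p by enumerating all group assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = rank_average_ties(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    center = n1 * len(b) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = float(ranks[list(combo)].sum() - n1 * (n1 + 1) / 2)
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


# ---------------------------------------------------------------------------
# spearman


def test_spearman_perfect_and_reversed():
    assert sc.spearman([1, 2, 3], [1, 2, 3]).statistic == pytest.approx(1.0)
    assert sc.spearman([1, 2, 3, 4], [8, 6, 4, 2]).statistic == pytest.approx(-1.0)


def test_spearman_constant_vector_flagged():
    res = sc.spearman([1.0, 1.0, 1.0], [1, 2, 3])
    assert res.flagged and math.isnan(res.statistic)


@pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
def test_spearman_matches_enumeration_oracle(n, rng):
    for _ in range(5):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        res = sc.spearman(x, y)
        rho, p = spearman_oracle(x, y)
        assert res.statistic == pytest.approx(rho, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)


def test_spearman_with_ties_matches_oracle(rng):
    x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0])
    y = rng.normal(size=6)
    res = sc.spearman(x, y)
    rho, p = spearman_oracle(x, y)
    assert res.statistic == pytest.approx(rho, abs=1e-12)
    assert res.p_value == pytest.approx(p, abs=1e-12)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    st.lists(st.integers(-1000, 1000), min_size=10, max_size=20, unique=True),
)
def test_spearman_invariant_under_monotone_transform(ints):
    x = np.array(ints, dtype=float) / 10.0
    y = np.array(sorted(ints, reverse=True), dtype=float)
    a = sc.spearman(x, y)
    b = sc.spearman(np.exp(x / 100.0), y)  # strictly increasing map
    assert a.statistic == pytest.approx(b.statistic, abs=1e-12)


# ---------------------------------------------------------------------------
# Mann-Whitney U


def test_mwu_simple_exact_case():
    res = sc.mann_whitney_u([1.0, 2.0], [3.0, 4.0])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(1 / 3)


@pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 4), (3, 5)])
def test_mwu_matches_enumeration_oracle(n1, n2, rng):
    for _ in range(5):
        a = rng.normal(size=n1)
        b = rng.normal(size=n2)
        res = sc.mann_whitney_u(a, b)
        u, p = mwu_oracle(a, b)
        assert res.statistic == pytest.approx(u)
        assert res.p_value == pytest.approx(p, abs=1e-12)


def test_mwu_identical_groups_non_significant(rng):
    x = rng.normal(size=30)
    res = sc.mann_whitney_u(x, x)
    assert res.p_value > 0.9


def test_mwu_power_increases_with_shift(rng):
    base = rng.normal(size=40)
    other = rng.normal(size=40)
    ps = [
        sc.mann_whitney_u(base, other + shift).p_value
        for shift in (0.5, 1.5, 3.0)
    ]
    assert ps[0] > ps[1] > ps[2]


# ---------------------------------------------------------------------------
# Welch t


def test_welch_identical_groups():
    res = sc.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_welch_zero_variance_cases():
    same = sc.welch_t([2.0, 2.0], [2.0, 2.0])
    assert same.p_value == 1.0 and same.flagged
    diff = sc.welch_t([2.0, 2.0], [3.0, 3.0])
    assert diff.p_value <= sc.P_FLOOR * 10 and diff.flagged


def test_welch_summary_matches_vector_form(rng):
    a = rng.normal(5, 2, size=50)
    b = rng.normal(4, 1, size=35)
    vec = sc.welch_t(a, b)
    summ = sc.welch_t_from_summary(
        a.mean(), a.std(ddof=1) / math.sqrt(a.size), a.size,
        b.mean(), b.std(ddof=1) / math.sqrt(b.size), b.size,
    )
    assert summ.statistic == pytest.approx(vec.statistic, abs=1e-10)
    assert summ.p_value == pytest.approx(vec.p_value, abs=1e-10)


def test_welch_type_i_error_calibrated(rng):
    """Rejection rate under the null within 3 MC standard errors of alpha."""
    n_sims = 2000
    rejections = {0.01: 0, 0.05: 0}
    for _ in range(n_sims):
        a = rng.normal(size=12)
        b = rng.normal(size=12) * 2.0  # unequal variances, same mean
        p = sc.welch_t(a, b).p_value
        for alpha in rejections:
            rejections[alpha] += p < alpha
    for alpha, k in rejections.items():
        se = math.sqrt(alpha * (1 - alpha) / n_sims)
        assert abs(k / n_sims - alpha) < 3 * se


# ---------------------------------------------------------------------------
# rank ANOVA and Bonferroni


def test_rank_anova_null_and_shifted(rng):
    null_groups = [rng.normal(size=15) for _ in range(3)]
    assert sc.rank_anova(null_groups).p_value > 0.01
    shifted = [rng.normal(size=15), rng.normal(size=15), rng.normal(4, 1, 15)]
    assert sc.rank_anova(shifted).p_value < 0.01


def test_rank_anova_all_tied():
    res = sc.rank_anova([[1.0, 1.0, 1.0], [1.0, 1.0]])
    assert res.statistic == 0.0 and res.flagged


def test_rank_anova_two_groups_agrees_with_mwu_direction(rng):
    a = rng.normal(size=20)
    b = rng.normal(1.0, 1, size=20)
    p_anova = sc.rank_anova([a, b]).p_value
    p_mwu = sc.mann_whitney_u(a, b).p_value
    assert (p_anova < 0.05) == (p_mwu < 0.05)


def test_bonferroni():
    out = sc.bonferroni([0.01, 0.02])
    assert out.tolist() == [0.02, 0.04]
    assert sc.bonferroni([0.01]).tolist() == [0.01]
    p = np.array([0.2, 0.9, 0.5])
    adj = sc.bonferroni(p)
    assert np.all(adj >= p) and np.all(adj <= 1.0)
    with pytest.raises(ValueError):
        sc.bonferroni([1.5])
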