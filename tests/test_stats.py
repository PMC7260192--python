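"""Exact-statistics unit and oracle tests.

Enumeration oracles here are built from math.comb only, independent of the
scipy distributions the implementation uses.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riokit.stats import (
    ContingencyTable2x2,
    SimonDesign,
    clopper_pearson,
    fisher_exact_two_sided,
    mann_whitney_u,
    simon_oc,
    simon_search,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------- oracles
def fisher_oracle(a, b, c, d):
    """Small-p-values two-sided Fisher by direct hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d
    if row1 in (0, n) or col1 in (0, n):
        return 1.0
    denom = math.comb(n, col1)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    probs = {
        x: math.comb(row1, x) * math.comb(n - row1, col1 - x) / denom
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))


def binom_pmf(k, n, p):
    if k < 0 or k > n:
        return 0.0
    return math.comb(n, k) * p**k * (1 - p) ** (n - k)


def simon_reject_oracle(n1, r1, n, r, p):
    total = 0.0
    for x1 in range(r1 + 1, n1 + 1):
        tail = sum(binom_pmf(x2, n - n1, p) for x2 in range(max(0, r - x1 + 1), n - n1 + 1))
        total += binom_pmf(x1, n1, p) * tail
    return total


def simon_minimax_oracle(p0, p1, alpha, beta, n_max):
    """Plain-loop exhaustive minimax search."""
    for n in range(2, n_max + 1):
        best = None
        for n1 in range(1, n):
            for r1 in range(0, n1):
                pet = sum(binom_pmf(x, n1, p0) for x in range(0, r1 + 1))
                en = n1 + (1 - pet) * (n - n1)
                for r in range(r1, n):
                    if simon_reject_oracle(n1, r1, n, r, p0) > alpha:
                        continue
                    if simon_reject_oracle(n1, r1, n, r, p1) < 1 - beta:
                        continue
                    if best is None or en < best[0]:
                        best = (en, n1, r1, n, r)
        if best:
            return best
    return None


# ----------------------------------------------------------------- fisher
@pytest.mark.parametrize(
    "table,expected",
    [
        # printed contingency tables from the association analyses
        ([[11, 7], [0, 5]], 0.0373),
        ([[12, 3], [1, 4]], 0.0307),
        ([[14, 5], [0, 8]], 5.797e-4),
        ([[5, 5], [5, 5]], 1.0),
    ],
)
def test_fisher_two_sided_reference_values(table, expected):
    assert fisher_exact_two_sided(table) == pytest.approx(expected, rel=2e-3)


def test_fisher_matches_enumeration_oracle(rng):
    for _ in range(200):
        a, b, c, d = (int(x) for x in rng.integers(0, 11, size=4))
        if a + b + c + d == 0:
            continue
        assert fisher_exact_two_sided([[a, b], [c, d]]) == pytest.approx(
            fisher_oracle(a, b, c, d), abs=1e-12
        )


def test_fisher_agrees_with_scipy(rng):
    from scipy.stats import fisher_exact

    for _ in range(100):
        a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
        if a + b + c + d == 0:
            continue
        assert fisher_exact_two_sided([[a, b], [c, d]]) == pytest.approx(
            fisher_exact([[a, b], [c, d]])[1], abs=1e-9
        )


@given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_fisher_invariant_to_row_and_column_swap(a, b, c, d):
    if a + b + c + d == 0:
        return
    p = fisher_exact_two_sided([[a, b], [c, d]])
    assert 0 < p <= 1
    assert fisher_exact_two_sided([[d, c], [b, a]]) == pytest.approx(p, abs=1e-12)


def test_fisher_empty_margin_is_uninformative():
    assert fisher_exact_two_sided([[0, 0], [3, 5]]) == 1.0


def test_fisher_doubling_convention_bounded_by_one():
    assert fisher_exact_two_sided([[5, 5], [5, 5]], method="doubling") == 1.0


# --------------------------------------------------------- clopper-pearson
def test_clopper_pearson_printed_interval():
    lo, hi = clopper_pearson(3, 25, 0.95)
    assert round(100 * lo, 1) == 2.5
    assert round(100 * hi, 1) == 31.2


def test_clopper_pearson_boundaries():
    assert clopper_pearson(0, 10)[0] == 0.0
    assert clopper_pearson(10, 10)[1] == 1.0


def test_clopper_pearson_matches_statsmodels():
    from statsmodels.stats.proportion import proportion_confint

    for k, n in [(3, 25), (0, 7), (7, 7), (10, 40)]:
        lo, hi = clopper_pearson(k, n, 0.95)
        slo, shi = proportion_confint(k, n, 0.05, method="beta")
        assert (lo, hi) == pytest.approx((slo, shi), abs=1e-10)


def test_clopper_pearson_coverage_at_least_nominal(rng):
    # exact intervals over-cover: empirical coverage >= 0.95 - 3 SE
    for n, p in [(10, 0.1), (25, 0.12), (50, 0.5)]:
        draws = rng.binomial(n, p, size=10_000)
        covered = 0
        for k in range(n + 1):
            lo, hi = clopper_pearson(k, n, 0.95)
            if lo <= p <= hi:
                covered += (draws == k).sum()
        coverage = covered / 10_000
        assert coverage >= 0.95 - 3 * math.sqrt(0.95 * 0.05 / 10_000)


def test_clopper_pearson_rejects_bad_inputs():
    with pytest.raises(ValueError):
        clopper_pearson(5, 3)
    with pytest.raises(ValueError):
        clopper_pearson(1, 3, level=1.5)


# ------------------------------------------------------------ rank tests
def test_mann_whitney_exact_separated_groups():
    res = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.method == "exact"
    assert res.p_value == pytest.approx(0.1)  # 2 * 1/C(6,3)


def test_mann_whitney_identical_split_is_null():
    res = mann_whitney_u([1, 2, 3, 4], [1.5, 2.5, 3.5, 4.5])
    assert res.p_value >= 0.5


def mw_oracle(x, y):
    pooled = list(x) + list(y)
    nx = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) + 0.5 * sum(
        1 for xi in x for yj in y if xi == yj
    )
    mu = nx * len(y) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(1 for xi in xs for yj in ys if xi > yj) + 0.5 * sum(
            1 for xi in xs for yj in ys if xi == yj
        )
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def test_mann_whitney_matches_enumeration_oracle(rng):
    for _ in range(20):
        x = rng.normal(size=5)
        y = rng.normal(size=4)
        res = mann_whitney_u(x, y)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(mw_oracle(x, y), abs=1e-12)


def test_mann_whitney_approximation_close_to_exact(rng):
    # continuity-corrected normal approximation within 0.02 at n=10 per arm
    for _ in range(20):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        exact = mann_whitney_u(x, y, exact_max_n=10)
        approx = mann_whitney_u(x, y, exact_max_n=0)
        assert exact.method == "exact" and approx.method == "normal_approx"
        assert abs(exact.p_value - approx.p_value) < 0.02


def test_wilcoxon_all_positive_equal_differences():
    res = wilcoxon_signed_rank([1.0] * 6)
    assert res.method == "exact"
    assert res.p_value == pytest.approx(2 / 64)


def test_wilcoxon_antisymmetric_differences_null():
    res = wilcoxon_signed_rank([3.0, -3.0, 1.0, -1.0])
    assert res.p_value == 1.0


def test_wilcoxon_drops_zeros_and_errors_when_all_zero():
    assert wilcoxon_signed_rank([0.0, 0.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0]).p_value == pytest.approx(2 / 64)
    with pytest.raises(ValueError):
        wilcoxon_signed_rank([0.0, 0.0])


def wilcoxon_oracle(diffs):
    d = [x for x in diffs if x != 0]
    n = len(d)
    ranks = {}
    s = sorted(range(n), key=lambda i: abs(d[i]))
    i = 0
    while i < n:
        j = i
        while j + 1 < n and abs(d[s[j + 1]]) == abs(d[s[i]]):
            j += 1
        for k in range(i, j + 1):
            ranks[s[k]] = (i + j) / 2 + 1
        i = j + 1
    w_obs = sum(ranks[i] for i in range(n) if d[i] > 0)
    mu = n * (n + 1) / 4
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(ranks[i] for i in range(n) if signs[i])
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / 2**n


def test_wilcoxon_matches_enumeration_oracle(rng):
    for _ in range(15):
        d = rng.normal(size=8)
        res = wilcoxon_signed_rank(d)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(wilcoxon_oracle(d), abs=1e-12)


def test_wilcoxon_approximation_close_to_exact(rng):
    for _ in range(15):
        d = rng.normal(size=12)
        exact = wilcoxon_signed_rank(d, exact_max_n=15)
        approx = wilcoxon_signed_rank(d, exact_max_n=0)
        assert abs(exact.p_value - approx.p_value) < 0.02


# ------------------------------------------------------------ simon design
def trial_design():
    return SimonDesign(n1=41, r1=3, n=73, r=13, p0=0.10, p1=0.25,
                       alpha_one_sided=0.016, beta=0.10)


def test_simon_oc_degenerate_p_zero():
    reject, pet, _ = simon_oc(trial_design(), 0.0)
    assert reject == 0.0
    assert pet == 1.0


def test_simon_oc_trial_design_exact_values():
    # exact binomial operating characteristics of the published boundaries
    reject0, pet, en = simon_oc(trial_design(), 0.10)
    reject1, _, _ = simon_oc(trial_design(), 0.25)
    assert reject0 == pytest.approx(0.012597, abs=1e-6)
    assert reject1 == pytest.approx(0.902992, abs=1e-6)
    assert reject1 >= 0.90
    assert reject0 == pytest.approx(simon_reject_oracle(41, 3, 73, 13, 0.10), abs=1e-12)


def test_simon_oc_single_stage_reduces_to_binomial_test():
    from scipy.stats import binom

    d = SimonDesign(n1=20, r1=3, n=20, r=3, p0=0.10, p1=0.30,
                    alpha_one_sided=0.05, beta=0.2)
    reject, _, en = simon_oc(d, 0.10)
    assert reject == pytest.approx(float(binom.sf(3, 20, 0.10)), abs=1e-12)
    assert en == 20


def test_simon_oc_monte_carlo_agreement(rng):
    d = trial_design()
    p = 0.25
    n_rep = 100_000
    x1 = rng.binomial(d.n1, p, size=n_rep)
    x2 = rng.binomial(d.n - d.n1, p, size=n_rep)
    rejected = ((x1 > d.r1) & (x1 + x2 > d.r)).mean()
    exact = simon_oc(d, p)[0]
    se = math.sqrt(exact * (1 - exact) / n_rep)
    assert abs(rejected - exact) < 3 * se


def test_simon_search_recovers_trial_design():
    d = simon_search(0.10, 0.25, 0.016, 0.10, n_max=100)
    assert (d.n1, d.n, d.r) == (41, 73, 13)
    assert d.attained_alpha <= 0.016
    assert d.attained_power >= 0.90
    # self-consistency through the operating-characteristic formula
    assert simon_oc(d, 0.10)[0] == pytest.approx(d.attained_alpha, abs=1e-12)
    assert simon_oc(d, 0.25)[0] == pytest.approx(d.attained_power, abs=1e-12)


def test_simon_search_matches_bruteforce_oracle():
    d = simon_search(0.10, 0.50, 0.05, 0.20, n_max=40)
    oracle = simon_minimax_oracle(0.10, 0.50, 0.05, 0.20, 40)
    assert (d.n1, d.r1, d.n, d.r) == oracle[1:]


def test_simon_search_infeasible_raises():
    with pytest.raises(ValueError, match="feasible"):
        simon_search(0.10, 0.12, 0.05, 0.10, n_max=30)
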