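"""Exact and rank-based statistics for single-arm window trials.

Implements the small set of tests a phase II biomarker trial actually uses:
two-sided Fisher's exact test on 2x2 tables, exact (Clopper-Pearson) binomial
confidence intervals, Mann-Whitney U and Wilcoxon signed-rank tests with
exact small-sample null distributions, and Simon two-stage designs -- exact
operating characteristics plus an exhaustive minimax/optimal design search.

All "exact" computations enumerate the relevant discrete null distribution;
scipy.stats supplies the underlying hypergeometric/binomial/beta
distributions but every decision rule and enumeration lives here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import binom, hypergeom, norm

__all__ = [
    "ContingencyTable2x2",
    "SimonDesign",
    "RankTestResult",
    "fisher_exact_two_sided",
    "clopper_pearson",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "simon_oc",
    "simon_search",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table of counts; rows = biomarker class, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name!r} must be a nonnegative integer, got {v!r}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact_two_sided(
    table: ContingencyTable2x2 | Sequence[Sequence[int]],
    method: Literal["small_p", "doubling"] = "small_p",
) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    The default ``small_p`` convention sums hypergeometric probabilities of
    every table with the observed margins whose probability does not exceed
    that of the observed table (with a small relative tolerance for floating
    point ties). ``doubling`` doubles the smaller one-sided tail, capped at 1.

    A table with an empty row or column margin carries no information about
    association; p = 1.0 is returned.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, col1, n = a + b, a + c, table.n
    if row1 in (0, n) or col1 in (0, n):
        return 1.0
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]
    if method == "small_p":
        p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    elif method == "doubling":
        lower = float(pmf[support <= a].sum())
        upper = float(pmf[support >= a].sum())
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError(f"unknown method {method!r}")
    return min(p, 1.0)


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) confidence interval as fractions.

    Bounds are beta-distribution quantiles; the lower bound is 0 for zero
    successes and the upper bound 1 when all trials succeed.
    """
    if not 0 <= successes <= n or n <= 0:
        raise ValueError(f"need 0 <= successes <= n with n > 0, got {successes}/{n}")
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(beta_dist.ppf(alpha / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(beta_dist.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lower, upper


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_value: float
    method: Literal["exact", "normal_approx"]


def _mann_whitney_exact(x: np.ndarray, y: np.ndarray) -> RankTestResult:
    # Enumerate all assignments of the pooled sample to group labels.
    pooled = np.concatenate([x, y])
    nx = len(x)
    ranks = _midranks(pooled)
    u_obs = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    mu = nx * len(y) / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        u = float(ranks[list(idx)].sum() - nx * (nx + 1) / 2)
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return RankTestResult(u_obs, count / total, "exact")


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 10
) -> RankTestResult:
    """Two-sided Mann-Whitney U test.

    Uses full enumeration of the exact null distribution when both groups
    have at most ``exact_max_n`` observations and the data are tie-free;
    otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(x) <= exact_max_n and len(y) <= exact_max_n and no_ties:
        return _mann_whitney_exact(x, y)
    nx, ny = len(x), len(y)
    ranks = _midranks(pooled)
    u = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    mu = nx * ny / 2
    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    sigma2 = nx * ny / 12 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return RankTestResult(u, 1.0, "normal_approx")
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)  # continuity corrected
    p = 2 * norm.sf(max(z, 0.0))
    return RankTestResult(u, min(float(p), 1.0), "normal_approx")


def wilcoxon_signed_rank(
    differences: Sequence[float], exact_max_n: int = 15
) -> RankTestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped. For at most ``exact_max_n`` nonzero pairs
    the null distribution is enumerated over all sign assignments; beyond
    that a continuity-corrected normal approximation with tie correction.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero; test undefined")
    ranks = _midranks(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4
    if n <= exact_max_n:
        count = 0
        for signs in itertools.product((0, 1), repeat=n):
            w = float(sum(r for r, s in zip(ranks, signs) if s))
            if abs(w - mu) >= abs(w_pos - mu) - 1e-12:
                count += 1
        return RankTestResult(w_pos, count / 2**n, "exact")
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24 - float((tie_counts**3 - tie_counts).sum()) / 48
    z = (abs(w_pos - mu) - 0.5) / math.sqrt(sigma2)
    p = 2 * norm.sf(max(z, 0.0))
    return RankTestResult(w_pos, min(float(p), 1.0), "normal_approx")


@dataclass
class SimonDesign:
    """Simon two-stage design: stop for futility after stage 1 if responses
    <= r1 of n1; declare the treatment inactive at the end if total responses
    <= r of n. ``attained_*`` fields are exact binomial quantities filled in
    by :func:`simon_search` or :func:`simon_oc`."""

    n1: int
    r1: int
    n: int
    r: int
    p0: float
    p1: float
    alpha_one_sided: float
    beta: float
    attained_alpha: float | None = None
    attained_power: float | None = None
    pet_p0: float | None = None
    expected_n_p0: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.r1 < self.n1 <= self.n):
            raise ValueError(f"need 0 <= r1 < n1 <= n, got r1={self.r1}, n1={self.n1}, n={self.n}")
        if not (self.r1 <= self.r < self.n):
            raise ValueError(f"need r1 <= r < n, got r1={self.r1}, r={self.r}, n={self.n}")
        if not (0 <= self.p0 < self.p1 <= 1):
            raise ValueError("need 0 <= p0 < p1 <= 1")


def simon_oc(design: SimonDesign, p: float) -> tuple[float, float, float]:
    """Exact operating characteristics of a two-stage design at response
    probability ``p``: (rejection probability of H0, probability of early
    termination, expected sample size)."""
    n1, r1, n, r = design.n1, design.r1, design.n, design.r
    n2 = n - n1
    x1 = np.arange(r1 + 1, n1 + 1)
    if n2 == 0:
        reject = float(binom.sf(r, n1, p))
    else:
        reject = float(np.sum(binom.pmf(x1, n1, p) * binom.sf(r - x1, n2, p)))
    pet = float(binom.cdf(r1, n1, p))
    return reject, pet, n1 + (1 - pet) * n2


def simon_search(
    p0: float,
    p1: float,
    alpha_one_sided: float,
    beta: float,
    n_max: int = 100,
    criterion: Literal["minimax", "optimal"] = "minimax",
) -> SimonDesign:
    """Exhaustive exact search for a Simon two-stage design.

    Scans all (n1, r1, n, r) with n <= n_max for designs with exact type-I
    error <= ``alpha_one_sided`` at p0 and power >= 1 - ``beta`` at p1.
    ``minimax`` returns the feasible design with the smallest maximum sample
    size n, ties broken by smallest expected sample size under p0;
    ``optimal`` minimises the expected sample size under p0 outright.
    """
    if not 0 <= p0 < p1 <= 1:
        raise ValueError("need 0 <= p0 < p1 <= 1")
    if not (0 < alpha_one_sided < 1 and 0 < beta < 1):
        raise ValueError("error rates must lie in (0,1)")
    best: tuple[float, int, int, int, int, float, float] | None = None
    for n in range(2, n_max + 1):
        for n1 in range(1, n):
            n2 = n - n1
            x1 = np.arange(0, n1 + 1)
            b0 = binom.pmf(x1, n1, p0)
            b1 = binom.pmf(x1, n1, p1)
            rr = np.arange(0, n)
            k = rr[None, :] - x1[:, None]
            contrib0 = b0[:, None] * binom.sf(k, n2, p0)
            contrib1 = b1[:, None] * binom.sf(k, n2, p1)
            # tail[i, r] = P(reject | continue iff X1 >= i)
            tail0 = np.cumsum(contrib0[::-1], axis=0)[::-1]
            tail1 = np.cumsum(contrib1[::-1], axis=0)[::-1]
            cdf0 = np.cumsum(b0)
            for r1 in range(0, n1):
                alphas = tail0[r1 + 1]
                powers = tail1[r1 + 1]
                ok = np.nonzero((alphas <= alpha_one_sided) & (powers >= 1 - beta) & (rr >= r1))[0]
                if ok.size == 0:
                    continue
                pet = float(cdf0[r1])
                en = n1 + (1 - pet) * n2
                for r in ok:
                    cand = (en, n1, r1, n, int(r), float(alphas[r]), float(powers[r]))
                    if best is None or cand[0] < best[0] - 1e-12:
                        best = cand
        if criterion == "minimax" and best is not None:
            break  # smallest n reached; ties within n already resolved by EN
    if best is None:
        raise ValueError(
            f"no feasible design with n <= {n_max} for p0={p0}, p1={p1}, "
            f"alpha={alpha_one_sided}, beta={beta}"
        )
    en, n1, r1, n, r, a, pw = best
    design = SimonDesign(
        n1=n1, r1=r1, n=n, r=r, p0=p0, p1=p1,
        alpha_one_sided=alpha_one_sided, beta=beta,
        attained_alpha=a, attained_power=pw,
    )
    _, pet, e_n = simon_oc(design, p0)
    design.pet_p0 = pet
    design.expected_n_p0 = e_n
    return design
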