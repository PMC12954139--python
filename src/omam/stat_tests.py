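"""Nonparametric and exact tests used throughout the package.

Five procedures: Spearman rank correlation, Mann-Whitney U, Wilcoxon
signed-rank, the exact binomial test, and McNemar's test for paired
binary outcomes.  Each switches between an exact small-sample method and
a classical approximation at a fixed, documented sample-size point, and
every result records which method produced it.

Conventions (recorded in every :class:`TestResult`):

* two-sided p-values for the discrete exact tests use the doubled
  smaller tail, capped at 1;
* ties are handled by midranks;
* zero differences in the signed-rank test are dropped and the dropped
  count logged.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "spearman",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "binomial_test",
    "mcnemar",
]

logger = logging.getLogger(__name__)

# exact-method switchover points (see module docstring); override per call
SPEARMAN_EXACT_MAX_N = 10
MANN_WHITNEY_EXACT_MAX_N = 12
WILCOXON_EXACT_MAX_N = 15
MCNEMAR_EXACT_BELOW = 25


@dataclass
class TestResult:
    """Outcome of one hypothesis test.

    ``status`` is ``"ok"`` for a computable result, ``"not_computable"``
    when the statistic is undefined (e.g. zero-variance input), or
    ``"no_discordance"`` for a McNemar test with no discordant pairs.
    """

    test: str
    statistic: float
    p_value: float
    method: str          # "exact" | "normal_approx" | "t_approx" | "chi_square_cc"
    sidedness: str = "two_sided"
    n: object = None
    status: str = "ok"
    detail: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.status == "ok" and self.p_value < 0.05

    def to_json(self) -> dict:
        return {
            "test": self.test,
            "statistic": None if self.statistic is None or not np.isfinite(self.statistic)
            else float(self.statistic),
            "p": None if self.p_value is None or not np.isfinite(self.p_value)
            else float(self.p_value),
            "method": self.method,
            "sidedness": self.sidedness,
            "n": self.n,
            "status": self.status,
        }


def _doubled_tail(lower: float, upper: float) -> float:
    return min(1.0, 2.0 * min(lower, upper))


def spearman(x, y, exact_max_n: int = SPEARMAN_EXACT_MAX_N) -> TestResult:
    """Spearman rank correlation with midrank ties.

    rho is the Pearson correlation of midranks.  The two-sided p-value is
    exact (full permutation enumeration) for n <= ``exact_max_n`` and a
    t approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 for a Spearman correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult("spearman", np.nan, np.nan, "none", n=n,
                          status="not_computable",
                          detail={"reason": "zero-variance input"})
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        p = _spearman_exact_p(rx, ry, rho)
        return TestResult("spearman", rho, p, "exact", n=n)
    res = stats.spearmanr(x, y)
    return TestResult("spearman", rho, float(res.pvalue), "t_approx", n=n)


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """P(|rho| >= |rho_obs|) over all n! equally likely pairings."""
    n = len(rx)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    t_obs = abs(rho_obs) * denom - 1e-9  # tolerance for float ties
    count = 0
    total = math.factorial(n)
    chunk = 200_000
    it = itertools.permutations(range(n))
    while True:
        block = list(itertools.islice(it, chunk))
        if not block:
            break
        perm = np.array(block, dtype=np.int8)
        t = np.abs(ry[perm] @ rx)
        count += int(np.sum(t >= t_obs))
    return count / total


def mann_whitney(group_a, group_b,
                 exact_max_n: int = MANN_WHITNEY_EXACT_MAX_N) -> TestResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    Exact p by enumeration of group labelings (midranks, so ties are
    handled exactly too) when ``len(a) + len(b) <= exact_max_n``;
    otherwise a normal approximation with tie and continuity corrections.
    The reported statistic is U for ``group_a``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2)
    has_ties = len(np.unique(pooled)) < len(pooled)
    if na + nb <= exact_max_n:
        u_min = min(u_a, na * nb - u_a)
        p = _mann_whitney_exact_p(ranks, na, nb, u_min)
        return TestResult("mann_whitney", u_a, p, "exact", n=(na, nb))
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return TestResult("mann_whitney", u_a, float(res.pvalue),
                      "normal_approx", n=(na, nb),
                      detail={"ties": bool(has_ties)})


def _mann_whitney_exact_p(ranks: np.ndarray, na: int, nb: int, u_min: float) -> float:
    """Doubled smaller tail of the exact U null distribution (no ties)."""
    count = 0
    total = math.comb(na + nb, na)
    base = na * (na + 1) / 2
    for combo in itertools.combinations(range(na + nb), na):
        u = ranks[list(combo)].sum() - base
        if min(u, na * nb - u) <= u_min + 1e-9:
            count += 1
    # the null distribution of min-tail membership already covers both
    # tails, so this is the two-sided p directly
    return min(1.0, count / total)


def wilcoxon_signed_rank(differences,
                         exact_max_n: int = WILCOXON_EXACT_MAX_N) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (classical treatment; the count is
    logged and recorded in ``detail``).  |d| is midranked; W+ is the sum
    of ranks of positive differences.  Exact p by enumerating all sign
    assignments for n <= ``exact_max_n``; otherwise a normal
    approximation with continuity correction.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or len(d) == 0:
        raise ValueError("differences must be a nonempty 1-d array")
    n_zero = int(np.sum(d == 0))
    d = d[d != 0]
    if n_zero:
        logger.info("wilcoxon_signed_rank: dropped %d zero differences", n_zero)
    n = len(d)
    if n == 0:
        return TestResult("wilcoxon_signed_rank", np.nan, np.nan, "none", n=0,
                          status="not_computable",
                          detail={"reason": "all differences zero",
                                  "n_zeros_dropped": n_zero})
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        # enumerate all 2^n sign vectors; ties in |d| are fine because the
        # midranks are held fixed
        signs = np.array(list(itertools.product([0.0, 1.0], repeat=n)))
        w_null = signs @ ranks
        lower = float(np.mean(w_null <= w_plus + 1e-9))
        upper = float(np.mean(w_null >= w_plus - 1e-9))
        p = _doubled_tail(lower, upper)
        method = "exact"
    else:
        res = stats.wilcoxon(d, correction=True, method="approx")
        p = float(res.pvalue)
        method = "normal_approx"
    return TestResult("wilcoxon_signed_rank", w_plus, p, method, n=n,
                      detail={"n_zeros_dropped": n_zero})


def binomial_test(k: int, n: int, p0: float) -> TestResult:
    """Exact binomial test; two-sided p = doubled smaller tail, capped at 1.

    One-sided tail probabilities are reported in ``detail``.
    """
    if not (0 <= k <= n) or n <= 0:
        raise ValueError("require 0 <= k <= n with n > 0")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie strictly between 0 and 1")
    lower = float(stats.binom.cdf(k, n, p0))
    upper = float(stats.binom.sf(k - 1, n, p0))
    p = _doubled_tail(lower, upper)
    return TestResult("binomial", float(k), p, "exact", n=n,
                      detail={"p_lower": lower, "p_upper": upper,
                              "p0": p0, "proportion": k / n})


def mcnemar(b: int, c: int, exact_below: int = MCNEMAR_EXACT_BELOW) -> TestResult:
    """McNemar's test from the two discordant-pair counts.

    ``b`` and ``c`` count the subjects classified positive by exactly one
    of two paired criteria.  Exact binomial form (doubled smaller tail of
    min(b, c) against Binomial(b+c, 1/2)) when ``b + c < exact_below``;
    continuity-corrected chi-square otherwise.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    m = b + c
    if m == 0:
        return TestResult("mcnemar", 0.0, 1.0, "exact", n=0,
                          status="no_discordance")
    if m < exact_below:
        x = min(b, c)
        p = min(1.0, 2.0 * float(stats.binom.cdf(x, m, 0.5)))
        return TestResult("mcnemar", float(x), p, "exact", n=m)
    chi2 = (abs(b - c) - 1) ** 2 / m
    p = float(stats.chi2.sf(chi2, df=1))
    return TestResult("mcnemar", float(chi2), p, "chi_square_cc", n=m)
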