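"""Independent brute-force oracles for the exact statistical procedures.

Everything here is written from the textbook definitions with no shared
code paths with the package (no scipy, no rank helpers from omam):
midranks by hand, U from pairwise comparisons, p-values by full
enumeration or direct pmf summation.
"""

import itertools
import math


def midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def spearman_exact(x, y):
    """(rho, two-sided p) with p = P(|rho_perm| >= |rho_obs|) over all n!."""
    rx = midranks(list(x))
    ry = midranks(list(y))
    rho = pearson(rx, ry)
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(pearson(rx, list(perm))) >= abs(rho) - 1e-9:
            count += 1
    return rho, count / total


def mann_whitney_u(a, b):
    """U for group a from pairwise comparisons (ties count half)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def mann_whitney_exact(a, b):
    """(U, two-sided p) by enumerating all group labelings of the pool."""
    pool = list(a) + list(b)
    na = len(a)
    u_obs = mann_whitney_u(a, b)
    m_obs = min(u_obs, na * len(b) - u_obs)
    count = total = 0
    for combo in itertools.combinations(range(len(pool)), na):
        ga = [pool[i] for i in combo]
        gb = [pool[i] for i in range(len(pool)) if i not in combo]
        u = mann_whitney_u(ga, gb)
        total += 1
        if min(u, na * len(gb) - u) <= m_obs + 1e-9:
            count += 1
    return u_obs, count / total


def wilcoxon_exact(diffs):
    """(W+, two-sided p) by enumerating all sign assignments; zeros dropped."""
    d = [v for v in diffs if v != 0]
    n = len(d)
    absd = [abs(v) for v in d]
    w_obs = sum(r for r, v in zip(midranks(absd), d) if v > 0)
    lower = upper = total = 0
    for signs in itertools.product([-1, 1], repeat=n):
        w = sum(r for r, s in zip(midranks(absd), signs) if s > 0)
        total += 1
        if w <= w_obs + 1e-9:
            lower += 1
        if w >= w_obs - 1e-9:
            upper += 1
    p = min(1.0, 2.0 * min(lower / total, upper / total))
    return w_obs, p


def binom_pmf(k, n, p):
    return math.comb(n, k) * p**k * (1 - p) ** (n - k)


def binomial_two_sided(k, n, p0):
    """Doubled smaller tail from direct pmf summation."""
    lower = sum(binom_pmf(i, n, p0) for i in range(0, k + 1))
    upper = sum(binom_pmf(i, n, p0) for i in range(k, n + 1))
    return min(1.0, 2.0 * min(lower, upper))


def mcnemar_exact(b, c):
    m = b + c
    if m == 0:
        return 1.0
    x = min(b, c)
    tail = sum(binom_pmf(i, m, 0.5) for i in range(0, x + 1))
    return min(1.0, 2.0 * tail)


def quantile_weibull(sample, p):
    """Sorted-sample interpolation at rank h = (n+1) p, clamped."""
    xs = sorted(sample)
    n = len(xs)
    h = (n + 1) * p
    if h <= 1:
        return xs[0]
    if h >= n:
        return xs[-1]
    lo = int(math.floor(h))
    frac = h - lo
    return xs[lo - 1] + frac * (xs[lo] - xs[lo - 1])
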