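"""Independent oracles for the estimator, the scan and the enrichment test.

Everything here is deliberately written against the published formulas in a
different style from the package: exact rational arithmetic for the
variance components and the hypergeometric tail, plain sorted-list
arithmetic for quantiles, and brute-force enumeration for window calling.
Nothing imports from rddscan.
"""

from __future__ import annotations

import math
from fractions import Fraction as F


def wc_theta_exact(pops: list[tuple[int, int, int]]) -> F | None:
    """Weir-Cockerham theta from integer counts, in exact rationals.

    pops: per population (n_called, alt_copies, het_individuals).
    Returns None when theta is undefined (a + b + c == 0) and raises on a
    population with no called individuals or mean sample size 1.
    """
    r = len(pops)
    n = [F(x[0]) for x in pops]
    if any(ni < 1 for ni in n):
        raise ValueError("population with no called individuals")
    p = [F(x[1], 2 * x[0]) for x in pops]
    h = [F(x[2], x[0]) for x in pops]
    n_sum = sum(n)
    n_bar = n_sum / r
    if n_bar == 1:
        raise ValueError("mean sample size 1")
    n_c = (n_sum - sum(ni * ni for ni in n) / n_sum) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / n_sum
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n, h)) / n_sum
    inner = p_bar * (1 - p_bar) - F(r - 1, r) * s2
    a = (n_bar / n_c) * (s2 - (inner - h_bar / 4) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (inner - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2
    denom = a + b + c
    if denom == 0:
        return None
    return a / denom


def quantile_type7(values, q: float) -> float:
    """Linear-interpolation (type 7) quantile of a sequence."""
    xs = sorted(float(v) for v in values)
    pos = (len(xs) - 1) * q
    lo = math.floor(pos)
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (pos - lo) * (xs[hi] - xs[lo])


def rdd_brute_force(
    focal: dict[tuple, float],
    comparisons: dict[str, dict[tuple, float]],
    top_fraction: float,
    bottom_fraction: float,
) -> set[tuple]:
    """Windows passing the quantile-intersection rule, by enumeration.

    focal / comparisons map window keys (chrom, start, end) to z values;
    eligibility is presence in every table.
    """
    eligible = set(focal)
    for table in comparisons.values():
        eligible &= set(table)
    hi = quantile_type7([focal[w] for w in eligible], 1.0 - top_fraction)
    thresholds = {
        line: quantile_type7([table[w] for w in eligible], bottom_fraction)
        for line, table in comparisons.items()
    }
    called = set()
    for w in eligible:
        if focal[w] < hi:
            continue
        if all(comparisons[l][w] <= thresholds[l] for l in comparisons):
            called.add(w)
    return called


def hypergeom_tail_exact(N: int, K: int, n: int, k: int) -> F:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), by big-integer summation."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(n, K) + 1):
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return F(acc, total)


def overlaps_inclusive(a_start, a_end, b_start, b_end) -> bool:
    """1-based inclusive interval intersection by >= 1 bp."""
    return a_start <= b_end and b_start <= a_end
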