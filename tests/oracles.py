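"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths they check: Fisher's exact test
by rational hypergeometric enumeration, Mann-Whitney U by enumerating
group assignments, and coverage breadth by a per-base loop.
"""

from fractions import Fraction
from itertools import combinations
from math import comb


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher P by exact rational enumeration over the support.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose point probability is <= that of the observed table
    (probability-mass convention), in exact Fraction arithmetic.
    """
    n1, n2 = a + b, c + d
    k = a + c
    n = n1 + n2
    denom = comb(n, k)

    def prob(x: int) -> Fraction:
        return Fraction(comb(n1, x) * comb(n2, k - x), denom)

    p_obs = prob(a)
    lo, hi = max(0, k - n2), min(k, n1)
    total = sum((prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs), Fraction(0))
    return float(min(total, Fraction(1)))


def mann_whitney_two_sided_enumeration(sample_a, sample_b) -> float:
    """Two-sided exact Mann-Whitney P as 2*min(tail) over all assignments."""
    pooled = list(sample_a) + list(sample_b)
    n, n_a = len(pooled), len(sample_a)

    def u_of(group_a, group_b) -> float:
        return sum(
            sum(1.0 for y in group_b if x > y) + sum(0.5 for y in group_b if x == y)
            for x in group_a
        )

    u_obs = u_of(sample_a, sample_b)
    lower = upper = total = 0
    for picked in combinations(range(n), n_a):
        chosen = set(picked)
        xs = [pooled[i] for i in picked]
        ys = [pooled[i] for i in range(n) if i not in chosen]
        u = u_of(xs, ys)
        total += 1
        if u <= u_obs + 1e-9:
            lower += 1
        if u >= u_obs - 1e-9:
            upper += 1
    return min(1.0, 2 * min(lower, upper) / total)


def breadth_per_base(track, exons, min_depth: int, chrom: str) -> float:
    """Coverage breadth by looping every exonic base (0-based half-open)."""
    covered = 0
    length = 0
    for start, end in exons:
        for pos in range(start, end):
            length += 1
            if track.depth_at(chrom, pos) >= min_depth:
                covered += 1
    return covered / length
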