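"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive: exact rational arithmetic, per-base
set algebra, exhaustive enumeration. None of it shares code with the
package under test.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def exact_binom_cdf(k: int, n: int, p: Fraction) -> Fraction:
    """P(X <= k), X ~ Binomial(n, p), by exact pmf summation."""
    if n == 0:
        return Fraction(1)
    k = min(k, n)
    q = 1 - p
    return sum(comb(n, j) * p**j * q ** (n - j) for j in range(k + 1))


def exact_binom_sf_inclusive(k: int, n: int, p: Fraction) -> Fraction:
    """Upper tail P(X >= k)."""
    q = 1 - p
    return sum(comb(n, j) * p**j * q ** (n - j) for j in range(k, n + 1))


def oracle_side_pvalue(vr: int, sr: int, vs: int, ss: int) -> Fraction:
    if vr + sr == 0:
        return Fraction(1)
    return exact_binom_cdf(vr, vr + sr, Fraction(vs, vs + ss))


def count_in(midpoints, lo, hi) -> int:
    return sum(1 for m in midpoints if lo <= m < hi)


def oracle_score_valley(
    midpoints,
    anchor: int,
    valley_sizes=(250, 300, 350, 400),
    shoulder_sizes=(300, 400, 500),
    chrom_len: int | None = None,
):
    """Exhaustively recompute every side score by exact binomial summation.

    Returns (best_left, best_right, final) as Fractions, plus the number of
    geometry combinations enumerated per side; None when a side has no
    fitting geometry.
    """
    L = chrom_len if chrom_len is not None else float("inf")
    per_side = {}
    counts = {}
    for side in ("left", "right"):
        best = None
        n_combos = 0
        for vs in valley_sizes:
            half_right = vs // 2
            vstart = anchor - (vs - half_right)
            vend = anchor + half_right
            if vstart < 0 or vend > L:
                continue
            vr = count_in(midpoints, vstart, vend)
            for ss in shoulder_sizes:
                if side == "left":
                    s_lo, s_hi = vstart - ss, vstart
                else:
                    s_lo, s_hi = vend, vend + ss
                if s_lo < 0 or s_hi > L:
                    continue
                n_combos += 1
                sr = count_in(midpoints, s_lo, s_hi)
                p = oracle_side_pvalue(vr, sr, vs, ss)
                if best is None or p < best:
                    best = p
        per_side[side] = best
        counts[side] = n_combos
    if per_side["left"] is None or per_side["right"] is None:
        return None, None, None, counts
    final = max(per_side["left"], per_side["right"])
    return per_side["left"], per_side["right"], final, counts


def per_base_union(intervals) -> set[tuple[str, int]]:
    """The exact base set covered by a collection of (chrom,start,end)."""
    bases: set[tuple[str, int]] = set()
    for chrom, start, end in intervals:
        for p in range(start, end):
            bases.add((chrom, p))
    return bases


def oracle_point_distance(start: int, end: int, p: int) -> int:
    """Min distance from p to any covered base index in [start, end)."""
    return min(abs(p - b) for b in range(start, end))


def oracle_rank_sum(a, b) -> float:
    """Mann-Whitney U for sample a by explicit pairwise comparison."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u
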