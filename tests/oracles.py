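"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity by exhaustive enumeration or the textbook
formula, sharing no code with the implementation it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np


def stable_pairs_oracle(
    gene_ids: np.ndarray, values: np.ndarray, stability_fraction: float = 1.0
) -> set[tuple[int, int, int]]:
    """Every unordered pair checked against every sample, pure python."""
    n, m = values.shape
    need = math.ceil(stability_fraction * m)
    out: set[tuple[int, int, int]] = set()
    for i, j in combinations(range(n), 2):
        gt = sum(1 for s in range(m) if values[i, s] > values[j, s])
        lt = sum(1 for s in range(m) if values[i, s] < values[j, s])
        a, b = int(gene_ids[i]), int(gene_ids[j])
        if a > b:
            a, b = b, a
            gt, lt = lt, gt
        if gt >= need:
            out.add((a, b, 1))
        elif lt >= need:
            out.add((a, b, -1))
    return out


def reversal_oracle(
    mature: set[tuple[int, int, int]], immature: set[tuple[int, int, int]]
) -> set[tuple[int, int, int]]:
    """Pairs stable in both conditions with opposite directions (mature direction kept)."""
    imm = {(a, b): d for a, b, d in immature}
    return {(a, b, d) for a, b, d in mature if imm.get((a, b)) == -d}


def fisher_two_sided_oracle(table) -> float:
    """Exact two-sided Fisher p by integer-arithmetic enumeration.

    Sums hypergeometric weights of every table with the observed margins
    whose weight is no greater than the observed weight (with the standard
    1e-7 relative slack for equal-probability ties).
    """
    (a, b), (c, d) = [[int(x) for x in row] for row in table]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    w_obs = math.comb(r1, a) * math.comb(r2, c)
    total = 0
    for a2 in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = math.comb(r1, a2) * math.comb(r2, c1 - a2)
        # integer form of: w <= w_obs * (1 + 1e-7)
        if w * 10_000_000 <= w_obs * 10_000_001:
            total += w
    return float(Fraction(total, math.comb(n, c1)))


def bh_oracle(p_values) -> list[float]:
    """Step-up definition: adj_i = min_{j >= rank(i)} p_(j) * m / j, capped at 1."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        adjusted[i] = running
    return adjusted


def hypergeom_tail_oracle(k: int, universe: int, set_size: int, list_size: int) -> float:
    """P(overlap >= k) by direct summation of the hypergeometric pmf."""
    denom = math.comb(universe, list_size)
    total = Fraction(0)
    for i in range(k, min(set_size, list_size) + 1):
        total += Fraction(
            math.comb(set_size, i) * math.comb(universe - set_size, list_size - i), denom
        )
    return float(total)


def backbone_oracle(pairs: set[tuple[int, int, int]]):
    """Per-gene below/above partner sets by direct scan of the pair list."""
    below: dict[int, set[int]] = {}
    above: dict[int, set[int]] = {}
    for a, b, d in pairs:
        hi, lo = (a, b) if d == 1 else (b, a)
        below.setdefault(hi, set()).add(lo)
        above.setdefault(lo, set()).add(hi)
    return below, above
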