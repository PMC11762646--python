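"""Independent brute-force oracles used to freeze expected test values.

Everything here is deliberately naive (enumeration, direct summation,
partial sums) and shares no code with the implementation under test.
"""

from __future__ import annotations

import math
from itertools import combinations


def hypergeom_tail_enum(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    marked = set(range(K))
    total = 0
    ge = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            ge += 1
    return ge / total


def zeta_partial_sum(alpha: float, terms: int = 2_000_000) -> float:
    """Riemann zeta by partial sum plus an integral tail bound midpoint."""
    s = sum(x ** -alpha for x in range(1, terms + 1))
    # integral bracket of the tail: between the two bounds
    lo = (terms + 1) ** (1 - alpha) / (alpha - 1)
    hi = terms ** (1 - alpha) / (alpha - 1)
    return s + (lo + hi) / 2


def mi_direct(joint: list[list[int]]) -> float:
    """Plug-in MI in nats by direct summation over a joint count table."""
    n = sum(sum(row) for row in joint)
    rows = [sum(r) / n for r in joint]
    cols = [sum(joint[i][j] for i in range(len(joint))) / n
            for j in range(len(joint[0]))]
    mi = 0.0
    for i, row in enumerate(joint):
        for j, c in enumerate(row):
            if c:
                p = c / n
                mi += p * math.log(p / (rows[i] * cols[j]))
    return mi


def pearson_direct(x: list[float], y: list[float]) -> float:
    """Product-moment correlation straight from the defining formula."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def bh_stepup(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg by the textbook step-up recursion."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvals[i] * m / rank)
        adj[i] = val
        prev = val
    return adj
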