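"""Independent brute-force oracles used only by the test suite.

Each function here recomputes a statistic by the most direct route possible
(explicit loops, exact rational arithmetic, enumeration), sharing no code
with the implementation it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def brute_force_es(ordered_genes, metric, members, weight_p=1.0):
    """Weighted running-sum enrichment score by a plain O(N) loop."""
    members = set(members)
    hits = [g in members for g in ordered_genes]
    n = len(ordered_genes)
    n_hit = sum(hits)
    assert 0 < n_hit < n
    denom = sum(abs(m) ** weight_p for m, h in zip(metric, hits) if h)
    running = []
    total = 0.0
    for m, h in zip(metric, hits):
        if h:
            total += (abs(m) ** weight_p / denom) if denom > 0 else 1.0 / n_hit
        else:
            total -= 1.0 / (n - n_hit)
        running.append(total)
    best = max(running, key=abs)
    return best, running


def ks_statistic(ordered_genes, members):
    """Signed two-sample KS statistic between hit and miss placements."""
    members = set(members)
    n = len(ordered_genes)
    n_hit = sum(1 for g in ordered_genes if g in members)
    n_miss = n - n_hit
    best = 0.0
    h = m = 0
    for g in ordered_genes:
        if g in members:
            h += 1
        else:
            m += 1
        dev = h / n_hit - m / n_miss
        if abs(dev) > abs(best):
            best = dev
    return best


def fisher_enumeration(a, b, c, d):
    """Two-sided Fisher p by exact-Fraction enumeration of the support."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = math.comb(n, row1)

    def point(k):
        return Fraction(math.comb(col1, k) * math.comb(n - col1, row1 - k), denom)

    p_obs = point(a)
    kmin = max(0, row1 + col1 - n)
    kmax = min(row1, col1)
    total = Fraction(0)
    for k in range(kmin, kmax + 1):
        pk = point(k)
        if pk <= p_obs:
            total += pk
    return float(total)


def average_ranks(x):
    """Average ranks computed by explicit sorting and tie grouping."""
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_rank_pearson(x, y):
    """Spearman rho as Pearson correlation of hand-computed average ranks."""
    rx = average_ranks(list(x))
    ry = average_ranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / math.sqrt(vx * vy)


def all_tables_with_margins_leq(max_margin):
    """All 2x2 count tables whose four margins are all <= max_margin."""
    out = []
    for a in range(max_margin + 1):
        for b in range(max_margin + 1 - a):
            for c in range(max_margin + 1 - a):
                if a + b + c == 0:
                    d_lo = 1
                else:
                    d_lo = 0
                for d in range(d_lo, max_margin + 1 - max(c, b)):
                    out.append((a, b, c, d))
    return out
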