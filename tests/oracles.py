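"""Independent brute-force oracles used by the test suite.

These deliberately use the simplest possible algorithms (per-item loops,
exhaustive enumeration, exact rational arithmetic) and share no code with
the implementation they check.
"""

from __future__ import annotations

import math
from itertools import combinations


def brute_classify(mid: int, genes, window: int = 1000,
                   distant_cutoff: int = 10_000) -> dict:
    """Zone + nearest-anchor classification of one midpoint by exhaustive
    scan over every (gene, anchor) pair.

    Ties in nearest distance go to the lexicographically smallest gene id,
    then TSS before polyA (enforced by scan order and strict '<').
    """
    genes = sorted(genes, key=lambda g: g.gene_id)
    body = any(g.start <= mid < g.end for g in genes)
    up_le = dn_le = False
    for g in genes:
        d_tss = (g.tss - mid) if g.strand == "+" else (mid - g.tss)
        d_pa = (mid - g.polyA) if g.strand == "+" else (g.polyA - mid)
        if 0 < d_tss <= window:
            up_le = True
        if 0 < d_pa <= window:
            dn_le = True
    best = None  # (distance, gene_id, anchor)
    for g in genes:
        for anchor, pos in (("tss", g.tss), ("polyA", g.polyA)):
            d = abs(mid - pos)
            if best is None or d < best[0]:
                best = (d, g.gene_id, anchor)
    if body:
        zone = "GeneBody"
    elif up_le:
        zone = "UpstreamLe1kb"
    elif dn_le:
        zone = "DownstreamLe1kb"
    elif best[0] <= distant_cutoff:
        zone = "UpstreamGt1kb" if best[2] == "tss" else "DownstreamGt1kb"
    else:
        zone = "Distant"
    return {"zone": zone, "nearest_gene": best[1], "nearest_anchor": best[2],
            "distance": best[0]}


def hypergeom_tail_enum(N: int, K: int, n: int, x: int) -> float:
    """P(overlap >= x) by enumerating every size-n draw from an N-element
    universe whose first K elements are the category."""
    category = set(range(K))
    hits = total = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(category.intersection(draw)) >= x:
            hits += 1
    return hits / total


def hypergeom_tail_exact(N: int, K: int, n: int, x: int):
    """P(overlap >= x) by direct summation with exact integer arithmetic."""
    num = sum(math.comb(K, k) * math.comb(N - K, n - k)
              for k in range(x, min(K, n) + 1) if n - k <= N - K)
    return num / math.comb(N, n)


def bh_stepup(pvalues):
    """Textbook Benjamini-Hochberg step-up, computed by the definition:
    q_(i) = min_{j >= i} ( m * p_(j) / j ), input order preserved."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvalues[i] / rank)
        q[i] = running
    return q
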