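"""Independent brute-force oracles used across the test suite.

These deliberately avoid the library code paths (and scipy where the
implementation uses it) so each check is a genuine cross-validation.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from collections import Counter


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive integer enumeration of the margins.

    Enumerates every table with the observed margins, weights each by its
    exact hypergeometric count (math.comb), and sums the weights of tables no
    more probable than the observed one. Ties use the standard relative
    tolerance 1e-7, applied here in exact integer arithmetic.
    """
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(n - r1, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    # include w <= w_obs * (1 + 1e-7), exactly: w * 10^7 <= w_obs * (10^7 + 1)
    threshold = (w_obs * 10_000_001) // 10_000_000
    total = sum(weights)
    return sum(w for w in weights if w <= threshold) / total


def fisher_two_sided_table(n: int, r1: int, c1: int) -> list[float]:
    """Vector of two-sided p-values for every table with the given margins."""
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(n - r1, c1 - k) for k in range(lo, hi + 1)]
    total = sum(weights)
    ordered = sorted(weights)
    prefix = [0]
    for w in ordered:
        prefix.append(prefix[-1] + w)
    out = []
    for w_obs in weights:
        threshold = (w_obs * 10_000_001) // 10_000_000
        out.append(prefix[bisect_right(ordered, threshold)] / total)
    return out


def pairwise_tally(site_calls) -> dict:
    """Per-read tally of joint methylation states for every site pair.

    ``site_calls`` is an iterable of objects with read_id, chrom, position,
    state. Returns {(chrom, pos1, pos2): Counter({'MM': ..., 'MU': ...,
    'UM': ..., 'UU': ...})} with pos1 < pos2.
    """
    by_read: dict[tuple[str, str], dict[int, bool]] = {}
    for call in site_calls:
        by_read.setdefault((call.read_id, call.chrom), {})[call.position] = call.state
    tallies: dict[tuple[str, int, int], Counter] = {}
    for (read_id, chrom), sites in by_read.items():
        positions = sorted(sites)
        for i, p1 in enumerate(positions):
            for p2 in positions[i + 1 :]:
                key = (chrom, p1, p2)
                label = ("M" if sites[p1] else "U") + ("M" if sites[p2] else "U")
                tallies.setdefault(key, Counter())[label] += 1
    return tallies


class UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: int, y: int) -> None:
        self.parent[self.find(x)] = self.find(y)


def cluster_by_union_find(positions: list[int], max_gap: int) -> list[list[int]]:
    """Independent clustering oracle: union all pairs within max_gap."""
    n = len(positions)
    uf = UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[j] - positions[i]) <= max_gap:
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i, p in enumerate(positions):
        groups.setdefault(uf.find(i), []).append(p)
    return sorted([sorted(g) for g in groups.values()])
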