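"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: exact combinatorics
via integer arithmetic, quadratic scans, and transitive-closure merging.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd


def hypergeom_right_tail(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for the 2x2 table's hypergeometric null, by exact
    integer enumeration."""
    N = a + b + c + d
    K = a + c  # "family" column margin
    n = a + b  # "peak" row margin
    denom = comb(N, n)
    total = 0
    for k in range(a, min(K, n) + 1):
        total += comb(K, k) * comb(N - K, n - k)
    return float(Fraction(total, denom))


def binom_right_tail(x: int, n: int, p: float) -> float:
    """P(X >= x) for X ~ Binomial(n, p) by term-by-term summation of the
    mass function."""
    return float(sum(comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(x, n + 1)))


def transitive_closure_clusters(
    intervals: list[tuple[int, int]], gap: int
) -> list[set]:
    """All-pairs merge: intervals whose gap is <= ``gap`` are linked;
    clusters are the connected components of the link graph."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = intervals[i], intervals[j]
            dist = max(s1, s2) - min(e1, e2)
            if dist <= gap:
                union(i, j)
    groups: dict[int, set] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return list(groups.values())


def quadratic_te_counts(
    reads: pd.DataFrame, annotation_df: pd.DataFrame, keycol: str = "insertion_id"
) -> dict:
    """Per-(key, sample) read counts by a double loop; a read counts once
    per key however many fragments it overlaps."""
    counts: dict = {}
    for r in reads.itertuples():
        hit = set()
        for f in annotation_df.itertuples():
            if (
                f.chrom == r.chrom
                and min(r.end, f.end) - max(r.start, f.start) > 0
            ):
                hit.add(getattr(f, keycol))
        for k in hit:
            counts[(k, r.sample_id)] = counts.get((k, r.sample_id), 0) + 1
    return counts
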