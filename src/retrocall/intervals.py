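"""Genomic interval primitives.

All coordinates are 0-based, half-open ``[start, end)``. Writers convert to
1-based only where a named file format requires it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome-anchored half-open span.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name.
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : str
        ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap in bp with ``other`` (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance(self, other: "GenomicInterval") -> float:
        """Gap in bp between the two spans; 0 if they touch or overlap,
        ``inf`` across chromosomes."""
        if self.chrom != other.chrom:
            return float("inf")
        if self.overlap(other) > 0:
            return 0
        return max(self.start, other.start) - min(self.end, other.end)

    def distance_to_point(self, chrom: str, pos: int) -> float:
        """Distance from a point to the nearest edge (0 if inside)."""
        if chrom != self.chrom:
            return float("inf")
        if self.start <= pos < self.end:
            return 0
        return self.start - pos if pos < self.start else pos - (self.end - 1)


class IntervalIndex:
    """Overlap index over a table of intervals.

    Wraps per-chromosome :class:`intervaltree.IntervalTree`; payloads are row
    indices of the source DataFrame.
    """

    def __init__(self, df: pd.DataFrame):
        self._trees: dict[str, IntervalTree] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            tree = IntervalTree()
            for idx, s, e in zip(sub.index, sub["start"], sub["end"]):
                if e > s:
                    tree.addi(int(s), int(e), idx)
            self._trees[chrom] = tree

    def query(self, chrom: str, start: int, end: int) -> list:
        """Row indices of intervals overlapping ``[start, end)``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]

    def any_within(self, chrom: str, start: int, end: int, distance: int) -> bool:
        """True if any indexed interval lies within ``distance`` bp of the
        query span (gap <= distance; overlap counts)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        # gap <= distance: an interval ending at start - distance (half-open)
        # or starting at end + distance still qualifies
        return bool(tree.overlap(start - distance - 1, end + distance + 1))


def merge_sorted_intervals(
    starts: np.ndarray, ends: np.ndarray, gap: int
) -> np.ndarray:
    """Assign cluster labels to position-sorted intervals on one chromosome.

    Two consecutive intervals join one cluster when the gap between the
    running cluster end and the next start is <= ``gap`` (the semantics of
    ``bedtools merge -d``: a gap of exactly ``gap`` bp merges, ``gap + 1``
    does not).
    """
    n = len(starts)
    labels = np.zeros(n, dtype=int)
    if n == 0:
        return labels
    cluster = 0
    cur_end = ends[0]
    for i in range(1, n):
        if starts[i] - cur_end <= gap:
            cur_end = max(cur_end, ends[i])
        else:
            cluster += 1
            cur_end = ends[i]
        labels[i] = cluster
    return labels
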