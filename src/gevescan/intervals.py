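"""Contig-anchored coordinate intervals.

All coordinates inside the package are 1-based inclusive.  Conversions to
0-based half-open happen only at the BED/PAF boundary (see :mod:`gevescan.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class Interval:
    """A 1-based inclusive coordinate range on a contig."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlap_bp(self, other: "Interval") -> int:
        """Number of bases shared with ``other`` (0 if different contigs)."""
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_point(self, pos: float) -> bool:
        return self.start <= pos <= self.end

    def shift(self, offset: int) -> "Interval":
        return Interval(self.contig, self.start + offset, self.end + offset, self.strand)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.contig}:{self.start}-{self.end}({self.strand})"


def coverage_mask(intervals: Iterable[Interval], region: Interval) -> np.ndarray:
    """Boolean per-base mask over ``region`` marking bases covered by any interval."""
    mask = np.zeros(region.length, dtype=bool)
    for iv in intervals:
        if iv.contig != region.contig:
            continue
        lo = max(iv.start, region.start) - region.start
        hi = min(iv.end, region.end) - region.start + 1
        if hi > lo:
            mask[lo:hi] = True
    return mask


def union_length(intervals: Sequence[Interval], region: Interval) -> int:
    """Total bases of ``region`` covered by the union of ``intervals``."""
    return int(coverage_mask(intervals, region).sum())


def complement_intervals(
    intervals: Sequence[Interval], region: Interval, min_len: int = 1
) -> list[Interval]:
    """Maximal sub-intervals of ``region`` not covered by any interval.

    Results are sorted by start; stretches shorter than ``min_len`` are dropped.
    """
    mask = coverage_mask(intervals, region)
    out: list[Interval] = []
    free = ~mask
    # run-length scan over the complement mask
    idx = np.flatnonzero(np.diff(np.concatenate(([False], free, [False])).astype(np.int8)))
    for lo, hi in zip(idx[::2], idx[1::2]):
        if hi - lo >= min_len:
            out.append(Interval(region.contig, region.start + int(lo), region.start + int(hi) - 1))
    return out
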