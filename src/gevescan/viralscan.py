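"""Windowed viral-score track, viral region calling and composition summaries.

Per-ORF raw score is the difference between the best viral and best cellular
HMM bitscore.  Scores are smoothed with a centered rolling window measured in
ORFs (window truncated at contig ends), and maximal runs of ORFs whose rolling
score exceeds a threshold are reported as viral region calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .intervals import Interval


@dataclass
class ScoreTrack:
    """Per-ORF raw and rolling viral scores for one contig, sorted by start."""

    contig: str
    intervals: list[Interval]  # sorted by start
    raw_scores: np.ndarray
    rolling_scores: np.ndarray
    window_w: int

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.raw_scores) or len(self.raw_scores) != len(
            self.rolling_scores
        ):
            raise ValueError("track arrays must have equal lengths")


@dataclass(frozen=True)
class ViralRegionCall:
    interval: Interval
    n_orfs: int
    mean_rolling_score: float
    markers: dict = field(default_factory=dict)  # label -> count
    gc: Optional[float] = None
    coding_density: Optional[float] = None


def orf_raw_score(
    viral_bitscore: Optional[float], cellular_bitscore: Optional[float]
) -> float:
    """(best viral bitscore or 0) - (best cellular bitscore or 0)."""
    for score in (viral_bitscore, cellular_bitscore):
        if score is not None and score < 0:
            raise ValueError("bitscores must be >= 0")
    return (viral_bitscore or 0.0) - (cellular_bitscore or 0.0)


def rolling_window_scores(raw_scores: Sequence[float], w: int = 150) -> np.ndarray:
    """Centered rolling mean over windows of up to ``w`` ORFs.

    The window for ORF ``i`` spans ``[i - (w-1)//2, i + w//2]`` clipped to the
    track ends, so every ORF receives a score (no NA padding) and the output
    length equals the input length.
    """
    if w < 1:
        raise ValueError("window must be >= 1")
    raw = np.asarray(raw_scores, dtype=float)
    n = raw.size
    if n == 0:
        return np.empty(0)
    half_left = (w - 1) // 2
    half_right = w // 2
    csum = np.concatenate(([0.0], np.cumsum(raw)))
    idx = np.arange(n)
    lo = np.maximum(idx - half_left, 0)
    hi = np.minimum(idx + half_right, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def build_track(
    contig: str,
    orf_intervals: Sequence[Interval],
    viral_bitscores: Sequence[Optional[float]],
    cellular_bitscores: Sequence[Optional[float]],
    w: int = 150,
) -> ScoreTrack:
    """Assemble a ScoreTrack from per-ORF bitscores, sorting ORFs by start."""
    order = sorted(
        range(len(orf_intervals)), key=lambda i: (orf_intervals[i].start, orf_intervals[i].end)
    )
    intervals = [orf_intervals[i] for i in order]
    raw = np.array(
        [orf_raw_score(viral_bitscores[i], cellular_bitscores[i]) for i in order]
    )
    return ScoreTrack(contig, intervals, raw, rolling_window_scores(raw, w), w)


def call_viral_regions(
    track: ScoreTrack, threshold: float = 0.0, min_orfs: int = 1
) -> list[ViralRegionCall]:
    """Maximal runs of consecutive ORFs with rolling score strictly above threshold."""
    above = track.rolling_scores > threshold
    calls: list[ViralRegionCall] = []
    i = 0
    n = above.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        if j - i + 1 >= min_orfs:
            start = track.intervals[i].start
            end = max(iv.end for iv in track.intervals[i : j + 1])
            calls.append(
                ViralRegionCall(
                    interval=Interval(track.contig, start, end),
                    n_orfs=j - i + 1,
                    mean_rolling_score=float(track.rolling_scores[i : j + 1].mean()),
                )
            )
        i = j + 1
    return calls


def _gc_counts(sequence: str) -> tuple[int, int]:
    """(G+C count, unambiguous base count)."""
    gc = sequence.count("G") + sequence.count("C") + sequence.count("g") + sequence.count("c")
    at = sequence.count("A") + sequence.count("T") + sequence.count("a") + sequence.count("t")
    return gc, gc + at


def gc_profile(sequence: str, window: int = 50_000) -> np.ndarray:
    """GC fraction per non-overlapping window tiled from position 1.

    N bases are excluded from the denominator; a window with no unambiguous
    base yields NaN.  The final partial window is included.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(sequence)
    n_win = math.ceil(n / window) if n else 0
    out = np.empty(n_win)
    for i in range(n_win):
        gc, acgt = _gc_counts(sequence[i * window : (i + 1) * window])
        out[i] = gc / acgt if acgt else np.nan
    return out


def gc_fraction(sequence: str) -> float:
    gc, acgt = _gc_counts(sequence)
    return gc / acgt if acgt else float("nan")


def region_gc_contrast(sequence: str, region: Interval) -> tuple[float, float]:
    """GC fraction inside ``region`` and in the rest of the contig.

    The complement GC is NaN when the region spans the whole contig.
    """
    if region.end > len(sequence):
        raise ValueError(
            f"region {region} exceeds contig length {len(sequence)}"
        )
    inside = sequence[region.start - 1 : region.end]
    outside = sequence[: region.start - 1] + sequence[region.end :]
    return gc_fraction(inside), gc_fraction(outside) if outside else float("nan")


def tally_markers(
    markers: Sequence[tuple[Interval, str]], region: Interval
) -> dict[str, int]:
    """Counts of markers whose interval midpoint lies inside ``region``."""
    tally: dict[str, int] = {}
    for iv, label in markers:
        if iv.contig == region.contig and region.contains_point(iv.midpoint):
            tally[label] = tally.get(label, 0) + 1
    return tally
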