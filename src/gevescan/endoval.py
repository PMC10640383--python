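"""Validation that a called viral region is a chromosomal insertion.

Junction-spanning long reads, coverage uniformity, Hi-C contact enrichment
and cross-strain presence/absence by translated k-mer comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .intervals import Interval


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-genome alignment; read/target coordinates are 0-based half-open."""

    read_id: str
    read_length: int
    read_start: int
    read_end: int
    strand: str
    target_contig: str
    target_start: int
    target_end: int
    mapq: int = 60

    def __post_init__(self) -> None:
        if not (0 <= self.read_start < self.read_end <= self.read_length):
            raise ValueError(f"bad read coordinates for {self.read_id}")
        if not (0 <= self.target_start < self.target_end):
            raise ValueError(f"bad target coordinates for {self.read_id}")


@dataclass(frozen=True)
class JunctionEvidence:
    read_id: str
    boundary: str  # "left" | "right"
    viral_bp: int
    host_bp: int


@dataclass
class ContactMatrix:
    """Pre-normalized symmetric Hi-C contact matrix for one contig."""

    values: np.ndarray
    resolution: int
    contig: str = "chr"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.resolution < 1:
            raise ValueError("resolution must be positive")
        if not np.allclose(v, v.T, rtol=1e-6, atol=1e-6):
            raise ValueError("contact matrix must be symmetric")
        if (v < 0).any():
            raise ValueError("contact values must be non-negative")
        self.values = v


def detect_junction_reads(
    alignments: Sequence[AlignmentRecord],
    region: Interval,
    min_anchor: int = 1000,
    contig_length: Optional[int] = None,
) -> list[JunctionEvidence]:
    """Reads whose single alignment spans a region boundary with both anchors.

    A read witnesses the left (right) boundary iff one alignment covers at
    least ``min_anchor`` bp strictly inside the region and at least
    ``min_anchor`` bp strictly outside it, across that boundary.  A read may
    witness both boundaries.  Output is sorted by read id then boundary.
    """
    if contig_length is not None and region.end > contig_length:
        raise ValueError(f"region {region} exceeds contig length {contig_length}")
    # 0-based half-open region span
    rs, re = region.start - 1, region.end
    evidence: list[JunctionEvidence] = []
    for aln in alignments:
        if aln.target_contig != region.contig:
            continue
        ts, te = aln.target_start, aln.target_end
        # left boundary: host bases before region start, viral bases after
        if ts < rs < te:
            host_bp = rs - ts
            viral_bp = min(te, re) - rs
            if host_bp >= min_anchor and viral_bp >= min_anchor:
                evidence.append(JunctionEvidence(aln.read_id, "left", viral_bp, host_bp))
        # right boundary: viral bases before region end, host bases after
        if ts < re < te:
            viral_bp = re - max(ts, rs)
            host_bp = te - re
            if host_bp >= min_anchor and viral_bp >= min_anchor:
                evidence.append(JunctionEvidence(aln.read_id, "right", viral_bp, host_bp))
    evidence.sort(key=lambda e: (e.read_id, e.boundary))
    return evidence


def coverage_profile(
    alignments: Sequence[AlignmentRecord],
    contig_length: int,
    bin_size: int = 1000,
    contig: Optional[str] = None,
) -> tuple[np.ndarray, float]:
    """Per-bin mean of per-base alignment depth plus the global mean depth.

    The last bin may be partial; its mean is taken over its actual width.
    Global mean = total aligned bases / contig length.
    """
    if bin_size < 1:
        raise ValueError("bin size must be >= 1")
    depth_delta = np.zeros(contig_length + 1, dtype=np.int64)
    total = 0
    for aln in alignments:
        if contig is not None and aln.target_contig != contig:
            continue
        ts = max(0, aln.target_start)
        te = min(contig_length, aln.target_end)
        if te <= ts:
            continue
        depth_delta[ts] += 1
        depth_delta[te] -= 1
        total += te - ts
    depth = np.cumsum(depth_delta[:-1])
    n_bins = math.ceil(contig_length / bin_size)
    starts = np.arange(n_bins) * bin_size
    sums = np.add.reduceat(depth, starts)
    widths = np.minimum(starts + bin_size, contig_length) - starts
    return sums / widths, total / contig_length


def coverage_contrast(
    profile: np.ndarray,
    region: Interval,
    bin_size: int = 1000,
) -> tuple[float, float, float]:
    """(region mean depth, complement mean depth, ratio), overlap-weighted.

    Bins are weighted by the number of bases they share with the region (or
    its complement).  Ratio is NaN when the complement has zero coverage.
    """
    n_bins = profile.size
    starts = np.arange(n_bins) * bin_size
    ends = starts + bin_size
    rs, re = region.start - 1, region.end
    in_bp = np.clip(np.minimum(ends, re) - np.maximum(starts, rs), 0, None)
    out_bp = (ends - starts) - in_bp
    in_w = in_bp.sum()
    out_w = out_bp.sum()
    region_mean = float((profile * in_bp).sum() / in_w) if in_w else float("nan")
    compl_mean = float((profile * out_bp).sum() / out_w) if out_w else float("nan")
    ratio = region_mean / compl_mean if compl_mean else float("nan")
    return region_mean, compl_mean, ratio


def contact_enrichment(
    matrix: ContactMatrix,
    region: Interval,
    display_threshold: float = 1.0,
) -> tuple[float, float, float, float]:
    """Within-region vs background mean contact over off-diagonal bin pairs.

    Returns (within mean, background mean, ratio, fraction of within-region
    off-diagonal pairs above ``display_threshold``).  Bins counted as inside
    must lie fully within the region.
    """
    res = matrix.resolution
    n = matrix.values.shape[0]
    bin_starts = np.arange(n) * res + 1  # 1-based
    bin_ends = bin_starts + res - 1
    inside = (bin_starts >= region.start) & (bin_ends <= region.end)
    if not inside.any():
        raise ValueError(
            f"region {region} does not cover a full {res}-bp bin"
        )
    off_diag = ~np.eye(n, dtype=bool)
    in_pairs = np.outer(inside, inside) & off_diag
    out_pairs = np.outer(~inside, ~inside) & off_diag
    within = float(matrix.values[in_pairs].mean())
    background = float(matrix.values[out_pairs].mean()) if out_pairs.any() else float("nan")
    ratio = within / background if background else float("nan")
    frac_hot = float((matrix.values[in_pairs] > display_threshold).mean())
    return within, background, ratio, frac_hot


def _six_frame_kmers(sequence: str, k: int) -> set[str]:
    """Amino-acid k-mers from all six translation frames (stops break k-mers)."""
    kmers: set[str] = set()
    seq = Seq(sequence)
    for s in (seq, seq.reverse_complement()):
        for frame in range(3):
            sub = s[frame : frame + 3 * ((len(s) - frame) // 3)]
            if len(sub) < 3 * k:
                continue
            aa = str(sub.translate())
            for chunk in aa.split("*"):
                for i in range(len(chunk) - k + 1):
                    kmers.add(chunk[i : i + k])
    return kmers


def compare_strain_chromosomes(
    seq_a: str,
    seq_b: str,
    window: int = 5000,
    kmer: int = 6,
    min_shared: int = 5,
    min_run: int = 10,
    contig_a: str = "A",
) -> tuple[np.ndarray, list[Interval]]:
    """Translated k-mer comparison of chromosome A against chromosome B.

    Each ``window``-bp tile of A is translated in six frames and counted as
    matching when it shares at least ``min_shared`` distinct amino-acid
    ``kmer``-mers with B's six-frame k-mer index.  Maximal runs of at least
    ``min_run`` consecutive non-matching windows are reported as candidate
    strain-specific insertions in A.

    Returns (per-window match flags, candidate insertion intervals of A).
    """
    if not seq_a or not seq_b:
        raise ValueError("both sequences must be non-empty")
    b_index = _six_frame_kmers(seq_b, kmer)
    n_win = math.ceil(len(seq_a) / window)
    matches = np.zeros(n_win, dtype=bool)
    for i in range(n_win):
        tile = seq_a[i * window : (i + 1) * window]
        shared = 0
        for km in _six_frame_kmers(tile, kmer):
            if km in b_index:
                shared += 1
                if shared >= min_shared:
                    break
        matches[i] = shared >= min_shared
    candidates: list[Interval] = []
    i = 0
    while i < n_win:
        if matches[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_win and not matches[j + 1]:
            j += 1
        if j - i + 1 >= min_run:
            start = i * window + 1
            end = min((j + 1) * window, len(seq_a))
            candidates.append(Interval(contig_a, start, end))
        i = j + 1
    return matches, candidates
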