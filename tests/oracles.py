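"""Independent brute-force oracles used to cross-check the package.

Every function here is deliberately naive (per-base masks, O(n*w) window
means, quadratic DP) and shares no code with the implementation it checks.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def orf_scan_oracle(sequence: str, min_aa: int = 50):
    """Six-frame STOP-to-STOP stretches via Biopython translation.

    Returns a set of (start, end, strand, frame) tuples, 1-based inclusive,
    stop codons excluded.  Codons with N never translate to '*' here because
    Biopython yields 'X' for ambiguous codons.
    """
    out = set()
    n = len(sequence)
    for strand in ("+", "-"):
        s = sequence if strand == "+" else str(Seq(sequence).reverse_complement())
        for frame in range(3):
            sub = s[frame : frame + 3 * ((n - frame) // 3)]
            aa = str(Seq(sub).translate())
            start_codon = 0
            for i, ch in enumerate(aa + "*"):
                if ch == "*":
                    length = i - start_codon
                    if length >= min_aa:
                        lo = frame + 3 * start_codon + 1
                        hi = frame + 3 * i
                        if strand == "-":
                            lo, hi = n - hi + 1, n - lo + 1
                        out.add((lo, hi, strand, frame))
                    start_codon = i + 1
    return out


def prune_oracle(candidates, primary, max_overlap_frac=0.5):
    """All-pairs overlap check; returns indices of retained candidates."""
    kept = []
    for i, c in enumerate(candidates):
        clen = c.interval.end - c.interval.start + 1
        drop = False
        for p in primary:
            if c.interval.contig != p.interval.contig:
                continue
            ov = max(
                0,
                min(c.interval.end, p.interval.end)
                - max(c.interval.start, p.interval.start)
                + 1,
            )
            if ov / clen > max_overlap_frac:
                drop = True
                break
        if not drop:
            kept.append(i)
    return kept


def base_mask(intervals, region_start, region_end):
    """Per-base boolean mask of region coverage from (start, end) pairs."""
    mask = np.zeros(region_end - region_start + 1, dtype=bool)
    for s, e in intervals:
        lo = max(s, region_start) - region_start
        hi = min(e, region_end) - region_start + 1
        if hi > lo:
            mask[lo:hi] = True
    return mask


def rolling_mean_oracle(values, w):
    """O(n*w) centered truncated-window mean."""
    values = list(values)
    n = len(values)
    half_left = (w - 1) // 2
    half_right = w // 2
    out = []
    for i in range(n):
        lo = max(0, i - half_left)
        hi = min(n - 1, i + half_right)
        out.append(sum(values[lo : hi + 1]) / (hi - lo + 1))
    return np.array(out)


def coverage_oracle(alignments, contig_length, bin_size):
    """Per-base pileup then per-bin mean."""
    depth = np.zeros(contig_length, dtype=int)
    for a in alignments:
        depth[max(0, a.target_start) : min(contig_length, a.target_end)] += 1
    means = []
    for start in range(0, contig_length, bin_size):
        chunk = depth[start : start + bin_size]
        means.append(chunk.mean())
    return np.array(means)


def sw_oracle(query_aa: str, subject_aa: str, open_=-11, ext=-1) -> float:
    """Textbook affine-gap local alignment; gap of length L costs open + (L-1)*ext."""
    m, n = len(query_aa), len(subject_aa)
    NEG = -(10**9)
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG, dtype=float)
    F = np.full((m + 1, n + 1), NEG, dtype=float)
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + open_, E[i][j - 1] + ext)
            F[i][j] = max(H[i - 1][j] + open_, F[i - 1][j] + ext)
            sc = BLOSUM62[query_aa[i - 1]][subject_aa[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + sc, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def contact_pair_means(values, inside):
    """Double-loop off-diagonal pair means for inside/outside bin sets."""
    n = values.shape[0]
    w_vals, b_vals = [], []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if inside[i] and inside[j]:
                w_vals.append(values[i, j])
            elif not inside[i] and not inside[j]:
                b_vals.append(values[i, j])
    return float(np.mean(w_vals)), float(np.mean(b_vals))
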