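"""ORF inventory of a genomic region.

Six-frame STOP-to-STOP ORF extraction, pruning of candidates that overlap
primary (ab initio) gene calls, coding density and intergenic extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .intervals import Interval, complement_intervals, coverage_mask

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BestHit:
    """Best database hit of an ORF, in subject residue coordinates."""

    subject_id: str
    subject_start: int
    subject_end: int
    evalue: float
    taxon: str = ""  # eukaryote | prokaryote | virus | ""
    lineage: str = ""


@dataclass(frozen=True)
class OrfRecord:
    interval: Interval
    frame: int  # 0/1/2 on the ORF's own strand
    aa_length: int
    source: str = "stop2stop"  # abinitio | stop2stop | imported
    viral_bitscore: Optional[float] = None
    cellular_bitscore: Optional[float] = None
    best_hit: Optional[BestHit] = None

    def __post_init__(self) -> None:
        if self.frame not in (0, 1, 2):
            raise ValueError(f"frame must be 0/1/2, got {self.frame}")
        for score in (self.viral_bitscore, self.cellular_bitscore):
            if score is not None and score < 0:
                raise ValueError("bitscores must be >= 0")

    def with_hit(self, hit: BestHit) -> "OrfRecord":
        return replace(self, best_hit=hit)


def call_stop_to_stop_orfs(
    sequence: str, contig: str = "seq", min_aa: int = 50
) -> list[OrfRecord]:
    """Maximal inter-stop codon stretches in all six frames.

    Stops are TAA/TAG/TGA read on the coding strand; codons containing an
    ambiguous base never count as stops.  Sequence ends act as boundaries.
    The returned interval excludes the flanking stop codons, so ``aa_length``
    equals the number of translatable codons.  Stretches shorter than
    ``min_aa`` residues are discarded.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if n == 0:
        return []
    out: list[OrfRecord] = []
    for strand in ("+", "-"):
        seq = sequence if strand == "+" else revcomp(sequence)
        for frame in range(3):
            n_codons = (n - frame) // 3
            start_codon = 0
            for ci in range(n_codons + 1):
                is_stop = (
                    ci < n_codons
                    and seq[frame + 3 * ci : frame + 3 * ci + 3] in STOP_CODONS
                )
                if is_stop or ci == n_codons:
                    aa = ci - start_codon
                    if aa >= min_aa:
                        # stretch coordinates on the reading strand (1-based)
                        s = frame + 3 * start_codon + 1
                        e = frame + 3 * ci
                        if strand == "-":
                            s, e = n - e + 1, n - s + 1
                        out.append(
                            OrfRecord(
                                interval=Interval(contig, s, e, strand),
                                frame=frame,
                                aa_length=aa,
                                source="stop2stop",
                            )
                        )
                    start_codon = ci + 1
    out.sort(key=lambda r: (r.interval.start, r.interval.end, r.interval.strand, r.frame))
    return out


def prune_overlapping_orfs(
    candidates: Sequence[OrfRecord],
    primary: Sequence[OrfRecord],
    max_overlap_frac: float = 0.5,
) -> list[OrfRecord]:
    """Drop candidates overlapping any primary call by more than ``max_overlap_frac``.

    Overlap is measured in nucleotides against the candidate's own length and
    is strand-agnostic.  A candidate exactly at the threshold is retained.
    """
    if not primary:
        return list(candidates)
    # interval scheduling: primaries sorted by start for a linear sweep
    prim = sorted(primary, key=lambda r: r.interval.start)
    prim_starts = np.array([p.interval.start for p in prim])
    retained: list[OrfRecord] = []
    for cand in candidates:
        civ = cand.interval
        removed = False
        # only primaries starting before the candidate ends can overlap
        hi = int(np.searchsorted(prim_starts, civ.end, side="right"))
        for p in prim[:hi]:
            ov = civ.overlap_bp(p.interval)
            if ov / civ.length > max_overlap_frac:
                removed = True
                break
        if not removed:
            retained.append(cand)
    return retained


def coding_density(orfs: Sequence[OrfRecord], region: Interval) -> float:
    """Fraction of ``region`` covered by the union of ORF intervals."""
    if not orfs:
        return 0.0
    mask = coverage_mask([o.interval for o in orfs], region)
    return float(mask.sum()) / region.length


def extract_intergenic(
    orfs: Sequence[OrfRecord], region: Interval, min_len: int = 100
) -> list[Interval]:
    """Maximal ORF-free sub-intervals of ``region`` with length >= ``min_len``."""
    return complement_intervals([o.interval for o in orfs], region, min_len=min_len)
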