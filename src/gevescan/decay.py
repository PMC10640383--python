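"""Gene-decay annotation inside a viral region.

Clusters fragmented ORFs that share a homology subject into pseudogene /
intron candidates, scans intergenic regions for gene traces with a translated
local-alignment search, and summarizes repeat density and best-hit taxonomy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

import biotite.sequence as _bseq
import biotite.sequence.align as _balign

from .intervals import Interval, coverage_mask
from .orfs import STOP_CODONS, BestHit, OrfRecord, revcomp

TAXA = ("eukaryote", "prokaryote", "virus")

# Karlin-Altschul parameters for gapped BLOSUM62 (gap open 11 / extend 1).
KA_LAMBDA = 0.267
KA_K = 0.041

_BLOSUM62 = _balign.SubstitutionMatrix.std_protein_matrix()
_GAP_PENALTY = (-11, -1)


# ---------------------------------------------------------------------------
# Pseudogene / intron clustering
# ---------------------------------------------------------------------------

@dataclass
class PseudogeneCluster:
    """Consecutive same-strand ORFs sharing one homology subject."""

    members: list[OrfRecord]
    subject_id: str
    classification: str = ""  # intron_candidate | pseudogene
    disruptions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a cluster needs at least two member ORFs")
        strands = {m.interval.strand for m in self.members}
        if len(strands) != 1:
            raise ValueError("cluster members must share a strand")
        starts = [m.interval.start for m in self.members]
        if starts != sorted(starts):
            raise ValueError("cluster members must be sorted by start")

    @property
    def strand(self) -> str:
        return self.members[0].interval.strand

    @property
    def span(self) -> Interval:
        return Interval(
            self.members[0].interval.contig,
            self.members[0].interval.start,
            self.members[-1].interval.end,
            self.strand,
        )


def _collinear(prev: OrfRecord, nxt: OrfRecord, strand: str) -> bool:
    """Subject coverage of consecutive members must advance, not nest."""
    a, b = prev.best_hit, nxt.best_hit
    if strand == "-":
        a, b = b, a  # translation order is descending genomic coordinate
    return b.subject_start > a.subject_start and b.subject_end > a.subject_end


def cluster_fragmented_orfs(
    orfs: Sequence[OrfRecord], max_gap: int = 5000
) -> list[PseudogeneCluster]:
    """Merge neighboring same-strand ORFs with the same best-hit subject.

    ORFs must be sorted by start.  Consecutive ORFs are merged when their
    inter-ORF gap is at most ``max_gap`` bp and their subject coverage is
    collinear (non-nested, advancing in translation order).  Singletons are
    not clusters.
    """
    starts = [o.interval.start for o in orfs]
    if starts != sorted(starts):
        raise ValueError("ORFs must be sorted by start")
    clusters: list[PseudogeneCluster] = []
    current: list[OrfRecord] = []
    for orf in orfs:
        if orf.best_hit is None:
            if len(current) >= 2:
                clusters.append(PseudogeneCluster(current, current[0].best_hit.subject_id))
            current = []
            continue
        if current:
            prev = current[-1]
            gap = orf.interval.start - prev.interval.end - 1
            if (
                orf.interval.strand == prev.interval.strand
                and orf.best_hit.subject_id == prev.best_hit.subject_id
                and orf.interval.contig == prev.interval.contig
                and 0 <= gap <= max_gap
                and _collinear(prev, orf, prev.interval.strand)
            ):
                current.append(orf)
                continue
            if len(current) >= 2:
                clusters.append(PseudogeneCluster(current, current[0].best_hit.subject_id))
        current = [orf]
    if len(current) >= 2:
        clusters.append(PseudogeneCluster(current, current[0].best_hit.subject_id))
    return clusters


def _genomic_frame(orf: OrfRecord, contig_length: int) -> int:
    """Absolute codon phase of the ORF start on its strand."""
    if orf.interval.strand == "-":
        return (contig_length - orf.interval.end) % 3
    return (orf.interval.start - 1) % 3


def classify_cluster(
    cluster: PseudogeneCluster,
    sequence: str,
    max_coverage_gap: int = 10,
) -> PseudogeneCluster:
    """Classify a cluster as intron candidate or pseudogene and list disruptions.

    A cluster is an intron candidate iff every inter-member gap begins with GT
    and ends with AG on the coding strand AND the subject coverage of adjacent
    members is contiguous (overlap or gap of at most ``max_coverage_gap``
    residues).  Otherwise it is a pseudogene; each junction is labeled
    frameshift (members in different genomic frames), stop_gain (same frame
    with an in-frame stop in the gap) or gap.
    """
    members = cluster.members
    n = len(sequence)
    splice_ok = True
    contiguous = True
    disruptions: list[str] = []
    # walk junctions in translation order
    order = members if cluster.strand != "-" else list(reversed(members))
    for prev, nxt in zip(order[:-1], order[1:]):
        lo = min(prev.interval.end, nxt.interval.end)
        hi = max(prev.interval.start, nxt.interval.start)
        gap_seq = sequence[lo : hi - 1]  # bases strictly between the two ORFs
        if cluster.strand == "-":
            gap_seq = revcomp(gap_seq)
        if not (len(gap_seq) >= 4 and gap_seq.startswith("GT") and gap_seq.endswith("AG")):
            splice_ok = False
        cov_step = nxt.best_hit.subject_start - prev.best_hit.subject_end - 1
        if abs(cov_step) > max_coverage_gap:
            contiguous = False
        # disruption typing
        if _genomic_frame(prev, n) != _genomic_frame(nxt, n):
            disruptions.append("frameshift")
        else:
            in_frame_stop = any(
                gap_seq[i : i + 3] in STOP_CODONS
                for i in range(0, len(gap_seq) - 2, 3)
            )
            disruptions.append("stop_gain" if in_frame_stop else "gap")
    if splice_ok and contiguous:
        cluster.classification = "intron_candidate"
        cluster.disruptions = []
    else:
        cluster.classification = "pseudogene"
        cluster.disruptions = disruptions
    return cluster


# ---------------------------------------------------------------------------
# Translated homology search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranslatedHit:
    query_id: str
    subject_id: str
    subject_start: int  # 1-based residues
    subject_end: int
    score: float
    evalue: float
    frame: int  # 1..3 forward, -1..-3 reverse


def _frames(seq: str) -> list[tuple[int, str]]:
    """Six-frame translations; stops become X so local alignment can bridge them."""
    out = []
    s = Seq(seq.upper())
    for sign, strand_seq in ((1, s), (-1, s.reverse_complement())):
        for f in range(3):
            sub = strand_seq[f : f + 3 * ((len(strand_seq) - f) // 3)]
            if len(sub) >= 3:
                out.append((sign * (f + 1), str(sub.translate()).replace("*", "X")))
    return out


def evalue_from_score(score: float, query_aa: int, db_residues: int) -> float:
    """Karlin-Altschul E-value with database-size correction."""
    return KA_K * query_aa * db_residues * math.exp(-KA_LAMBDA * score)


def align_protein_local(query_aa: str, subject_aa: str) -> tuple[float, int, int]:
    """Best local alignment score of two protein strings plus subject span.

    Returns (score, subject_start, subject_end) with 1-based residue
    coordinates; score 0 means no positive-scoring alignment.
    """
    q = _bseq.ProteinSequence(query_aa)
    t = _bseq.ProteinSequence(subject_aa)
    alns = _balign.align_optimal(
        q, t, _BLOSUM62, gap_penalty=_GAP_PENALTY, local=True, max_number=1
    )
    if not alns or alns[0].score <= 0:
        return 0.0, 0, 0
    trace = alns[0].trace
    t_pos = trace[:, 1]
    t_pos = t_pos[t_pos >= 0]
    return float(alns[0].score), int(t_pos.min()) + 1, int(t_pos.max()) + 1


def translated_search(
    queries: Sequence[tuple[str, str]],
    database: Sequence[tuple[str, str]],
    e_threshold: float = 1e-5,
) -> dict[str, TranslatedHit]:
    """Best hit per nucleotide query against a protein database.

    Each query is translated in six frames and aligned locally (affine gaps,
    BLOSUM62) against every database protein; the best raw score is converted
    to an E-value with database-size correction.  Only hits with
    E < ``e_threshold`` are reported.  Queries shorter than one codon are
    skipped with a warning.
    """
    if not database:
        raise ValueError("protein database must be non-empty")
    db_residues = sum(len(p) for _, p in database)
    hits: dict[str, TranslatedHit] = {}
    for qid, qseq in queries:
        if len(qseq) < 3:
            warnings.warn(f"query {qid} shorter than one codon; skipped")
            continue
        best: Optional[TranslatedHit] = None
        for frame, aa in _frames(qseq):
            for sid, prot in database:
                score, s_start, s_end = align_protein_local(aa, prot)
                if score <= 0:
                    continue
                ev = evalue_from_score(score, len(aa), db_residues)
                if best is None or score > best.score:
                    best = TranslatedHit(qid, sid, s_start, s_end, score, ev, frame)
        if best is not None and best.evalue < e_threshold:
            hits[qid] = best
    return hits


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceSummary:
    n_queries: int
    n_db1: int
    pct_db1: float
    n_db2: int
    pct_db2: float
    n_both: int


def summarize_gene_traces(
    query_ids: Sequence[str],
    hits_db1: Sequence[str],
    hits_db2: Sequence[str],
) -> TraceSummary:
    """Counts and one-decimal percentages of queries hitting each database."""
    queries = set(query_ids)
    h1 = set(hits_db1) & queries
    h2 = set(hits_db2) & queries
    n = len(queries)
    pct = lambda k: round(100.0 * k / n, 1) if n else 0.0
    return TraceSummary(n, len(h1), pct(len(h1)), len(h2), pct(len(h2)), len(h1 & h2))


@dataclass(frozen=True)
class RepeatDensity:
    total_fraction: float
    coding_fraction: float  # repeat bases inside the ORF-union mask / |region|
    noncoding_fraction: float
    te_fraction: float


def repeat_density(
    annotation: Sequence[tuple[Interval, str]],
    region: Interval,
    orfs: Sequence[OrfRecord],
) -> RepeatDensity:
    """Repeat coverage of ``region`` split by the coding (ORF-union) mask.

    ``annotation`` carries (interval, class) pairs where class is ``repeat``
    or ``TE:<family>``; TE intervals count both as repeats and toward the
    TE-only fraction.  coding + non-coding components sum to the total.
    """
    rep_mask = coverage_mask([iv for iv, _ in annotation], region)
    te_mask = coverage_mask(
        [iv for iv, cls in annotation if cls.startswith("TE")], region
    )
    orf_mask = coverage_mask([o.interval for o in orfs], region)
    L = region.length
    total = rep_mask.sum() / L
    coding = (rep_mask & orf_mask).sum() / L
    return RepeatDensity(
        total_fraction=float(total),
        coding_fraction=float(coding),
        noncoding_fraction=float(total - coding),
        te_fraction=float(te_mask.sum() / L),
    )


def taxonomy_breakdown(
    hits: Sequence[BestHit],
) -> tuple[dict[str, int], dict[str, int]]:
    """Counts per coarse taxon and per lineage string.

    Unknown taxon labels are counted under ``unclassified`` with a warning.
    """
    coarse = {t: 0 for t in TAXA}
    lineages: dict[str, int] = {}
    for hit in hits:
        if hit.taxon in coarse:
            coarse[hit.taxon] += 1
        else:
            warnings.warn(f"unknown taxon label {hit.taxon!r}; counted as unclassified")
            coarse["unclassified"] = coarse.get("unclassified", 0) + 1
        if hit.lineage:
            lineages[hit.lineage] = lineages.get(hit.lineage, 0) + 1
    return coarse, lineages
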