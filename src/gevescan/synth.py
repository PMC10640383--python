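"""Synthetic endogenization generator.

Builds a low-GC host chromosome carrying a single contiguous higher-GC viral
insert with decayed genes, simulates long reads with known alignments and
per-ORF viral/cellular bitscores, and records full ground truth so every
downstream stage can be tested without external data.

Sequence backgrounds are i.i.d. bases with P(G)=P(C)=gc/2 and
P(A)=P(T)=(1-gc)/2, realized with exact base counts so composition targets
are met at any length.  Decay events are applied per gene in a fixed order
(deletions, frameshifts, stop gains, introns) for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .endoval import AlignmentRecord
from .intervals import Interval
from .orfs import BestHit, OrfRecord, revcomp

MARKER_LABELS = (
    "PolB", "RNAPL", "RNAPS", "mRNAc", "VLTF3", "MCP", "A32", "D5", "RNR", "SFII",
)

_STOPS = ("TAA", "TAG", "TGA")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# codon positions this close to a gene end are protected from decay so that
# every fragment stays long enough to be recovered as an ORF
_EDGE_PROTECT = 10


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HostModel:
    length: int = 5_000_000
    gc: float = 0.28
    repeat_fraction: float = 0.5
    repeat_unit_length: int = 200

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("host length must be positive")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0,1]")
        if not 0.0 <= self.repeat_fraction < 1.0:
            raise ValueError("repeat_fraction must be in [0,1)")


@dataclass(frozen=True)
class InsertModel:
    length: int = 1_500_000
    gc: float = 0.37
    n_genes: int = 500
    gene_length_mean: int = 1080
    coding_target: float = 0.36
    marker_names: frozenset = frozenset({"PolB", "RNAPL", "RNAPS", "mRNAc", "VLTF3"})

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if not 0.0 < self.coding_target <= 1.0:
            raise ValueError("coding_target must be in (0,1]")
        unknown = set(self.marker_names) - set(MARKER_LABELS)
        if unknown:
            raise ValueError(f"unknown marker labels: {sorted(unknown)}")


@dataclass(frozen=True)
class DecayModel:
    stop_gain_rate: float = 0.0002  # per codon
    frameshift_rate: float = 0.03  # per gene
    deletion_rate: float = 0.02  # per gene
    intron_rate: float = 0.04  # per gene
    intron_length_range: tuple[int, int] = (60, 180)

    def __post_init__(self) -> None:
        for r in (self.stop_gain_rate, self.frameshift_rate, self.deletion_rate, self.intron_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("decay rates must be in [0,1]")
        if self.intron_length_range[0] < 4:
            raise ValueError("introns must be at least 4 bp (GT..AG)")

    @classmethod
    def none(cls) -> "DecayModel":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ReadSimModel:
    depth: float = 20.0
    read_length_mean: int = 15_000
    read_length_sd: int = 6_000
    error_rate: float = 0.0
    reverse_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.read_length_mean <= 0:
            raise ValueError("depth and read_length_mean must be positive")
        if not 0.0 <= self.error_rate <= 0.3:
            raise ValueError("error_rate must be in [0,0.3]")


@dataclass(frozen=True)
class ScoreModel:
    viral_mean: float = 80.0
    cellular_mean: float = 240.0
    sd: float = 20.0
    baseline: float = 5.0  # mean of the "wrong database" score

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")


# ---------------------------------------------------------------------------
# Truth records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFragment:
    """One recoverable ORF piece of a (possibly decayed) gene."""

    start: int  # 1-based within the containing coordinate system
    end: int
    subject_start: int  # covered residues of the ancestral protein
    subject_end: int


@dataclass
class GeneModel:
    interval: Interval
    status: str  # intact | pseudogene | intron_bearing
    marker: Optional[str]
    protein_length: int  # ancestral residue count
    fragments: list[GeneFragment]


@dataclass(frozen=True)
class DecayEvent:
    gene_index: int
    kind: str  # stop_gain | frameshift | deletion | intron
    position: int  # codon index within the gene at time of application


@dataclass
class SyntheticTruth:
    insert_interval: Interval
    gene_models: list[GeneModel]
    decay_events: list[DecayEvent]
    read_alignments: list[AlignmentRecord] = field(default_factory=list)
    orf_scores: Optional[pd.DataFrame] = None


# ---------------------------------------------------------------------------
# Sequence primitives
# ---------------------------------------------------------------------------

def _rng(seed: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _random_array(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    """Random base array (uint8 ASCII) with an exact G+C count."""
    n_gc = round(length * gc)
    n_g = n_gc // 2
    n_c = n_gc - n_g
    n_at = length - n_gc
    n_a = n_at // 2
    n_t = n_at - n_a
    arr = np.concatenate(
        [
            np.full(n_g, ord("G"), np.uint8),
            np.full(n_c, ord("C"), np.uint8),
            np.full(n_a, ord("A"), np.uint8),
            np.full(n_t, ord("T"), np.uint8),
        ]
    )
    rng.shuffle(arr)
    return arr


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _stop_free_codons(rng: np.random.Generator, n_codons: int, gc: float) -> np.ndarray:
    """(n_codons, 3) uint8 array of codons with no TAA/TAG/TGA."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    codons = _BASES[rng.choice(4, size=(n_codons, 3), p=p)]
    stops = np.array([np.frombuffer(s.encode(), dtype=np.uint8) for s in _STOPS])
    while True:
        is_stop = (codons[:, None, :] == stops[None, :, :]).all(axis=2).any(axis=1)
        if not is_stop.any():
            return codons
        codons[is_stop] = _BASES[rng.choice(4, size=(int(is_stop.sum()), 3), p=p)]


# ---------------------------------------------------------------------------
# Host chromosome
# ---------------------------------------------------------------------------

def generate_host_sequence(
    model: HostModel, seed: int, contig: str = "chr1"
) -> tuple[str, list[Interval]]:
    """Host chromosome with tandem-repeat blocks covering ``repeat_fraction``.

    Returns the sequence and the non-overlapping repeat block intervals
    (1-based inclusive), sorted by start.  Deterministic per seed.
    """
    rng = _rng(seed, 0)
    arr = _random_array(rng, model.length, model.gc)
    repeats: list[Interval] = []
    target = model.repeat_fraction * model.length
    if target > 0:
        unit_len = model.repeat_unit_length
        copies: list[int] = []
        covered = 0
        while covered < target:
            c = int(rng.integers(2, 11))
            copies.append(c)
            covered += c * unit_len
        block_lens = [c * unit_len for c in copies]
        total_gap = model.length - sum(block_lens)
        while total_gap < len(copies) + 1 and copies:
            total_gap += block_lens.pop()
            copies.pop()
        gaps = rng.multinomial(total_gap - (len(copies) + 1), np.full(len(copies) + 1, 1.0 / (len(copies) + 1))) + 1
        pos = 0
        for c, blen, gap in zip(copies, block_lens, gaps):
            pos += int(gap)
            unit = _random_array(rng, unit_len, model.gc)
            arr[pos : pos + blen] = np.tile(unit, c)
            repeats.append(Interval(contig, pos + 1, pos + blen))
            pos += blen
    return _to_str(arr), repeats


# ---------------------------------------------------------------------------
# Viral insert with decayed genes
# ---------------------------------------------------------------------------

def _decay_gene(
    rng: np.random.Generator,
    codons: np.ndarray,
    decay: DecayModel,
    gc: float,
) -> tuple[str, list[GeneFragment], list[tuple[str, int]], str]:
    """Apply decay to one gene and derive its recoverable ORF fragments.

    Returns (final gene sequence in translation orientation, fragments with
    local 1-based coordinates and ancestral residue coverage, events as
    (kind, codon position), status).
    """
    aa = len(codons)
    codon_list = [bytes(c).decode() for c in codons]
    anc = list(range(1, aa + 1))
    events: list[tuple[str, int]] = []

    lo, hi = _EDGE_PROTECT, aa - _EDGE_PROTECT  # decay-eligible codon slice

    # 1. deletion: drop an in-frame run of codons (ORF continuity preserved)
    if decay.deletion_rate > 0 and rng.random() < decay.deletion_rate and hi - lo > 12:
        k = int(rng.integers(3, max(4, min(30, (hi - lo) // 3)) + 1))
        pos = int(rng.integers(lo, hi - k))
        del codon_list[pos : pos + k]
        del anc[pos : pos + k]
        events.append(("deletion", pos))
        aa = len(codon_list)
        lo, hi = _EDGE_PROTECT, aa - _EDGE_PROTECT

    is_stop = [False] * aa
    fs_after = [False] * aa  # 1-bp insertion after codon i
    intron_after: dict[int, str] = {}

    # 2. frameshift: insert one base after a codon boundary
    if decay.frameshift_rate > 0 and rng.random() < decay.frameshift_rate and hi > lo:
        pos = int(rng.integers(lo, hi))
        fs_after[pos] = True
        events.append(("frameshift", pos))

    # 3. stop gains, binomial per eligible codon
    if decay.stop_gain_rate > 0 and hi > lo:
        hits = np.flatnonzero(rng.random(hi - lo) < decay.stop_gain_rate) + lo
        for pos in hits:
            codon_list[pos] = _STOPS[int(rng.integers(3))]
            is_stop[pos] = True
            events.append(("stop_gain", int(pos)))

    # 4. intron insertion: GT..AG between two codons
    if decay.intron_rate > 0 and rng.random() < decay.intron_rate and hi > lo:
        pos = int(rng.integers(lo, hi))
        ilen = int(rng.integers(decay.intron_length_range[0], decay.intron_length_range[1] + 1))
        body = _to_str(_random_array(rng, ilen - 4, gc)) if ilen > 4 else ""
        intron_after[pos] = "GT" + body + "AG"
        events.append(("intron", pos))

    disrupted = any(k in ("stop_gain", "frameshift") for k, _ in events)
    has_intron = any(k == "intron" for k, _ in events)
    status = "pseudogene" if disrupted else ("intron_bearing" if has_intron else "intact")

    # linearize and split into fragments
    parts: list[str] = []
    fragments: list[GeneFragment] = []
    pos_bp = 0
    frag_start: Optional[int] = None
    frag_anc: list[int] = []

    def close() -> None:
        nonlocal frag_start, frag_anc
        if frag_start is not None and frag_anc:
            fragments.append(
                GeneFragment(frag_start + 1, pos_bp, min(frag_anc), max(frag_anc))
            )
        frag_start, frag_anc = None, []

    for i, codon in enumerate(codon_list):
        if is_stop[i]:
            close()
            parts.append(codon)
            pos_bp += 3
        else:
            if frag_start is None:
                frag_start = pos_bp
            parts.append(codon)
            pos_bp += 3
            frag_anc.append(anc[i])
        if fs_after[i]:
            close()
            base = "ACGT"[int(rng.integers(4))]
            parts.append(base)
            pos_bp += 1
        if i in intron_after:
            close()
            parts.append(intron_after[i])
            pos_bp += len(intron_after[i])
    close()
    # fragments shorter than 5 codons cannot be recovered as ORFs
    fragments = [f for f in fragments if f.end - f.start + 1 >= 15]
    return "".join(parts), fragments, events, status


def generate_viral_insert(
    model: InsertModel,
    decay: DecayModel,
    seed: int,
    contig: str = "chr1",
) -> tuple[str, list[GeneModel], list[DecayEvent]]:
    """Viral insert sequence with non-overlapping decayed genes and truth.

    Gene coordinates in the returned models are local to the insert
    (1-based).  The realized GC of the insert is tuned to ``model.gc``
    exactly by flipping intergenic bases.
    """
    rng = _rng(seed, 1)
    mean_codons = max(60, round(model.gene_length_mean / 3))
    gene_seqs: list[str] = []
    gene_meta: list[tuple[list[GeneFragment], list[tuple[str, int]], str, str, int]] = []
    events_all: list[DecayEvent] = []
    for gi in range(model.n_genes):
        n_codons = max(50, int(round(rng.normal(mean_codons, 0.2 * mean_codons))))
        codons = _stop_free_codons(rng, n_codons, model.gc)
        strand = "+" if rng.random() < 0.5 else "-"
        seq, fragments, events, status = _decay_gene(rng, codons, decay, model.gc)
        gene_seqs.append(seq)
        gene_meta.append((fragments, events, status, strand, n_codons))
        for kind, pos in events:
            events_all.append(DecayEvent(gi, kind, pos))

    total_genes = sum(len(s) for s in gene_seqs)
    n_gaps = model.n_genes + 1
    total_spacer = model.length - total_genes
    if total_spacer < n_gaps:
        raise ValueError(
            f"cannot place {model.n_genes} genes totalling {total_genes} bp "
            f"in a {model.length}-bp insert"
        )
    gaps = rng.multinomial(total_spacer - n_gaps, np.full(n_gaps, 1.0 / n_gaps)) + 1

    # marker assignment: spread the requested markers over distinct genes
    markers = sorted(model.marker_names, key=MARKER_LABELS.index)
    marker_at: dict[int, str] = {}
    if markers and model.n_genes:
        step = max(1, model.n_genes // (len(markers) + 1))
        for k, label in enumerate(markers):
            marker_at[min((k + 1) * step, model.n_genes - 1)] = label

    arr = np.empty(model.length, dtype=np.uint8)
    spacer_mask = np.zeros(model.length, dtype=bool)
    genes: list[GeneModel] = []
    pos = 0
    for gi, (seq, (fragments, events, status, strand, n_codons)) in enumerate(
        zip(gene_seqs, gene_meta)
    ):
        gap = int(gaps[gi])
        arr[pos : pos + gap] = _random_array(rng, gap, model.gc)
        spacer_mask[pos : pos + gap] = True
        pos += gap
        placed = seq if strand == "+" else revcomp(seq)
        arr[pos : pos + len(seq)] = np.frombuffer(placed.encode(), dtype=np.uint8)
        g_start, g_end = pos + 1, pos + len(seq)
        placed_frags = []
        for f in fragments:
            if strand == "+":
                s, e = g_start + f.start - 1, g_start + f.end - 1
            else:
                s, e = g_end - f.end + 1, g_end - f.start + 1
            placed_frags.append(GeneFragment(s, e, f.subject_start, f.subject_end))
        placed_frags.sort(key=lambda f: f.start)
        genes.append(
            GeneModel(
                interval=Interval(contig, g_start, g_end, strand),
                status=status,
                marker=marker_at.get(gi),
                protein_length=n_codons,
                fragments=placed_frags,
            )
        )
        pos += len(seq)
    arr[pos:] = _random_array(rng, model.length - pos, model.gc)
    spacer_mask[pos:] = True

    # exact GC tuning via intergenic flips
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    deficit = round(model.gc * model.length) - int(is_gc.sum())
    if deficit != 0:
        if deficit > 0:
            candidates = np.flatnonzero(spacer_mask & ~is_gc)
            new = (ord("G"), ord("C"))
        else:
            candidates = np.flatnonzero(spacer_mask & is_gc)
            new = (ord("A"), ord("T"))
        k = min(abs(deficit), candidates.size)
        chosen = rng.choice(candidates, size=k, replace=False)
        arr[chosen] = np.where(rng.random(k) < 0.5, new[0], new[1])
    return _to_str(arr), genes, events_all


# ---------------------------------------------------------------------------
# Assembly, reads, scores
# ---------------------------------------------------------------------------

def assemble_genome(
    host_sequence: str,
    insert_sequence: str,
    insertion_point: int,
    contig: str = "chr1",
) -> tuple[str, Interval]:
    """Insert the viral sequence after ``insertion_point`` host bases.

    Returns the combined sequence and the 1-based inclusive insert interval.
    """
    if not 0 <= insertion_point <= len(host_sequence):
        raise ValueError(
            f"insertion point {insertion_point} outside host [0,{len(host_sequence)}]"
        )
    genome = (
        host_sequence[:insertion_point] + insert_sequence + host_sequence[insertion_point:]
    )
    interval = Interval(contig, insertion_point + 1, insertion_point + len(insert_sequence))
    return genome, interval


def simulate_long_reads(
    genome: str,
    model: ReadSimModel,
    contig: str = "chr1",
) -> tuple[list[tuple[str, str]], list[AlignmentRecord]]:
    """Sample long reads with known alignments.

    Read starts are uniform over the genome; lengths are normal (clipped) and
    truncated at the genome end, so total bases / genome length approximates
    ``model.depth``.  Substitution errors are injected at ``error_rate``.
    """
    if not genome:
        raise ValueError("genome must be non-empty")
    rng = _rng(model.seed, 2)
    L = len(genome)
    arr = np.frombuffer(genome.encode(), dtype=np.uint8)
    n_reads = max(1, round(model.depth * L / model.read_length_mean))
    starts = rng.integers(0, L, size=n_reads)
    lengths = np.clip(
        rng.normal(model.read_length_mean, model.read_length_sd, size=n_reads),
        200,
        None,
    ).astype(np.int64)
    reads: list[tuple[str, str]] = []
    alignments: list[AlignmentRecord] = []
    for i in range(n_reads):
        ts = int(starts[i])
        te = min(L, ts + int(lengths[i]))
        seq_arr = arr[ts:te].copy()
        rlen = te - ts
        if model.error_rate > 0:
            k = rng.binomial(rlen, model.error_rate)
            if k:
                pos = rng.choice(rlen, size=k, replace=False)
                shift = rng.integers(1, 4, size=k)
                idx = (np.searchsorted(_BASES, seq_arr[pos]) + shift) % 4
                seq_arr[pos] = _BASES[idx]
        strand = "-" if rng.random() < model.reverse_fraction else "+"
        seq = _to_str(seq_arr) if strand == "+" else revcomp(_to_str(seq_arr))
        rid = f"read{i:06d}"
        reads.append((rid, seq))
        alignments.append(
            AlignmentRecord(
                read_id=rid,
                read_length=rlen,
                read_start=0,
                read_end=rlen,
                strand=strand,
                target_contig=contig,
                target_start=ts,
                target_end=te,
            )
        )
    return reads, alignments


def simulate_orf_scores(
    truth: SyntheticTruth,
    genome_length: int,
    host_orfs: int,
    score_model: ScoreModel,
    seed: int,
    contig: str = "chr1",
    host_orf_length: int = 900,
) -> pd.DataFrame:
    """Per-ORF viral/cellular bitscore table for insert genes and host ORFs.

    Insert-gene ORFs draw viral bitscores around ``viral_mean`` and low
    cellular scores; host ORFs draw the reverse.  The table is keyed by ORF
    interval and sorted by start.  Deterministic per seed.
    """
    rng = _rng(seed, 3)
    ins = truth.insert_interval
    rows = []
    for gene in truth.gene_models:
        v = max(0.0, rng.normal(score_model.viral_mean, score_model.sd))
        c = max(0.0, rng.normal(score_model.baseline, score_model.sd / 4))
        rows.append((contig, gene.interval.start, gene.interval.end, gene.interval.strand, v, c))
    host_space = genome_length - ins.length
    if host_orfs > 0 and host_space > host_orf_length:
        starts = np.sort(rng.integers(1, host_space - host_orf_length, size=host_orfs))
        for s in starts:
            s = int(s)
            if s >= ins.start:  # map around the insert
                s += ins.length
            v = max(0.0, rng.normal(score_model.baseline, score_model.sd / 4))
            c = max(0.0, rng.normal(score_model.cellular_mean, score_model.sd))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((contig, s, s + host_orf_length - 1, strand, v, c))
    df = pd.DataFrame(
        rows,
        columns=["contig", "start", "end", "strand", "viral_bitscore", "cellular_bitscore"],
    )
    df["viral_bitscore"] = df["viral_bitscore"].round(3)
    df["cellular_bitscore"] = df["cellular_bitscore"].round(3)
    return df.sort_values(["start", "end"], kind="mergesort", ignore_index=True)


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    contig: str
    genome: str
    host_sequence: str
    truth: SyntheticTruth
    repeats: list[tuple[Interval, str]]
    reads: list[tuple[str, str]]
    markers: list[tuple[Interval, str]]
    scores: pd.DataFrame


def simulate_endogenization(
    host: HostModel = HostModel(),
    insert: InsertModel = InsertModel(),
    decay: DecayModel = DecayModel(),
    read_model: Optional[ReadSimModel] = ReadSimModel(),
    score_model: ScoreModel = ScoreModel(),
    seed: int = 0,
    host_orfs: Optional[int] = None,
    insertion_point: Optional[int] = None,
    contig: str = "chr1",
) -> SimulationResult:
    """Full scenario: host + single insert + reads + scores + ground truth."""
    rng = _rng(seed, 4)
    host_seq, host_repeats = generate_host_sequence(host, seed, contig)
    insert_seq, genes, events = generate_viral_insert(insert, decay, seed, contig)
    if insertion_point is None:
        insertion_point = int(rng.integers(round(0.2 * host.length), round(0.8 * host.length)))
    genome, insert_interval = assemble_genome(host_seq, insert_seq, insertion_point, contig)

    shifted_genes: list[GeneModel] = []
    for g in genes:
        shifted_genes.append(
            GeneModel(
                interval=g.interval.shift(insertion_point),
                status=g.status,
                marker=g.marker,
                protein_length=g.protein_length,
                fragments=[
                    GeneFragment(
                        f.start + insertion_point,
                        f.end + insertion_point,
                        f.subject_start,
                        f.subject_end,
                    )
                    for f in g.fragments
                ],
            )
        )
    repeats: list[tuple[Interval, str]] = []
    for i, iv in enumerate(host_repeats):
        if iv.end <= insertion_point:
            shifted = iv
        elif iv.start > insertion_point:
            shifted = iv.shift(insert_interval.length)
        else:  # repeat straddling the insertion point is split by the insert
            shifted = Interval(contig, iv.start, insertion_point)
        cls = "TE:LTR" if i % 5 == 0 else "repeat"
        repeats.append((shifted, cls))

    truth = SyntheticTruth(
        insert_interval=insert_interval,
        gene_models=shifted_genes,
        decay_events=events,
    )
    reads: list[tuple[str, str]] = []
    if read_model is not None:
        rm = ReadSimModel(
            depth=read_model.depth,
            read_length_mean=read_model.read_length_mean,
            read_length_sd=read_model.read_length_sd,
            error_rate=read_model.error_rate,
            reverse_fraction=read_model.reverse_fraction,
            seed=seed if read_model.seed == 0 else read_model.seed,
        )
        reads, alignments = simulate_long_reads(genome, rm, contig)
        truth.read_alignments = alignments
    if host_orfs is None:
        host_orfs = max(1, round((host.length / insert.length) * insert.n_genes))
    truth.orf_scores = simulate_orf_scores(
        truth, len(genome), host_orfs, score_model, seed, contig
    )
    markers = [(g.interval, g.marker) for g in shifted_genes if g.marker]
    return SimulationResult(
        contig=contig,
        genome=genome,
        host_sequence=host_seq,
        truth=truth,
        repeats=repeats,
        reads=reads,
        markers=markers,
        scores=truth.orf_scores,
    )


def truth_orf_records(
    truth: SyntheticTruth, genome_length: int, min_aa: int = 5
) -> list[OrfRecord]:
    """ORF records (with best hits) re-derived from the simulation truth.

    Intact genes yield one ``abinitio`` record; decayed genes yield one
    ``stop2stop`` record per recoverable fragment.  Every record carries a
    best hit to its ancestral protein, so the decay stage can be exercised
    without an external homology search.
    """
    records: list[OrfRecord] = []
    for gi, gene in enumerate(truth.gene_models):
        subject = f"prot{gi:05d}"
        strand = gene.interval.strand
        source = "abinitio" if gene.status == "intact" and len(gene.fragments) == 1 else "stop2stop"
        for frag in gene.fragments:
            aa = (frag.end - frag.start + 1) // 3
            if aa < min_aa:
                continue
            if strand == "-":
                frame = (genome_length - frag.end) % 3
            else:
                frame = (frag.start - 1) % 3
            records.append(
                OrfRecord(
                    interval=Interval(gene.interval.contig, frag.start, frag.end, strand),
                    frame=frame,
                    aa_length=aa,
                    source=source,
                    best_hit=BestHit(
                        subject_id=subject,
                        subject_start=frag.subject_start,
                        subject_end=frag.subject_end,
                        evalue=1e-30,
                        taxon="virus",
                        lineage="Nucleocytoviricota",
                    ),
                )
            )
    records.sort(key=lambda r: (r.interval.start, r.interval.end))
    return records
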