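"""Readers and writers for the plain-text formats used by the pipeline.

Internal coordinates are 1-based inclusive; BED and PAF use their native
0-based half-open convention.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .endoval import AlignmentRecord, ContactMatrix
from .intervals import Interval
from .orfs import BestHit, OrfRecord

SCORE_COLUMNS = ["contig", "start", "end", "strand", "viral_bitscore", "cellular_bitscore"]


# -- FASTA ------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path: str, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        path,
        "fasta",
    )


# -- BED --------------------------------------------------------------------

def write_bed(path: str, rows: Iterable[tuple[Interval, str]]) -> None:
    """Intervals + name column, converted to 0-based half-open."""
    with open(path, "w") as fh:
        for iv, name in rows:
            fh.write(f"{iv.contig}\t{iv.start - 1}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed(path: str) -> list[tuple[Interval, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            out.append((Interval(contig, start + 1, end, strand), name))
    return out


# -- GFF3 -------------------------------------------------------------------

def _gff_attrs(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items()) or "."


def write_gff3(
    path: str,
    rows: Sequence[tuple[Interval, str, str, dict]],
) -> None:
    """Rows are (interval, source, feature_type, attributes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv, source, ftype, attrs in rows:
            fh.write(
                f"{iv.contig}\t{source}\t{ftype}\t{iv.start}\t{iv.end}\t.\t"
                f"{iv.strand if iv.strand != '.' else '.'}\t.\t{_gff_attrs(attrs)}\n"
            )


def read_gff3(path: str) -> list[tuple[Interval, str, str, dict]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 line")
            contig, source, ftype, start, end, _, strand, _, attr_str = parts[:9]
            attrs = {}
            for item in attr_str.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k] = v
            strand = strand if strand in "+-" else "."
            out.append((Interval(contig, int(start), int(end), strand), source, ftype, attrs))
    return out


def write_orfs_gff3(path: str, orfs: Sequence[OrfRecord]) -> None:
    rows = []
    for i, orf in enumerate(orfs):
        attrs = {
            "ID": f"orf{i:06d}",
            "frame": str(orf.frame),
            "aa_length": str(orf.aa_length),
        }
        if orf.viral_bitscore is not None:
            attrs["viral_bitscore"] = f"{orf.viral_bitscore:g}"
        if orf.cellular_bitscore is not None:
            attrs["cellular_bitscore"] = f"{orf.cellular_bitscore:g}"
        if orf.best_hit is not None:
            h = orf.best_hit
            attrs["subject"] = h.subject_id
            attrs["subject_range"] = f"{h.subject_start}-{h.subject_end}"
            attrs["evalue"] = f"{h.evalue:g}"
            if h.taxon:
                attrs["taxon"] = h.taxon
            if h.lineage:
                attrs["lineage"] = h.lineage
        rows.append((orf.interval, orf.source, "ORF", attrs))
    write_gff3(path, rows)


def read_orfs_gff3(path: str) -> list[OrfRecord]:
    orfs = []
    for iv, source, _ftype, attrs in read_gff3(path):
        hit = None
        if "subject" in attrs:
            s, e = attrs.get("subject_range", "0-0").split("-")
            hit = BestHit(
                subject_id=attrs["subject"],
                subject_start=int(s),
                subject_end=int(e),
                evalue=float(attrs.get("evalue", "1")),
                taxon=attrs.get("taxon", ""),
                lineage=attrs.get("lineage", ""),
            )
        vb = attrs.get("viral_bitscore")
        cb = attrs.get("cellular_bitscore")
        orfs.append(
            OrfRecord(
                interval=iv,
                frame=int(attrs.get("frame", "0")),
                aa_length=int(attrs.get("aa_length", str(iv.length // 3))),
                source=source,
                viral_bitscore=float(vb) if vb is not None else None,
                cellular_bitscore=float(cb) if cb is not None else None,
                best_hit=hit,
            )
        )
    return orfs


# -- PAF --------------------------------------------------------------------

def write_paf(path: str, alignments: Sequence[AlignmentRecord], target_length: int) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            n = a.target_end - a.target_start
            fh.write(
                f"{a.read_id}\t{a.read_length}\t{a.read_start}\t{a.read_end}\t"
                f"{a.strand}\t{a.target_contig}\t{target_length}\t"
                f"{a.target_start}\t{a.target_end}\t{n}\t{n}\t{a.mapq}\n"
            )


def read_paf(path: str) -> list[AlignmentRecord]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) < 12:
                raise ValueError(f"{path}:{lineno}: PAF needs >= 12 columns")
            out.append(
                AlignmentRecord(
                    read_id=p[0],
                    read_length=int(p[1]),
                    read_start=int(p[2]),
                    read_end=int(p[3]),
                    strand=p[4],
                    target_contig=p[5],
                    target_start=int(p[7]),
                    target_end=int(p[8]),
                    mapq=int(p[11]),
                )
            )
    return out


# -- score / marker tables --------------------------------------------------

def write_scores_tsv(path: str, scores: pd.DataFrame) -> None:
    scores.to_csv(path, sep="\t", index=False, columns=SCORE_COLUMNS)


def read_scores_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing score columns {sorted(missing)}")
    return df


def write_markers_tsv(path: str, markers: Sequence[tuple[Interval, str]]) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tstrand\tmarker\n")
        for iv, label in markers:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.strand}\t{label}\n")


def read_markers_tsv(path: str) -> list[tuple[Interval, str]]:
    df = pd.read_csv(path, sep="\t")
    return [
        (Interval(r.contig, int(r.start), int(r.end), str(r.strand)), str(r.marker))
        for r in df.itertuples()
    ]


# -- contact matrix ---------------------------------------------------------

def write_contact_matrix(path: str, matrix: ContactMatrix) -> None:
    with open(path, "w") as fh:
        fh.write(f"# resolution={matrix.resolution}\tcontig={matrix.contig}\n")
        np.savetxt(fh, matrix.values, delimiter="\t", fmt="%.6g")


def read_contact_matrix(path: str) -> ContactMatrix:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '# resolution=...' header")
        fields = dict(
            item.split("=", 1) for item in header.lstrip("#").split() if "=" in item
        )
        values = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return ContactMatrix(values, int(fields["resolution"]), fields.get("contig", "chr"))
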