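"""Pipeline orchestration: simulate -> scan -> validate -> decay -> report.

Every stage reads and writes plain files under the run directory so stages
are independently testable and resumable; rerunning with the same config
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__, decay as decay_mod, endoval, io as gio, orfs as orfs_mod, synth, viralscan
from .intervals import Interval


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "run"
    contig: str = "chr1"
    # synth
    host_length: int = 5_000_000
    host_gc: float = 0.28
    host_repeat_fraction: float = 0.5
    insert_length: int = 1_500_000
    insert_gc: float = 0.37
    insert_genes: int = 500
    gene_length_mean: int = 1080
    depth: float = 20.0
    read_length_mean: int = 15_000
    read_length_sd: int = 6_000
    error_rate: float = 0.0
    stop_gain_rate: float = 0.0002
    frameshift_rate: float = 0.03
    deletion_rate: float = 0.02
    intron_rate: float = 0.04
    # scan
    window_orfs: int = 150
    score_threshold: float = 0.0
    min_orfs: int = 1
    gc_window: int = 50_000
    # orfs
    min_aa: int = 50
    min_intergenic: int = 100
    max_overlap_frac: float = 0.5
    # validate
    min_anchor: int = 1000
    coverage_bin: int = 1000
    contact_matrix: str = ""  # optional dense TSV path
    # decay
    max_gap: int = 5000
    e_threshold: float = 1e-5

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, value = (x.strip() for x in line.split("=", 1))
                if key not in types:
                    raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
                t = types[key]
                if t in ("int", int):
                    kwargs[key] = int(value)
                elif t in ("float", float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)

    # model builders ---------------------------------------------------------
    def host_model(self) -> synth.HostModel:
        return synth.HostModel(self.host_length, self.host_gc, self.host_repeat_fraction)

    def insert_model(self) -> synth.InsertModel:
        return synth.InsertModel(
            self.insert_length, self.insert_gc, self.insert_genes, self.gene_length_mean
        )

    def decay_model(self) -> synth.DecayModel:
        return synth.DecayModel(
            self.stop_gain_rate, self.frameshift_rate, self.deletion_rate, self.intron_rate
        )

    def read_model(self) -> synth.ReadSimModel:
        return synth.ReadSimModel(
            self.depth, self.read_length_mean, self.read_length_sd, self.error_rate
        )


def format_region_length_kb(interval: Interval) -> str:
    """Region length in kb: floor of inclusive bp span / 1000, thousands-separated."""
    return f"{interval.length // 1000:,}"


def _path(config: RunConfig, name: str) -> str:
    return os.path.join(config.outdir, name)


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig) -> None:
    os.makedirs(config.outdir, exist_ok=True)
    result = synth.simulate_endogenization(
        host=config.host_model(),
        insert=config.insert_model(),
        decay=config.decay_model(),
        read_model=config.read_model(),
        seed=config.seed,
        contig=config.contig,
    )
    gio.write_fasta(_path(config, "genome.fasta"), [(result.contig, result.genome)])
    gio.write_fasta(_path(config, "reads.fasta"), result.reads)
    gio.write_paf(_path(config, "alignments.paf"), result.truth.read_alignments, len(result.genome))
    gio.write_scores_tsv(_path(config, "scores.tsv"), result.scores)
    gio.write_markers_tsv(_path(config, "markers.tsv"), result.markers)
    gio.write_bed(_path(config, "insert.bed"), [(result.truth.insert_interval, "insert")])
    gio.write_bed(_path(config, "repeats.bed"), result.repeats)
    gio.write_gff3(
        _path(config, "truth.gff3"),
        [
            (
                g.interval,
                "synth",
                "gene",
                {"ID": f"gene{i:05d}", "status": g.status, **({"marker": g.marker} if g.marker else {})},
            )
            for i, g in enumerate(result.truth.gene_models)
        ],
    )
    gio.write_orfs_gff3(
        _path(config, "orfs.gff3"),
        synth.truth_orf_records(result.truth, len(result.genome)),
    )


def stage_scan(config: RunConfig) -> list[viralscan.ViralRegionCall]:
    genome = gio.read_fasta(_path(config, "genome.fasta"))
    scores = gio.read_scores_tsv(_path(config, "scores.tsv"))
    markers_path = _path(config, "markers.tsv")
    markers = gio.read_markers_tsv(markers_path) if os.path.exists(markers_path) else []
    orf_path = _path(config, "orfs.gff3")
    orf_records = gio.read_orfs_gff3(orf_path) if os.path.exists(orf_path) else []

    all_calls: list[viralscan.ViralRegionCall] = []
    bed_rows = []
    tsv_rows = []
    for contig, seq in genome.items():
        sub = scores[scores["contig"] == contig]
        if sub.empty:
            continue
        intervals = [
            Interval(contig, int(r.start), int(r.end), str(r.strand)) for r in sub.itertuples()
        ]
        track = viralscan.build_track(
            contig,
            intervals,
            sub["viral_bitscore"].tolist(),
            sub["cellular_bitscore"].tolist(),
            w=config.window_orfs,
        )
        calls = viralscan.call_viral_regions(track, config.score_threshold, config.min_orfs)
        for call in calls:
            gc_in, gc_out = viralscan.region_gc_contrast(seq, call.interval)
            tally = viralscan.tally_markers(markers, call.interval)
            cds = orfs_mod.coding_density(
                [o for o in orf_records if o.interval.contig == contig], call.interval
            )
            enriched = viralscan.ViralRegionCall(
                call.interval, call.n_orfs, call.mean_rolling_score, tally, gc_in, cds
            )
            all_calls.append(enriched)
            bed_rows.append((call.interval, f"region{len(all_calls):03d}"))
            tsv_rows.append(
                {
                    "contig": contig,
                    "start": call.interval.start,
                    "end": call.interval.end,
                    "length_kb": format_region_length_kb(call.interval),
                    "n_orfs": call.n_orfs,
                    "mean_rolling_score": round(call.mean_rolling_score, 3),
                    "gc_region": round(gc_in, 4),
                    "gc_complement": round(gc_out, 4) if gc_out == gc_out else "NA",
                    "coding_density": round(cds, 4),
                    "markers": ",".join(f"{k}:{v}" for k, v in sorted(tally.items())) or ".",
                }
            )
        # GC profile track
        prof = viralscan.gc_profile(seq, config.gc_window)
        with open(_path(config, f"gc_profile.{contig}.tsv"), "w") as fh:
            fh.write("window_start\tgc\n")
            for i, g in enumerate(prof):
                fh.write(f"{i * config.gc_window + 1}\t{'NA' if g != g else round(float(g), 5)}\n")
    gio.write_bed(_path(config, "regions.bed"), bed_rows)
    pd.DataFrame(
        tsv_rows,
        columns=[
            "contig", "start", "end", "length_kb", "n_orfs", "mean_rolling_score",
            "gc_region", "gc_complement", "coding_density", "markers",
        ],
    ).to_csv(_path(config, "regions.tsv"), sep="\t", index=False)
    return all_calls


def stage_validate(config: RunConfig) -> dict:
    genome = gio.read_fasta(_path(config, "genome.fasta"))
    regions = gio.read_bed(_path(config, "regions.bed"))
    alignments = gio.read_paf(_path(config, "alignments.paf"))
    out: dict[str, dict] = {}
    junction_rows = []
    for region, name in regions:
        contig_len = len(genome[region.contig])
        evid = endoval.detect_junction_reads(
            alignments, region, config.min_anchor, contig_len
        )
        for e in evid:
            junction_rows.append(
                {"region": name, "read_id": e.read_id, "boundary": e.boundary,
                 "viral_bp": e.viral_bp, "host_bp": e.host_bp}
            )
        profile, global_mean = endoval.coverage_profile(
            alignments, contig_len, config.coverage_bin, region.contig
        )
        r_mean, c_mean, ratio = endoval.coverage_contrast(profile, region, config.coverage_bin)
        entry = {
            "junction_reads": len({(e.read_id, e.boundary) for e in evid}),
            "junction_read_ids": sorted({e.read_id for e in evid}),
            "coverage_region": round(r_mean, 3),
            "coverage_complement": round(c_mean, 3),
            "coverage_ratio": round(ratio, 4),
            "global_mean_depth": round(global_mean, 3),
        }
        if config.contact_matrix:
            matrix = gio.read_contact_matrix(config.contact_matrix)
            within, background, cratio, frac_hot = endoval.contact_enrichment(matrix, region)
            entry.update(
                contact_within=round(within, 4),
                contact_background=round(background, 4),
                contact_ratio=round(cratio, 4),
                contact_frac_hot=round(frac_hot, 4),
            )
        out[name] = entry
        # coverage track for the region's contig
        with open(_path(config, f"coverage.{region.contig}.tsv"), "w") as fh:
            fh.write("bin_start\tmean_depth\n")
            for i, d in enumerate(profile):
                fh.write(f"{i * config.coverage_bin + 1}\t{round(float(d), 4)}\n")
    pd.DataFrame(
        junction_rows, columns=["region", "read_id", "boundary", "viral_bp", "host_bp"]
    ).to_csv(_path(config, "junctions.tsv"), sep="\t", index=False)
    with open(_path(config, "validate.json"), "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out


def stage_decay(config: RunConfig) -> dict:
    genome = gio.read_fasta(_path(config, "genome.fasta"))
    regions = gio.read_bed(_path(config, "regions.bed"))
    orf_records = gio.read_orfs_gff3(_path(config, "orfs.gff3"))
    repeats_path = _path(config, "repeats.bed")
    repeats = gio.read_bed(repeats_path) if os.path.exists(repeats_path) else []
    out: dict[str, dict] = {}
    cluster_rows = []
    for region, name in regions:
        seq = genome[region.contig]
        in_region = [
            o for o in orf_records
            if o.interval.contig == region.contig and region.contains(o.interval)
        ]
        clusters = decay_mod.cluster_fragmented_orfs(in_region, config.max_gap)
        n_pseudo = n_intron = 0
        for ci, cluster in enumerate(clusters):
            decay_mod.classify_cluster(cluster, seq)
            if cluster.classification == "pseudogene":
                n_pseudo += 1
            else:
                n_intron += 1
            cluster_rows.append(
                {
                    "region": name,
                    "cluster": f"cluster{ci:04d}",
                    "contig": cluster.span.contig,
                    "start": cluster.span.start,
                    "end": cluster.span.end,
                    "strand": cluster.strand,
                    "subject": cluster.subject_id,
                    "n_members": len(cluster.members),
                    "classification": cluster.classification,
                    "disruptions": ",".join(cluster.disruptions) or ".",
                }
            )
        density = decay_mod.repeat_density(repeats, region, in_region)
        coarse, _ = decay_mod.taxonomy_breakdown(
            [o.best_hit for o in in_region if o.best_hit is not None]
        )
        intergenic = orfs_mod.extract_intergenic(in_region, region, config.min_intergenic)
        out[name] = {
            "pseudogene_clusters": n_pseudo,
            "intron_candidates": n_intron,
            "n_intergenic": len(intergenic),
            "repeat_total_pct": round(100 * density.total_fraction, 2),
            "repeat_coding_pct": round(100 * density.coding_fraction, 2),
            "repeat_noncoding_pct": round(100 * density.noncoding_fraction, 2),
            "te_pct": round(100 * density.te_fraction, 2),
            "taxonomy": coarse,
        }
    pd.DataFrame(
        cluster_rows,
        columns=["region", "cluster", "contig", "start", "end", "strand", "subject",
                 "n_members", "classification", "disruptions"],
    ).to_csv(_path(config, "clusters.tsv"), sep="\t", index=False)
    with open(_path(config, "decay.json"), "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out


def stage_report(config: RunConfig) -> pd.DataFrame:
    regions = pd.read_csv(_path(config, "regions.tsv"), sep="\t", dtype={"length_kb": str})
    with open(_path(config, "validate.json")) as fh:
        validate = json.load(fh)
    with open(_path(config, "decay.json")) as fh:
        decayed = json.load(fh)
    rows = []
    for i, r in enumerate(regions.itertuples(), start=1):
        name = f"region{i:03d}"
        v = validate.get(name, {})
        d = decayed.get(name, {})
        tax = d.get("taxonomy", {})
        rows.append(
            {
                "region": name,
                "contig": r.contig,
                "start": r.start,
                "end": r.end,
                "length_kb": r.length_kb,
                "n_orfs": r.n_orfs,
                "mean_rolling_score": r.mean_rolling_score,
                "gc_region": r.gc_region,
                "gc_complement": r.gc_complement,
                "coding_pct": round(100 * r.coding_density, 2),
                "noncoding_pct": round(100 * (1 - r.coding_density), 2),
                "markers": r.markers,
                "junction_reads": v.get("junction_reads", 0),
                "coverage_ratio": v.get("coverage_ratio", "NA"),
                "pseudogene_clusters": d.get("pseudogene_clusters", 0),
                "intron_candidates": d.get("intron_candidates", 0),
                "repeat_total_pct": d.get("repeat_total_pct", 0.0),
                "repeat_coding_pct": d.get("repeat_coding_pct", 0.0),
                "repeat_noncoding_pct": d.get("repeat_noncoding_pct", 0.0),
                "te_pct": d.get("te_pct", 0.0),
                "tax_eukaryote": tax.get("eukaryote", 0),
                "tax_prokaryote": tax.get("prokaryote", 0),
                "tax_virus": tax.get("virus", 0),
            }
        )
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    report.to_csv(_path(config, "report.tsv"), sep="\t", index=False)
    with open(_path(config, "summary.txt"), "w") as fh:
        if report.empty:
            fh.write("No viral regions called.\n")
        for row in rows:
            fh.write(
                f"{row['region']}: {row['contig']}:{row['start']}-{row['end']} "
                f"({row['length_kb']} kb), {row['n_orfs']} ORFs, "
                f"GC {row['gc_region']:.4f} vs {row['gc_complement']}, "
                f"coding {row['coding_pct']:.2f}%, "
                f"{row['junction_reads']} junction reads, "
                f"{row['pseudogene_clusters']} pseudogene clusters, "
                f"{row['intron_candidates']} intron candidates\n"
            )
    return report


REPORT_COLUMNS = [
    "region", "contig", "start", "end", "length_kb", "n_orfs", "mean_rolling_score",
    "gc_region", "gc_complement", "coding_pct", "noncoding_pct", "markers",
    "junction_reads", "coverage_ratio", "pseudogene_clusters", "intron_candidates",
    "repeat_total_pct", "repeat_coding_pct", "repeat_noncoding_pct", "te_pct",
    "tax_eukaryote", "tax_prokaryote", "tax_virus",
]

_STAGES = ("simulate", "scan", "validate", "decay", "report")


def run_pipeline(config: RunConfig, stages: Optional[list[str]] = None) -> pd.DataFrame:
    """Run the requested stages (default all) in dependency order."""
    os.makedirs(config.outdir, exist_ok=True)
    stages = list(stages) if stages else list(_STAGES)
    report = pd.DataFrame(columns=REPORT_COLUMNS)
    for stage in _STAGES:
        if stage not in stages:
            continue
        try:
            if stage == "simulate":
                stage_simulate(config)
            elif stage == "scan":
                stage_scan(config)
            elif stage == "validate":
                stage_validate(config)
            elif stage == "decay":
                stage_decay(config)
            elif stage == "report":
                report = stage_report(config)
        except Exception as exc:  # noqa: BLE001 - stage failures must be named
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
    _write_log(config, stages)
    return report


def _write_log(config: RunConfig, stages: list[str]) -> None:
    lines = [f"gevescan {__version__}", f"stages: {','.join(stages)}"]
    for f in dataclasses.fields(config):
        lines.append(f"param {f.name} = {getattr(config, f.name)}")
    for name in sorted(os.listdir(config.outdir)):
        path = os.path.join(config.outdir, name)
        if name != "run.log" and os.path.isfile(path):
            lines.append(f"input {name} sha256:{_checksum(path)}")
    with open(_path(config, "run.log"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
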