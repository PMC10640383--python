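# gevescan

Detection and characterization of giant endogenous viral elements (GEVEs) on
eukaryotic chromosomes.

Given chromosome-level assemblies, per-ORF viral/cellular homology bitscores,
long-read alignments and repeat annotations, `gevescan` calls candidate viral
regions with a rolling-window score track, validates that a called region is a
bona fide chromosomal insertion (junction-spanning reads, coverage uniformity,
Hi-C contact enrichment, cross-strain presence/absence), and annotates gene
decay inside the region (pseudogene and intron-candidate clusters, intergenic
gene traces, repeat/TE density, best-hit taxonomy). A synthetic endogenization
generator produces host chromosomes with a single decayed viral insert plus
full ground truth, so the entire pipeline is testable without external data.

## Modules

| module      | role |
|-------------|------|
| `gevescan.synth`     | synthetic host + viral insert + decay + reads + ORF scores, with ground truth |
| `gevescan.orfs`      | six-frame STOP-to-STOP ORF extraction, overlap pruning, coding density, intergenic extraction |
| `gevescan.viralscan` | rolling-window viral score track, region calling, GC profiling, marker tallies |
| `gevescan.endoval`   | junction-spanning reads, coverage profiles/contrast, contact enrichment, translated k-mer strain comparison |
| `gevescan.decay`     | fragmented-ORF clustering, pseudogene/intron classification, translated homology search, repeat density, taxonomy |
| `gevescan.pipeline`  | config, stage orchestration, report writing |

Coordinates are 1-based inclusive throughout the API; BED and PAF files use
their native 0-based half-open conventions.

## CLI

```
# generate a synthetic endogenization scenario with ground truth
geve-scan simulate --host-gc 0.28 --insert-gc 0.37 --insert-length 1500000 \
    --depth 20 --seed 1 --out run/

# call viral regions from a score table
geve-scan scan --fasta run/genome.fasta --scores run/scores.tsv -w 150 -s 0 --out run/

# junction-read validation of a region against a PAF file
geve-scan validate --paf run/alignments.paf --region chr1:1370742-2921549 \
    --contig-length 6500000 --min-anchor 1000

# cross-strain comparison (candidate strain-specific insertions of A)
geve-scan compare --a strainA.fa --b strainB.fa

# full pipeline from a flat key=value config
geve-scan all --config run.cfg
```

Exit codes: 0 success, 2 config/parse error, 3 stage failure. `run.cfg` keys
mirror the fields of `gevescan.pipeline.RunConfig` (`seed`, `outdir`,
`host_length`, `insert_gc`, `window_orfs`, `min_anchor`, ...).

## Notes

- The per-ORF raw score is (best viral bitscore) − (best cellular bitscore);
  rolling windows are centered on ORF rank and truncated at contig ends, and
  regions are maximal runs with rolling score strictly above the threshold.
- The translated homology search uses exact local alignment (BLOSUM62, affine
  gaps) with Karlin–Altschul E-values; thresholds, not raw scores, are the
  contract.
- The strain comparison matches translated k-mers; `min_shared` should scale
  with the size of the reference chromosome (expected chance collisions per
  window ≈ `n_window_kmers * n_index / 20^k`).
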