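# trackrank

Rank genomic coverage tracks (ChIP-seq, CAGE, ...) by statistical
over-representation of signal in a **query** set of genomic regions versus a
**background** set.

Given a collection of per-base coverage tracks, a genome annotation and a
query given as gene symbols, Ensembl transcript IDs, RefSeq accessions, BED
or narrowPeak lines, or `chr:start-end` strings (the input dialect is
auto-detected), trackrank:

1. resolves identifiers to promoter windows around each transcription start
   site (TSS ± 1000 bp by default);
2. samples a background of 1000 random gene promoters (or accepts any
   user-supplied region set);
3. for every track, compares length-normalized, log-transformed mean
   coverages between query and background with a Welch two-sample t-test,
   Bonferroni-corrected over the tracks tested;
4. emits a ranked TSV/HTML table, per-track stack plots (sorted coverage
   distributions) and strand-aware TSS-anchored coverage profiles, plus a
   JSON manifest that makes every run reproducible.

A single-region mode scores one promoter or interval against the background
with a parametric z-score.

## Signal formats

Tracks are registered in a metadata TSV (`track_id`, `path`, `assembly`,
`category`, optional `total_tags`, `description`). Signal files may be:

- **bedGraph** text (`.bedgraph`/`.bg`) — always supported, used by the
  bundled fixture generator;
- **bigWig** (`.bw`/`.bigwig`) — supported when `pyBigWig` is installed
  (optional; not required for any test).

All backends share one contract: bases without data count as coverage 0,
reads past the recorded chromosome end are clamped while the divisor stays
the requested length, and chromosome names are aliased (`chr1` ≡ `1`).

## CLI

```sh
# generate a synthetic fixture collection with planted enrichment
trackrank simulate --out fixture --seed 7

# rank all tracks for a query of gene symbols against 1000 sampled promoters
trackrank enrich --query genes.txt \
    --tracks fixture/tracks.tsv \
    --annotation fixture/annotation.gtf --chrom-sizes fixture/chrom.sizes \
    --background sample:1000 --seed 1 --out run/ --html

# single-gene z-score inspection
trackrank inspect GENE0005 --tracks fixture/tracks.tsv \
    --annotation fixture/annotation.gtf --chrom-sizes fixture/chrom.sizes

# TSS-anchored coverage profiles / identifier resolution
trackrank profile --query genes.txt --out profiles/ --tracks fixture/tracks.tsv \
    --annotation fixture/annotation.gtf --chrom-sizes fixture/chrom.sizes
trackrank resolve --query genes.txt --out resolved.bed \
    --annotation fixture/annotation.gtf --chrom-sizes fixture/chrom.sizes
```

Exit codes: 0 success, 2 input error, 3 I/O error. `--background` takes a
file (BED/narrowPeak/identifiers) or `sample:N`; `--query` may be repeated
to profile several sets side by side (the first is tested).

## Package layout

| module | purpose |
| --- | --- |
| `trackrank.ranges` | interval model; BED / narrowPeak / coordinate parsing; input-kind auto-detection; peak filtering |
| `trackrank.annotation` | GTF indexing, identifier → promoter resolution, seeded background sampling |
| `trackrank.tracks` | track registry, signal backends, mean-coverage extraction, tags-per-million scaling |
| `trackrank.enrichment` | log transform, Welch t-test, Bonferroni, ranked enrichment, single-region z-scores |
| `trackrank.profiles` | strand-aware center-anchored profiles and stack-plot data |
| `trackrank.report` | ranked table (TSV/HTML), nearest-gene annotation, run manifest |
| `trackrank.synthetic` | deterministic fixture generator with planted, analytically checkable enrichment |
| `trackrank.cli` | `trackrank` command-line entry point |
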