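"""Synthetic genome, annotation and track-collection generator.

Produces a toy genome (evenly spaced genes on alternating strands), a GTF +
chrom.sizes annotation, and coverage tracks of baseline + half-normal noise
with optional triangular peaks planted at chosen gene TSSs.  The triangular
shape is chosen because its mean over any window has an exact closed form,
which makes the planted signal checkable against an analytic oracle.

Everything is deterministic in (config, seed): per-track noise streams are
spawned from one root SeedSequence, and files serialize the same arrays the
in-memory collection exposes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationIndex, load_annotation
from .tracks import ArraySignal, TrackCollection, TrackRecord, write_bedgraph

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "make_annotation",
    "make_annotation_index",
    "make_track_arrays",
    "make_collection",
    "write_collection",
]

GENE_BODY_LENGTH = 5000  # nominal transcript span in the toy GTF


@dataclass(frozen=True)
class SyntheticConfig:
    n_chroms: int = 1
    chrom_length: int = 1_000_000
    n_genes: int = 100
    enriched_genes: int | tuple[str, ...] = 10
    peak_amplitude: float = 3.0
    peak_halfwidth: int = 300
    noise_sd: float = 1.0
    baseline: float = 1.0
    n_tracks: int = 20
    n_enriched_tracks: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracks < 1 or self.n_chroms < 1 or self.n_genes < 1:
            raise ValueError("counts must be positive")
        if self.n_enriched_tracks > self.n_tracks:
            raise ValueError("n_enriched_tracks > n_tracks")
        if isinstance(self.enriched_genes, int) and self.enriched_genes > self.n_genes:
            raise ValueError("enriched_genes > n_genes")
        if self.peak_amplitude < 0 or self.noise_sd < 0 or self.baseline < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.peak_halfwidth < 1:
            raise ValueError("peak_halfwidth must be >= 1")


@dataclass
class SyntheticTruth:
    enriched_track_ids: list[str]
    enriched_gene_symbols: list[str]
    peak_amplitude: float
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "enriched_track_ids": self.enriched_track_ids,
                "enriched_gene_symbols": self.enriched_gene_symbols,
                "peak_amplitude": self.peak_amplitude,
                "seed": self.seed,
            },
            indent=2,
            sort_keys=True,
        )


def _gene_layout(config: SyntheticConfig) -> list[tuple[str, str, str, str, int]]:
    """(symbol, transcript_id, chrom, strand, tss) per gene, evenly spaced."""
    per_chrom = -(-config.n_genes // config.n_chroms)  # ceil division
    spacing = config.chrom_length // per_chrom
    if spacing < 2000:
        raise ValueError(
            f"genome too small: {config.n_genes} genes in {config.n_chroms} x "
            f"{config.chrom_length} bp leaves spacing {spacing} < 2000"
        )
    layout = []
    for g in range(config.n_genes):
        chrom = f"chr{g // per_chrom + 1}"
        slot = g % per_chrom
        tss = slot * spacing + spacing // 2
        strand = "+" if g % 2 == 0 else "-"
        symbol = f"GENE{g + 1:04d}"
        tid = f"ENST{g + 1:011d}"
        layout.append((symbol, tid, chrom, strand, tss))
    return layout


def make_annotation(config: SyntheticConfig, outdir) -> tuple[Path, Path]:
    """Write the toy GTF and chrom.sizes; returns their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gtf_path = outdir / "annotation.gtf"
    sizes_path = outdir / "chrom.sizes"
    layout = _gene_layout(config)
    with open(gtf_path, "w") as fh:
        fh.write("#!synthetic toy annotation\n")
        for g, (symbol, tid, chrom, strand, tss) in enumerate(layout):
            body = min(GENE_BODY_LENGTH, config.chrom_length // 10)
            if strand == "+":
                start1 = tss + 1
                end1 = min(tss + body, config.chrom_length)
            else:
                end1 = tss + 1
                start1 = max(1, tss + 1 - body + 1)
            refseq = f"NM_{g + 1:06d}"
            attrs = (
                f'gene_id "{symbol}"; gene_name "{symbol}"; '
                f'transcript_id "{tid}"; refseq_id "{refseq}";'
            )
            fh.write(
                f"{chrom}\tsynthetic\ttranscript\t{start1}\t{end1}\t.\t{strand}\t.\t{attrs}\n"
            )
    with open(sizes_path, "w") as fh:
        for c in range(config.n_chroms):
            fh.write(f"chr{c + 1}\t{config.chrom_length}\n")
    return gtf_path, sizes_path


def make_annotation_index(config: SyntheticConfig) -> AnnotationIndex:
    """In-memory equivalent of loading the files written by make_annotation."""
    from .annotation import TranscriptRecord

    layout = _gene_layout(config)
    records = [
        TranscriptRecord(
            transcript_id=tid,
            gene_symbol=symbol,
            chrom=chrom,
            strand=strand,
            tss=tss,
            refseq_ids=(f"NM_{g + 1:06d}",),
        )
        for g, (symbol, tid, chrom, strand, tss) in enumerate(layout)
    ]
    sizes = {f"chr{c + 1}": config.chrom_length for c in range(config.n_chroms)}
    return AnnotationIndex.build(records, sizes)


def _triangle(amplitude: float, halfwidth: int) -> np.ndarray:
    """Per-base triangular peak: amplitude at the apex, 0 at +/- halfwidth."""
    offsets = np.arange(-halfwidth, halfwidth + 1)
    return amplitude * (1.0 - np.abs(offsets) / halfwidth)


def make_track_arrays(
    config: SyntheticConfig,
    index: AnnotationIndex,
    enriched_symbols: Sequence[str],
    enriched: bool,
    seed,
) -> dict[str, np.ndarray]:
    """Per-chromosome signal arrays for one track.

    Signal = baseline + |N(0, noise_sd)| per base; enriched tracks add a
    triangular peak centered on each enriched gene's TSS.
    """
    rng = np.random.default_rng(seed)
    arrays: dict[str, np.ndarray] = {}
    for chrom, length in index.chrom_sizes.items():
        arr = np.full(length, config.baseline, dtype=np.float64)
        if config.noise_sd > 0:
            arr += np.abs(rng.normal(0.0, config.noise_sd, size=length))
        arrays[chrom] = arr
    if enriched and config.peak_amplitude > 0:
        peak = _triangle(config.peak_amplitude, config.peak_halfwidth)
        for symbol in enriched_symbols:
            rec = index.genes[symbol.upper()]
            arr = arrays[rec.chrom]
            lo = rec.tss - config.peak_halfwidth
            hi = rec.tss + config.peak_halfwidth + 1
            plo, phi = max(lo, 0), min(hi, arr.size)
            arr[plo:phi] += peak[plo - lo : peak.size - (hi - phi)]
    return arrays


def make_collection(
    config: SyntheticConfig,
    index: AnnotationIndex | None = None,
) -> tuple[TrackCollection, SyntheticTruth]:
    """Build an in-memory track collection with planted enrichment.

    The first ``n_enriched_tracks`` track ids (T01, T02, ...) carry peaks at
    the enriched genes' TSSs; enriched genes are either an explicit symbol
    list or ``enriched_genes`` seeded random draws.
    """
    if index is None:
        index = make_annotation_index(config)
    root = np.random.SeedSequence(config.seed)
    pick_seed, *track_seeds = root.spawn(config.n_tracks + 1)
    if isinstance(config.enriched_genes, int):
        rng = np.random.default_rng(pick_seed)
        symbols = sorted(index.genes)
        chosen = rng.choice(len(symbols), size=config.enriched_genes, replace=False)
        enriched_symbols = [index.genes[symbols[i]].gene_symbol for i in sorted(chosen)]
    else:
        enriched_symbols = list(config.enriched_genes)
    tracks: list[TrackRecord] = []
    enriched_ids: list[str] = []
    for t in range(config.n_tracks):
        track_id = f"T{t + 1:02d}"
        enriched = t < config.n_enriched_tracks
        arrays = make_track_arrays(config, index, enriched_symbols, enriched, track_seeds[t])
        if enriched:
            enriched_ids.append(track_id)
        tracks.append(
            TrackRecord(
                track_id=track_id,
                path=f"{track_id}.bedgraph",
                assembly="toy1",
                description="planted enrichment" if enriched else "null track",
                category="TF" if enriched else "other",
                total_tags=1_000_000.0,
                signal=ArraySignal(arrays, source=track_id),
            )
        )
    truth = SyntheticTruth(
        enriched_track_ids=enriched_ids,
        enriched_gene_symbols=enriched_symbols,
        peak_amplitude=config.peak_amplitude,
        seed=config.seed,
    )
    return TrackCollection(tracks=tracks, assembly="toy1"), truth


def write_collection(config: SyntheticConfig, outdir) -> tuple[Path, Path, Path, Path]:
    """Materialize the full fixture set on disk.

    Writes annotation.gtf, chrom.sizes, one bedGraph per track, the track
    metadata TSV and truth.json; returns (gtf, chrom.sizes, metadata TSV,
    truth JSON) paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gtf_path, sizes_path = make_annotation(config, outdir)
    index = load_annotation(gtf_path, sizes_path)
    collection, truth = make_collection(config, index)
    rows = []
    for track in collection:
        bg_path = outdir / f"{track.track_id}.bedgraph"
        write_bedgraph(track.signal.to_arrays(), bg_path)
        rows.append(
            {
                "track_id": track.track_id,
                "path": bg_path.name,
                "assembly": track.assembly,
                "category": track.category,
                "total_tags": track.total_tags,
                "description": track.description,
            }
        )
    meta_path = outdir / "tracks.tsv"
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)
    truth_path = outdir / "truth.json"
    truth_path.write_text(truth.to_json() + "\n")
    return gtf_path, sizes_path, meta_path, truth_path
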