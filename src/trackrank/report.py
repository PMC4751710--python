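"""Ranked enrichment table rendering: TSV, optional HTML, and the run manifest.

Column order follows the ranked-table layout: track, query coverage,
background coverage, fold difference, p-value, Bonferroni-corrected p-value,
then file-path columns for the stack/profile artifacts, the per-interval
gene detail, and the track description.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .annotation import AnnotationIndex
from .enrichment import EnrichmentResult
from .ranges import GenomicInterval, QuerySet
from .tracks import TrackCollection, coverage_matrix

__all__ = [
    "ReportRow",
    "nearest_gene",
    "build_report",
    "write_table",
    "write_manifest",
    "format_pvalue",
]

TSV_COLUMNS = [
    "track",
    "query",
    "background",
    "fold_difference",
    "p_value",
    "bonferroni",
    "stack_plot",
    "histogram",
    "genes",
    "description",
]


@dataclass
class ReportRow:
    result: EnrichmentResult
    genes: list[tuple[str, str, float]] = field(default_factory=list)  # (label, symbol, coverage)
    stack_path: str = ""
    histogram_path: str = ""


def format_pvalue(p: float) -> str:
    """Scientific with 2 significant digits below 1e-3, else 4 decimals."""
    if p < 0.001:
        return f"{p:.1e}"
    return f"{p:.4f}"


def nearest_gene(
    interval: GenomicInterval,
    index: AnnotationIndex,
    window: int = 1000,
) -> tuple[str, int]:
    """Gene (canonical transcript) whose TSS is closest to the interval center.

    Distance is |TSS - center|, reported as 0 when the center falls within
    TSS +/- window.  Ties break lexicographically on the symbol.  Returns
    ("", -1) when the chromosome carries no genes.
    """
    center = interval.center
    best: tuple[int, str] | None = None
    for symbol in sorted(index.genes):
        rec = index.genes[symbol]
        if rec.chrom != interval.chrom:
            continue
        dist = abs(rec.tss - center)
        if best is None or dist < best[0]:
            best = (dist, rec.gene_symbol)
    if best is None:
        import warnings

        warnings.warn(f"no genes on chromosome {interval.chrom!r}")
        return "", -1
    dist, symbol = best
    return symbol, 0 if dist <= window else dist


def build_report(
    results: Sequence[EnrichmentResult],
    collection: TrackCollection,
    query: QuerySet,
    index: AnnotationIndex | None = None,
    artifact_dir: Path | None = None,
) -> list[ReportRow]:
    """Assemble report rows in ranking order with per-interval gene detail."""
    rows: list[ReportRow] = []
    cov = coverage_matrix(collection, query.intervals) if len(query) else None
    track_pos = {t.track_id: i for i, t in enumerate(collection)}
    for res in results:
        genes: list[tuple[str, str, float]] = []
        t_idx = track_pos[res.track_id]
        for i_idx, iv in enumerate(query.intervals):
            symbol, _ = nearest_gene(iv, index) if index is not None else ("", -1)
            coverage = float(cov.values[t_idx, i_idx]) if cov is not None else 0.0
            genes.append((iv.label or f"{iv.chrom}:{iv.start}-{iv.end}", symbol, coverage))
        row = ReportRow(result=res, genes=genes)
        if artifact_dir is not None:
            row.stack_path = str(Path(artifact_dir) / f"{res.track_id}.stack.tsv")
            row.histogram_path = str(Path(artifact_dir) / f"{res.track_id}.profile.tsv")
        rows.append(row)
    return rows


def _genes_cell(genes: list[tuple[str, str, float]]) -> str:
    return ";".join(f"{label}|{symbol}|{coverage:.4g}" for label, symbol, coverage in genes)


def rows_to_frame(rows: Sequence[ReportRow]) -> pd.DataFrame:
    records = []
    for row in rows:
        r = row.result
        records.append(
            {
                "track": r.track_id,
                "query": f"{r.query_mean:.4g}",
                "background": f"{r.background_mean:.4g}",
                "fold_difference": f"{r.fold_difference:.4g}",
                "p_value": format_pvalue(r.p_value),
                "bonferroni": format_pvalue(r.bonferroni_p),
                "stack_plot": row.stack_path,
                "histogram": row.histogram_path,
                "genes": _genes_cell(row.genes),
                "description": r.description,
            }
        )
    return pd.DataFrame(records, columns=TSV_COLUMNS)


def write_table(rows: Sequence[ReportRow], path, html: bool = False) -> None:
    """Write the ranked table as TSV (and optionally a sibling .html)."""
    frame = rows_to_frame(rows)
    frame.to_csv(path, sep="\t", index=False)
    if html:
        _write_html(frame, Path(path).with_suffix(".html"))


_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Track enrichment report</title>
<style>
body { font-family: sans-serif; margin: 2em; }
table { border-collapse: collapse; }
th, td { border: 1px solid #999; padding: 4px 8px; font-size: 90%; }
th { background: #eee; }
</style></head>
<body>
<h1>Track enrichment report</h1>
{{ table }}
</body></html>
"""


def _write_html(frame: pd.DataFrame, path) -> None:
    from jinja2 import Template

    html_table = frame.to_html(index=False, escape=True)
    Path(path).write_text(Template(_HTML_TEMPLATE).render(table=html_table))


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, *, config: dict, seed: int | None, m: int, inputs: dict[str, str],
                   background: str) -> None:
    """JSON sidecar recording everything needed to reproduce the run."""
    manifest = {
        "config": config,
        "seed": seed,
        "n_tracks_tested": m,
        "background": background,
        "input_digests": {name: file_digest(p) for name, p in inputs.items() if p and Path(p).exists()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
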