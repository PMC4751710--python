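"""Genome annotation index: identifier -> promoter resolution and background sampling.

The index is built from a GTF (Ensembl/GENCODE dialect; ``transcript``
features with ``gene_name`` and ``transcript_id`` attributes) plus a
UCSC-style two-column chrom.sizes table.  Promoters are fixed windows around
the transcription start site (TSS), oriented in transcription direction.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ranges import GenomicInterval, InputKind, QuerySet, detect_input_kind

__all__ = [
    "TranscriptRecord",
    "AnnotationIndex",
    "load_annotation",
    "read_chrom_sizes",
    "promoters_for",
    "promoter_interval",
    "sample_background",
]

DEFAULT_UPSTREAM = 1000
DEFAULT_DOWNSTREAM = 1000

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript: its identifiers, strand and 0-based TSS position."""

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    tss: int
    refseq_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


@dataclass
class AnnotationIndex:
    transcripts: list[TranscriptRecord]
    chrom_sizes: dict[str, int]
    by_transcript: dict[str, TranscriptRecord] = field(default_factory=dict)
    by_refseq: dict[str, list[TranscriptRecord]] = field(default_factory=dict)
    by_symbol: dict[str, list[TranscriptRecord]] = field(default_factory=dict)
    genes: dict[str, TranscriptRecord] = field(default_factory=dict)

    @classmethod
    def build(
        cls, transcripts: Sequence[TranscriptRecord], chrom_sizes: Mapping[str, int]
    ) -> "AnnotationIndex":
        index = cls(transcripts=list(transcripts), chrom_sizes=dict(chrom_sizes))
        for tr in index.transcripts:
            size = index.chrom_sizes.get(tr.chrom)
            if size is not None and tr.tss >= size:
                raise ValueError(
                    f"transcript {tr.transcript_id}: tss {tr.tss} beyond {tr.chrom} length {size}"
                )
            index.by_transcript[_strip_version(tr.transcript_id)] = tr
            for acc in tr.refseq_ids:
                index.by_refseq.setdefault(_strip_version(acc), []).append(tr)
            index.by_symbol.setdefault(tr.gene_symbol.upper(), []).append(tr)
        # canonical transcript per gene: 5'-most TSS in transcription direction
        for symbol, records in index.by_symbol.items():
            plus = [r for r in records if r.strand == "+"]
            if plus:
                canon = min(plus, key=lambda r: (r.tss, r.transcript_id))
            else:
                canon = min(records, key=lambda r: (-r.tss, r.transcript_id))
            index.genes[symbol] = canon
        return index

    def lookup(self, token: str, kind: InputKind) -> list[TranscriptRecord]:
        """Resolve one identifier token to transcript records (maybe empty)."""
        key = _strip_version(token.strip())
        if kind is InputKind.ENSEMBL_TRANSCRIPT:
            rec = self.by_transcript.get(key)
            return [rec] if rec else []
        if kind is InputKind.REFSEQ:
            return list(self.by_refseq.get(key, []))
        return list(self.by_symbol.get(key.upper(), []))


def _strip_version(identifier: str) -> str:
    # ENST00000000001.2 -> ENST00000000001 ; symbols with dots are left alone
    head, dot, tail = identifier.rpartition(".")
    if dot and tail.isdigit() and (head.startswith("ENS") or head[:3] in ("NM_", "NR_", "XM_", "XR_")):
        return head
    return identifier


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2 or not fields[1].isdigit():
                raise ValueError(f"{path}: malformed chrom.sizes line {lineno}: {line!r}")
            sizes[fields[0]] = int(fields[1])
    if not sizes:
        raise ValueError(f"{path}: empty chrom.sizes file")
    return sizes


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def load_annotation(gtf_path, chrom_sizes) -> AnnotationIndex:
    """Build an :class:`AnnotationIndex` from a GTF and a chrom.sizes table.

    Only ``transcript`` features are used.  The TSS is the feature start for
    + strand transcripts and the feature end for - strand ones, both
    converted from GTF 1-based inclusive to 0-based coordinates.  Records
    lacking ``transcript_id``/``gene_name`` are skipped with a warning.
    """
    sizes = chrom_sizes if isinstance(chrom_sizes, Mapping) else read_chrom_sizes(chrom_sizes)
    transcripts: list[TranscriptRecord] = []
    n_skipped = 0
    with open(gtf_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "transcript":
                continue
            chrom, start1, end1, strand = fields[0], int(fields[3]), int(fields[4]), fields[6]
            attrs = _parse_gtf_attributes(fields[8])
            tid = attrs.get("transcript_id")
            symbol = attrs.get("gene_name") or attrs.get("gene_id")
            if not tid or not symbol or strand not in ("+", "-"):
                n_skipped += 1
                continue
            tss = start1 - 1 if strand == "+" else end1 - 1
            refseq = tuple(a for a in (attrs.get("refseq_id"),) if a)
            transcripts.append(
                TranscriptRecord(
                    transcript_id=tid,
                    gene_symbol=symbol,
                    chrom=chrom,
                    strand=strand,
                    tss=tss,
                    refseq_ids=refseq,
                )
            )
    if n_skipped:
        warnings.warn(f"{gtf_path}: skipped {n_skipped} transcript records with missing attributes")
    if not transcripts:
        raise ValueError(f"{gtf_path}: no transcripts loaded")
    return AnnotationIndex.build(transcripts, sizes)


def promoter_interval(
    record: TranscriptRecord,
    chrom_sizes: Mapping[str, int],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    label: str | None = None,
) -> GenomicInterval:
    """The window [tss - upstream, tss + downstream) in transcription direction.

    On the - strand the transcribed offsets -upstream..downstream-1 map to
    genomic positions tss+upstream..tss-downstream+1, i.e. the genomic
    interval [tss - downstream + 1, tss + upstream + 1).  Clamped to the
    chromosome bounds.
    """
    if record.strand == "+":
        start = record.tss - upstream
        end = record.tss + downstream
    else:
        start = record.tss - downstream + 1
        end = record.tss + upstream + 1
    size = chrom_sizes.get(record.chrom)
    start = max(0, start)
    if size is not None:
        end = min(end, size)
    return GenomicInterval(
        record.chrom, start, end, record.strand,
        label if label is not None else record.gene_symbol,
    )


def promoters_for(
    tokens: Sequence[str],
    index: AnnotationIndex,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    label: str = "query",
    kind: InputKind | None = None,
) -> QuerySet:
    """Resolve identifier tokens to promoter intervals.

    Unresolved tokens (unknown identifiers or minority-kind tokens from a
    mixed submission) are collected on the returned set, not fatal; zero
    resolved tokens is an error.
    """
    if upstream < 0 or downstream < 0 or upstream + downstream <= 0:
        raise ValueError("need upstream, downstream >= 0 and upstream + downstream > 0")
    if kind is None:
        kind, minority = detect_input_kind(tokens)
    else:
        minority = []
    minority_set = set(minority)
    intervals: list[GenomicInterval] = []
    unresolved: list[str] = list(minority)
    for token in tokens:
        tok = token.strip()
        if not tok or tok in minority_set:
            continue
        records = index.lookup(tok, kind)
        if not records:
            unresolved.append(tok)
            continue
        if kind is InputKind.SYMBOL:
            records = [index.genes[records[0].gene_symbol.upper()]]
        for rec in records:
            intervals.append(
                promoter_interval(rec, index.chrom_sizes, upstream, downstream, label=tok)
            )
    if not intervals:
        raise ValueError("no tokens resolved to promoters")
    if unresolved:
        warnings.warn(f"{len(unresolved)} token(s) unresolved: {unresolved[:5]}...")
    return QuerySet(label=label, intervals=intervals, unresolved=unresolved)


def sample_background(
    index: AnnotationIndex,
    n: int = 1000,
    seed: int = 0,
    exclude: QuerySet | Iterable[str] | None = None,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> QuerySet:
    """Draw ``n`` distinct gene promoters uniformly without replacement.

    One promoter per gene, via the gene's canonical transcript.  Genes whose
    symbol appears in ``exclude`` (a QuerySet's labels or an iterable of
    symbols) are never drawn.  The draw depends only on the sorted gene
    symbols and the seed, so it is invariant to GTF record order.
    """
    if exclude is None:
        excluded: set[str] = set()
    elif isinstance(exclude, QuerySet):
        excluded = {iv.label.upper() for iv in exclude.intervals}
    else:
        excluded = {str(s).upper() for s in exclude}
    eligible = sorted(s for s in index.genes if s.upper() not in excluded)
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} eligible genes for a background of {n}; use a smaller n"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n, replace=False)
    intervals = [
        promoter_interval(index.genes[eligible[i]], index.chrom_sizes, upstream, downstream)
        for i in chosen
    ]
    return QuerySet(label=f"background[n={n},seed={seed}]", intervals=intervals)
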