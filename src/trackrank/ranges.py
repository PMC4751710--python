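"""Genomic interval model and parsers for the accepted positional input dialects.

Supported inputs: BED (3-6 columns), ENCODE narrowPeak (BED6+4),
``chr:start-end`` coordinate strings (1-based inclusive, genome-browser
convention), and plain identifier lists (gene symbols, Ensembl transcript
IDs, RefSeq accessions).  The identifier kind is auto-detected per token.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "QuerySet",
    "PeakRecord",
    "InputKind",
    "ParseError",
    "parse_bed",
    "parse_coordinate",
    "parse_narrowpeak",
    "filter_peaks",
    "detect_input_kind",
    "classify_token",
    "format_coordinate",
    "write_bed6",
]

VALID_STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """Raised when an input dialect cannot be parsed."""


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware half-open range on a named chromosome.

    Coordinates follow the BED convention: ``start`` is 0-based inclusive,
    ``end`` is 0-based exclusive.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class QuerySet:
    """A named, ordered collection of intervals plus any unmapped input tokens."""

    label: str
    intervals: list[GenomicInterval]
    unresolved: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


@dataclass(frozen=True)
class PeakRecord:
    """A called peak: an interval plus its narrowPeak signal value."""

    interval: GenomicInterval
    signal_value: float
    score: int = 0

    def __post_init__(self) -> None:
        if self.signal_value < 0:
            raise ValueError("signal_value must be >= 0")


class InputKind(str, Enum):
    BED = "bed"
    NARROWPEAK = "narrowpeak"
    COORDINATE = "coordinate"
    ENSEMBL_TRANSCRIPT = "ensembl_transcript"
    REFSEQ = "refseq"
    SYMBOL = "symbol"


_COORD_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$")
_ENSEMBL_RE = re.compile(r"^ENS[A-Z]*T\d+(\.\d+)?$")
_REFSEQ_RE = re.compile(r"^(NM_|NR_|XM_|XR_)\d+(\.\d+)?$")


def _split_fields(line: str) -> list[str]:
    return line.rstrip("\n").split("\t") if "\t" in line else line.split()


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def parse_bed(lines: Iterable[str]) -> list[GenomicInterval]:
    """Parse BED lines (3-6 columns, 0-based half-open) into intervals.

    Column 4 becomes the label and column 6 the strand when present.
    Comment (``#``, ``track``, ``browser``) and blank lines are skipped.

    Raises
    ------
    ParseError
        On a malformed line (naming its line number) or if no interval
        was parsed at all.
    """
    intervals: list[GenomicInterval] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = _split_fields(line)
        if len(fields) < 3:
            raise ParseError(f"line {lineno}: expected >=3 columns, got {len(fields)}")
        chrom = fields[0]
        if not (_is_int(fields[1]) and _is_int(fields[2])):
            raise ParseError(f"line {lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}")
        start, end = int(fields[1]), int(fields[2])
        label = fields[3] if len(fields) >= 4 else ""
        strand = fields[5] if len(fields) >= 6 and fields[5] in VALID_STRANDS else "."
        try:
            intervals.append(GenomicInterval(chrom, start, end, strand, label))
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
    if not intervals:
        raise ParseError("no ranges parsed")
    return intervals


def parse_coordinate(token: str) -> GenomicInterval:
    """Parse a ``chrom:start-end`` token (1-based inclusive, commas allowed).

    The result is converted to 0-based half-open coordinates, so
    ``chr1:1000-2000`` maps to ``[999, 2000)``.
    """
    m = _COORD_RE.match(token.strip())
    if m is None:
        raise ParseError(f"malformed coordinate token {token!r}")
    start1 = int(m.group("start").replace(",", ""))
    end1 = int(m.group("end").replace(",", ""))
    if end1 < start1:
        raise ParseError(f"coordinate {token!r}: end < start")
    if start1 < 1:
        raise ParseError(f"coordinate {token!r}: positions are 1-based")
    return GenomicInterval(m.group("chrom"), start1 - 1, end1)


def format_coordinate(interval: GenomicInterval) -> str:
    """Inverse of :func:`parse_coordinate` (1-based inclusive text)."""
    return f"{interval.chrom}:{interval.start + 1}-{interval.end}"


def parse_narrowpeak(lines: Iterable[str]) -> list[PeakRecord]:
    """Parse ENCODE narrowPeak (BED6+4) lines; signal value is column 7."""
    peaks: list[PeakRecord] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = _split_fields(line)
        if len(fields) < 7:
            raise ParseError(f"line {lineno}: narrowPeak needs >=7 columns, got {len(fields)}")
        try:
            interval = GenomicInterval(
                fields[0],
                int(fields[1]),
                int(fields[2]),
                fields[5] if fields[5] in VALID_STRANDS else ".",
                fields[3],
            )
            peaks.append(
                PeakRecord(
                    interval=interval,
                    signal_value=float(fields[6]),
                    score=int(float(fields[4])),
                )
            )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
    if not peaks:
        raise ParseError("no peaks parsed")
    return peaks


def filter_peaks(
    peaks: Sequence[PeakRecord],
    min_signal: float = float("-inf"),
    top_n: int | None = None,
    bottom_n: int | None = None,
) -> list[PeakRecord]:
    """Filter peaks by signal value.

    Keeps records with ``signal_value`` strictly greater than ``min_signal``;
    ``top_n`` then keeps the strongest n (ties broken by input order), and
    ``bottom_n`` instead keeps the weakest n — used to build a low-signal
    background set from the same peak call.
    """
    if not peaks:
        raise ValueError("filter_peaks: empty peak list")
    if top_n is not None and bottom_n is not None:
        raise ValueError("top_n and bottom_n are mutually exclusive")
    kept = [p for p in peaks if p.signal_value > min_signal]
    if not kept:
        raise ValueError("no peaks survive filter")
    if top_n is not None:
        order = sorted(range(len(kept)), key=lambda i: (-kept[i].signal_value, i))
        kept = [kept[i] for i in sorted(order[:top_n])]
    elif bottom_n is not None:
        order = sorted(range(len(kept)), key=lambda i: (kept[i].signal_value, i))
        kept = [kept[i] for i in sorted(order[:bottom_n])]
    if not kept:
        raise ValueError("no peaks survive filter")
    return kept


def classify_token(token: str) -> InputKind:
    """Classify one input token/line by pattern."""
    fields = _split_fields(token)
    if len(fields) >= 7 and _is_int(fields[1]) and _is_int(fields[2]) and _is_float(fields[6]):
        return InputKind.NARROWPEAK
    if len(fields) >= 3 and _is_int(fields[1]) and _is_int(fields[2]):
        return InputKind.BED
    if len(fields) == 1:
        tok = fields[0]
        if _COORD_RE.match(tok):
            return InputKind.COORDINATE
        if _ENSEMBL_RE.match(tok):
            return InputKind.ENSEMBL_TRANSCRIPT
        if _REFSEQ_RE.match(tok):
            return InputKind.REFSEQ
    return InputKind.SYMBOL


def detect_input_kind(tokens: Sequence[str]) -> tuple[InputKind, list[str]]:
    """Detect the dominant input kind of a token list.

    Each non-empty token is classified independently; the majority kind wins
    (ties broken by first appearance) and minority tokens are returned as the
    second element so callers can report them as unresolved rather than fail
    the whole submission.
    """
    cleaned = [t for t in tokens if t.strip()]
    if not cleaned:
        raise ParseError("empty input")
    kinds = [classify_token(t) for t in cleaned]
    counts = Counter(kinds)
    best = max(counts.values())
    # first-seen among the kinds sharing the max count
    majority = next(k for k in kinds if counts[k] == best)
    minority = [t for t, k in zip(cleaned, kinds) if k is not majority]
    return majority, minority


def write_bed6(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as BED6 (score column fixed at 0) for audit."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t0\t{iv.strand}\n")
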