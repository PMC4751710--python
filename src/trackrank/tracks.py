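"""Registry of coverage tracks and the coverage-extraction primitive.

A track is a per-base, non-negative signal across a genome.  Two on-disk
backends are supported: bedGraph text (self-contained, used throughout the
test fixtures) and bigWig via ``pyBigWig`` when that library is importable.
An in-memory array backend serves simulation-heavy callers that never touch
disk.  All backends share one contract:

* bases with no record count as signal 0 (no reads means zero coverage);
* requests extending past the recorded chromosome length are clamped for
  reading, but the caller's divisor stays the full requested length;
* chromosome names are normalized through an alias layer ("chr1" == "1"),
  because files from different sources disagree on naming.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ranges import GenomicInterval

__all__ = [
    "TrackRecord",
    "TrackCollection",
    "CoverageMatrix",
    "ArraySignal",
    "BedGraphSignal",
    "open_signal",
    "load_collection",
    "mean_coverage",
    "coverage_matrix",
    "scale_to_tags_per_million",
]

CATEGORIES = ("TF", "histone", "polymerase", "CAGE", "enhancer", "insulator", "other")


def _chrom_key(name: str) -> str:
    """Canonical chromosome key: lowercase, 'chr' prefix stripped."""
    n = name.lower()
    return n[3:] if n.startswith("chr") else n


class _MissingChromWarner:
    """Warn once per (signal, chromosome) pair about absent chromosomes."""

    def __init__(self) -> None:
        self._seen: set[str] = set()

    def warn(self, chrom: str, source: str) -> None:
        if chrom not in self._seen:
            self._seen.add(chrom)
            warnings.warn(f"{source}: chromosome {chrom!r} absent; returning 0 coverage")


class ArraySignal:
    """Per-base signal held as one numpy array per chromosome."""

    def __init__(self, arrays: Mapping[str, np.ndarray], source: str = "<memory>") -> None:
        self._arrays = {_chrom_key(c): np.asarray(v, dtype=np.float64) for c, v in arrays.items()}
        self._names = {_chrom_key(c): c for c in arrays}  # original spelling, for serialization
        self.source = source
        self._warner = _MissingChromWarner()

    def to_arrays(self) -> dict[str, np.ndarray]:
        """Per-chromosome arrays under their original chromosome names."""
        return {self._names[k]: v for k, v in self._arrays.items()}

    def chrom_length(self, chrom: str) -> int | None:
        arr = self._arrays.get(_chrom_key(chrom))
        return None if arr is None else arr.size

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); zeros where no data exists."""
        if end <= start:
            raise ValueError("need start < end")
        out = np.zeros(end - start, dtype=np.float64)
        arr = self._arrays.get(_chrom_key(chrom))
        if arr is None:
            self._warner.warn(chrom, self.source)
            return out
        lo, hi = max(start, 0), min(end, arr.size)
        if lo < hi:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        arr = self._arrays.get(_chrom_key(chrom))
        if arr is None:
            self._warner.warn(chrom, self.source)
            return 0.0
        lo, hi = max(start, 0), min(end, arr.size)
        return float(arr[lo:hi].sum()) if lo < hi else 0.0


class BedGraphSignal:
    """Signal read from a bedGraph text file (chrom, start, end, value rows).

    Intervals are half-open 0-based and must be non-overlapping per
    chromosome; they are sorted at load time.  Query cost is O(log k) per
    lookup via binary search on interval starts.
    """

    def __init__(self, path, chrom_sizes: Mapping[str, int] | None = None) -> None:
        self.source = str(path)
        frame = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": np.float64},
        )
        if frame.empty:
            raise ValueError(f"{path}: empty bedGraph")
        self._per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._lengths: dict[str, int] = {}
        for chrom, grp in frame.groupby("chrom", sort=False):
            key = _chrom_key(chrom)
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if np.any(ends[:-1] > starts[1:]):
                raise ValueError(f"{path}: overlapping bedGraph records on {chrom}")
            self._per_chrom[key] = (starts, ends, grp["value"].to_numpy())
            self._lengths[key] = int(ends[-1])
        if chrom_sizes:
            for chrom, size in chrom_sizes.items():
                self._lengths[_chrom_key(chrom)] = int(size)
        self._warner = _MissingChromWarner()

    def chrom_length(self, chrom: str) -> int | None:
        return self._lengths.get(_chrom_key(chrom))

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        if end <= start:
            raise ValueError("need start < end")
        out = np.zeros(end - start, dtype=np.float64)
        data = self._per_chrom.get(_chrom_key(chrom))
        if data is None:
            self._warner.warn(chrom, self.source)
            return out
        starts, ends, vals = data
        i = max(0, np.searchsorted(ends, start, side="right"))
        j = np.searchsorted(starts, end, side="left")
        for k in range(i, j):
            lo = max(int(starts[k]), start, 0)
            hi = min(int(ends[k]), end)
            if lo < hi:
                out[lo - start : hi - start] = vals[k]
        return out

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        data = self._per_chrom.get(_chrom_key(chrom))
        if data is None:
            self._warner.warn(chrom, self.source)
            return 0.0
        starts, ends, vals = data
        i = np.searchsorted(ends, start, side="right")
        j = np.searchsorted(starts, end, side="left")
        if i >= j:
            return 0.0
        s = starts[i:j].astype(np.float64).copy()
        e = ends[i:j].astype(np.float64).copy()
        np.clip(s, start, None, out=s)
        np.clip(e, None, end, out=e)
        lengths = np.maximum(e - s, 0.0)
        return float(np.dot(lengths, vals[i:j]))


class BigWigSignal:
    """bigWig backend, available only when pyBigWig is importable."""

    def __init__(self, path) -> None:
        import pyBigWig  # deferred: optional dependency

        self.source = str(path)
        self._bw = pyBigWig.open(str(path))
        self._chroms = {_chrom_key(c): int(n) for c, n in self._bw.chroms().items()}
        self._names = {_chrom_key(c): c for c in self._bw.chroms()}
        self._warner = _MissingChromWarner()

    def chrom_length(self, chrom: str) -> int | None:
        return self._chroms.get(_chrom_key(chrom))

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        if end <= start:
            raise ValueError("need start < end")
        out = np.zeros(end - start, dtype=np.float64)
        key = _chrom_key(chrom)
        if key not in self._chroms:
            self._warner.warn(chrom, self.source)
            return out
        lo, hi = max(start, 0), min(end, self._chroms[key])
        if lo < hi:
            vals = np.asarray(self._bw.values(self._names[key], lo, hi), dtype=np.float64)
            out[lo - start : hi - start] = np.nan_to_num(vals)
        return out

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        return float(self.values(chrom, start, end).sum())


def open_signal(path, chrom_sizes: Mapping[str, int] | None = None):
    """Open a signal file by extension (.bedgraph/.bg text, .bw/.bigwig binary)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".bw", ".bigwig"):
        return BigWigSignal(path)
    return BedGraphSignal(path, chrom_sizes=chrom_sizes)


def write_bedgraph(arrays: Mapping[str, np.ndarray], path, decimals: int = 4) -> None:
    """Serialize per-base arrays as run-length-encoded bedGraph text."""
    with open(path, "w") as fh:
        for chrom in arrays:
            vals = np.round(np.asarray(arrays[chrom], dtype=np.float64), decimals)
            if vals.size == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [vals.size]))
            frame = pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "value": vals[starts]}
            )
            frame.to_csv(fh, sep="\t", header=False, index=False, float_format="%.10g")


@dataclass
class TrackRecord:
    """One coverage track: a signal file plus catalogue metadata."""

    track_id: str
    path: str
    assembly: str = ""
    description: str = ""
    category: str = "other"
    total_tags: float | None = None
    signal: object | None = None  # preopened backend, used by simulations

    def open(self, chrom_sizes: Mapping[str, int] | None = None):
        if self.signal is None:
            self.signal = open_signal(self.path, chrom_sizes=chrom_sizes)
        return self.signal


@dataclass
class TrackCollection:
    tracks: list[TrackRecord]
    assembly: str = ""

    def __post_init__(self) -> None:
        ids = [t.track_id for t in self.tracks]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate track_id(s): {dup}")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def __getitem__(self, track_id: str) -> TrackRecord:
        for t in self.tracks:
            if t.track_id == track_id:
                return t
        raise KeyError(track_id)


@dataclass
class CoverageMatrix:
    """tracks x intervals mean per-base coverage."""

    values: np.ndarray
    track_ids: list[str]
    interval_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.track_ids), len(self.interval_labels)):
            raise ValueError("CoverageMatrix shape mismatch")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("coverage values must be finite and >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.track_ids, columns=self.interval_labels)


def load_collection(metadata_path, check_files: bool = True) -> TrackCollection:
    """Load a track collection from its metadata TSV.

    Required columns: track_id, path, assembly, category; optional:
    total_tags, description.  Relative signal paths are resolved against the
    TSV's directory.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"track_id": str})
    required = {"track_id", "path", "assembly", "category"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{metadata_path}: missing metadata columns {sorted(missing)}")
    base = Path(metadata_path).parent
    tracks: list[TrackRecord] = []
    for row in meta.itertuples(index=False):
        path = Path(row.path)
        if not path.is_absolute():
            path = base / path
        if check_files and not path.exists():
            raise FileNotFoundError(f"track {row.track_id}: signal file not found: {path}")
        total = getattr(row, "total_tags", None)
        if total is not None and pd.isna(total):
            total = None
        tracks.append(
            TrackRecord(
                track_id=str(row.track_id),
                path=str(path),
                assembly=str(row.assembly),
                description=str(getattr(row, "description", "") or ""),
                category=str(row.category),
                total_tags=float(total) if total is not None else None,
            )
        )
    if not tracks:
        raise ValueError(f"{metadata_path}: no tracks listed")
    assemblies = {t.assembly for t in tracks}
    if len(assemblies) > 1:
        raise ValueError(f"tracks span multiple assemblies: {sorted(assemblies)}")
    collection = TrackCollection(tracks=tracks, assembly=tracks[0].assembly)
    if check_files:
        for t in collection:
            try:
                t.open()
            except Exception as exc:  # noqa: BLE001 - surface the offending file
                raise ValueError(f"track {t.track_id}: cannot open {t.path}: {exc}") from exc
    return collection


def mean_coverage(signal, interval: GenomicInterval) -> float:
    """Length-normalized coverage: per-base sum over [start, end) / length.

    Bases without data (or beyond the recorded chromosome length) count as 0;
    the divisor is always the full requested interval length, so windows
    clipped at chromosome ends stay comparable.
    """
    total = signal.interval_sum(interval.chrom, interval.start, interval.end)
    return total / len(interval)


def coverage_matrix(collection: TrackCollection, intervals: Sequence[GenomicInterval]) -> CoverageMatrix:
    """Mean coverage of every track over every interval (track-major)."""
    if not intervals:
        raise ValueError("empty interval list")
    values = np.empty((len(collection), len(intervals)), dtype=np.float64)
    for t_idx, track in enumerate(collection):
        signal = track.open()
        for i_idx, iv in enumerate(intervals):
            values[t_idx, i_idx] = mean_coverage(signal, iv)
    labels = [iv.label or f"{iv.chrom}:{iv.start}-{iv.end}" for iv in intervals]
    return CoverageMatrix(values=values, track_ids=[t.track_id for t in collection], interval_labels=labels)


def scale_to_tags_per_million(value: float, total_tags: float | None) -> float:
    """Scale a coverage value by 1e6 / total_tags (display normalization)."""
    if total_tags is None:
        warnings.warn("total_tags absent; assuming track is pre-normalized")
        return value
    if total_tags <= 0:
        raise ValueError("total_tags must be positive")
    return value * 1_000_000.0 / total_tags
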