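"""Center-anchored coverage profiles and per-interval coverage distributions.

Profiles average per-base signal in a fixed window around each interval's
center; windows on - strand intervals are reversed so the x-axis always
reads 5' to 3'.  For promoter windows built as TSS +/- w the center is the
TSS, so these are TSS metagene profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ranges import QuerySet
from .tracks import TrackRecord, mean_coverage, scale_to_tags_per_million

__all__ = ["ProfileMatrix", "StackData", "profile", "stack_data"]


@dataclass
class ProfileMatrix:
    """query-sets x positions mean coverage around interval centers."""

    offsets: np.ndarray  # bin start offsets relative to center, 5'->3'
    values: np.ndarray  # shape (n_sets, n_bins)
    set_labels: list[str]
    bin_size: int
    n_intervals: list[int]
    track_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.set_labels), self.offsets.size):
            raise ValueError("ProfileMatrix shape mismatch")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("profile values must be finite and >= 0")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values.T, columns=self.set_labels)
        frame.insert(0, "offset", self.offsets)
        return frame

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class StackData:
    """Per query set, the descending-sorted per-interval mean coverages."""

    track_id: str
    set_labels: list[str]
    coverages: list[np.ndarray]

    def write_tsv(self, path) -> None:
        rows = []
        for label, vec in zip(self.set_labels, self.coverages):
            for rank, value in enumerate(vec, start=1):
                rows.append((label, rank, value))
        frame = pd.DataFrame(rows, columns=["set", "rank", "coverage"])
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def profile(
    track: TrackRecord,
    sets: Sequence[QuerySet],
    halfwidth: int = 1000,
    bin_size: int = 10,
    scale_per_million: bool = False,
) -> ProfileMatrix:
    """Mean coverage in [center - halfwidth, center + halfwidth) per query set.

    Windows of - strand intervals are reversed base-by-base before
    averaging; "." strands count as +.  Bases outside chromosome bounds
    contribute 0.  Bins average ``bin_size`` consecutive bases; offsets are
    the 5'-most base of each bin relative to the center.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be > 0")
    width = 2 * halfwidth
    if bin_size <= 0 or width % bin_size != 0:
        raise ValueError(f"bin_size must divide {width}")
    signal = track.open()
    per_set: list[np.ndarray] = []
    n_intervals: list[int] = []
    for qset in sets:
        if len(qset) == 0:
            raise ValueError(f"query set {qset.label!r} is empty")
        acc = np.zeros(width, dtype=np.float64)
        for iv in qset:
            center = iv.center
            window = signal.values(iv.chrom, center - halfwidth, center + halfwidth)
            if iv.strand == "-":
                window = window[::-1]
            acc += window
        mean = acc / len(qset)
        binned = mean.reshape(-1, bin_size).mean(axis=1)
        if scale_per_million:
            binned = binned * scale_to_tags_per_million(1.0, track.total_tags)
        per_set.append(binned)
        n_intervals.append(len(qset))
    offsets = np.arange(-halfwidth, halfwidth, bin_size)
    return ProfileMatrix(
        offsets=offsets,
        values=np.vstack(per_set),
        set_labels=[s.label for s in sets],
        bin_size=bin_size,
        n_intervals=n_intervals,
        track_id=track.track_id,
    )


def stack_data(track: TrackRecord, sets: Sequence[QuerySet]) -> StackData:
    """Per-interval mean coverages of each set, sorted descending for display."""
    signal = track.open()
    coverages: list[np.ndarray] = []
    for qset in sets:
        if len(qset) == 0:
            raise ValueError(f"query set {qset.label!r} is empty")
        vec = np.array([mean_coverage(signal, iv) for iv in qset], dtype=np.float64)
        coverages.append(np.sort(vec)[::-1])
    return StackData(track_id=track.track_id, set_labels=[s.label for s in sets], coverages=coverages)
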