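"""Shared fixtures: small synthetic genomes, annotations and track collections."""

from __future__ import annotations

import numpy as np
import pytest

from trackrank.annotation import AnnotationIndex, TranscriptRecord
from trackrank.synthetic import SyntheticConfig, make_annotation_index, make_collection
from trackrank.tracks import ArraySignal, TrackCollection, TrackRecord


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_chroms=1,
        chrom_length=200_000,
        n_genes=50,
        enriched_genes=8,
        peak_amplitude=5.0,
        peak_halfwidth=300,
        noise_sd=1.0,
        baseline=1.0,
        n_tracks=6,
        n_enriched_tracks=1,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_index(small_config) -> AnnotationIndex:
    return make_annotation_index(small_config)


@pytest.fixture(scope="session")
def small_collection(small_config, small_index):
    return make_collection(small_config, small_index)


@pytest.fixture()
def toy_index() -> AnnotationIndex:
    """Hand-built 4-gene index with known TSSs on both strands."""
    records = [
        TranscriptRecord("ENST00000000001", "Alpha", "chr1", "+", 5000, ("NM_000001",)),
        TranscriptRecord("ENST00000000002", "Alpha", "chr1", "+", 5200, ("NM_000002",)),
        TranscriptRecord("ENST00000000003", "Beta", "chr1", "-", 20000, ("NM_000003",)),
        TranscriptRecord("ENST00000000004", "Gamma", "chr1", "+", 40000),
        TranscriptRecord("ENST00000000005", "Delta", "chr2", "-", 300, ("NM_000005",)),
    ]
    return AnnotationIndex.build(records, {"chr1": 100_000, "chr2": 50_000})


def constant_track(track_id: str, value: float, chroms: dict[str, int]) -> TrackRecord:
    arrays = {c: np.full(n, value, dtype=float) for c, n in chroms.items()}
    return TrackRecord(
        track_id=track_id,
        path=f"{track_id}.bedgraph",
        assembly="toy1",
        category="other",
        signal=ArraySignal(arrays, source=track_id),
    )


@pytest.fixture()
def constant_collection() -> TrackCollection:
    chroms = {"chr1": 10_000}
    return TrackCollection(
        tracks=[constant_track("C1", 1.0, chroms), constant_track("C3", 3.0, chroms)],
        assembly="toy1",
    )
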