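"""Coverage over-representation statistics.

Per track, mean per-base coverages of the query and background interval sets
are log-transformed (with a pseudocount) and compared by a Welch two-sample
t-test; raw p-values are Bonferroni-corrected by the number of tracks
actually tested.  A parametric z-score mode serves single-region lookups.

The log base provably does not affect t, p or the ranking (a base change is
a common linear rescaling of both samples), and a track-constant scaling
factor cancels between query and background — which is why tags-per-million
normalization is applied only when plotting, never here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .ranges import GenomicInterval, QuerySet
from .tracks import TrackCollection, coverage_matrix, mean_coverage

__all__ = [
    "EnrichmentConfig",
    "EnrichmentResult",
    "ZScoreResult",
    "log_transform",
    "welch_t_test",
    "bonferroni",
    "fold_difference",
    "enrich_all",
    "single_region_zscore",
]


@dataclass(frozen=True)
class EnrichmentConfig:
    """Knobs of the enrichment procedure with their defaults."""

    pseudocount: float = 0.01
    log_base: float = 2.0
    n_background: int = 1000
    promoter_upstream: int = 1000
    promoter_downstream: int = 1000
    profile_halfwidth: int = 1000
    profile_bin: int = 10
    alpha: float = 0.05
    seed: int = 0
    test_sides: int = 2

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.log_base <= 1:
            raise ValueError("log_base must be > 1")
        if self.n_background < 2:
            raise ValueError("n_background must be >= 2")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.test_sides not in (1, 2):
            raise ValueError("test_sides must be 1 or 2")


@dataclass(frozen=True)
class EnrichmentResult:
    track_id: str
    query_mean: float
    background_mean: float
    fold_difference: float
    t_statistic: float
    degrees_freedom: float
    p_value: float
    bonferroni_p: float
    n_query: int
    n_background: int
    degenerate: bool = False
    description: str = ""


@dataclass(frozen=True)
class ZScoreResult:
    track_id: str
    region_value: float
    background_mean_log: float
    background_sd_log: float
    z: float
    p_value: float
    degenerate: bool = False
    description: str = ""


def log_transform(values, config: EnrichmentConfig = EnrichmentConfig()) -> np.ndarray:
    """Element-wise log_base(value + pseudocount); values must be >= 0."""
    arr = np.asarray(values, dtype=np.float64)
    if np.any(arr < 0):
        raise ValueError("coverage values must be non-negative")
    return np.log(arr + config.pseudocount) / math.log(config.log_base)


def welch_t_test(x, y, sides: int = 2) -> tuple[float, float, float]:
    """Welch unequal-variance two-sample t-test.

    Returns (t, df, p) with t = (mean_x - mean_y) / sqrt(s2x/nx + s2y/ny)
    and Welch-Satterthwaite degrees of freedom.  Both samples need >= 2
    observations.  When both sample variances are zero: p = 1 (t = 0) for
    equal means, p = 0 with t = +/-inf for differing means (degenerate).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError(f"welch_t_test needs >= 2 observations per sample, got {nx} and {ny}")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if mx == my:
            return 0.0, float(nx + ny - 2), 1.0
        return math.copysign(math.inf, mx - my), float(nx + ny - 2), 0.0
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    if sides == 2:
        p = 2.0 * stats.t.sf(abs(t), df)
    else:
        p = float(stats.t.sf(t, df))
    return float(t), float(df), float(min(p, 1.0))


def bonferroni(p: float, m: int) -> float:
    """min(1, p * m): family-wise correction over m tested tracks."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


def fold_difference(query_mean: float, background_mean: float, epsilon: float = 0.01) -> float:
    """(query + eps) / (background + eps) on raw, un-logged means."""
    if query_mean < 0 or background_mean < 0:
        raise ValueError("coverage means must be >= 0")
    return (query_mean + epsilon) / (background_mean + epsilon)


def _rank_key(result: EnrichmentResult):
    # ascending p, then descending fold, then track id: deterministic reports
    return (result.p_value, -result.fold_difference, result.track_id)


def enrich_all(
    collection: TrackCollection,
    query: QuerySet,
    background: QuerySet,
    config: EnrichmentConfig = EnrichmentConfig(),
) -> list[EnrichmentResult]:
    """Test every track for query-vs-background coverage over-representation.

    Returns one result per track, sorted by ascending p-value (ties broken
    by descending fold difference, then track id).  Tracks with identically
    zero coverage on both sets are kept, flagged degenerate with p = 1 —
    dropping them would silently change the Bonferroni family size m.
    """
    if len(query) < 2 or len(background) < 2:
        raise ValueError("query and background each need >= 2 intervals")
    if len(collection) == 0:
        raise ValueError("empty track collection")
    q_cov = coverage_matrix(collection, query.intervals).values
    b_cov = coverage_matrix(collection, background.intervals).values
    m = len(collection)
    results: list[EnrichmentResult] = []
    for idx, track in enumerate(collection):
        q_raw, b_raw = q_cov[idx], b_cov[idx]
        q_log = log_transform(q_raw, config)
        b_log = log_transform(b_raw, config)
        degenerate = bool(np.all(q_raw == 0.0) and np.all(b_raw == 0.0))
        if degenerate:
            t, df, p = 0.0, float(q_raw.size + b_raw.size - 2), 1.0
        else:
            t, df, p = welch_t_test(q_log, b_log, sides=config.test_sides)
            if math.isinf(t):
                degenerate = True
        qm, bm = float(q_raw.mean()), float(b_raw.mean())
        results.append(
            EnrichmentResult(
                track_id=track.track_id,
                query_mean=qm,
                background_mean=bm,
                fold_difference=fold_difference(qm, bm, epsilon=config.pseudocount),
                t_statistic=t,
                degrees_freedom=df,
                p_value=p,
                bonferroni_p=bonferroni(p, m),
                n_query=int(q_raw.size),
                n_background=int(b_raw.size),
                degenerate=degenerate,
                description=track.description,
            )
        )
    return sorted(results, key=_rank_key)


def single_region_zscore(
    collection: TrackCollection,
    region: GenomicInterval,
    background: QuerySet,
    config: EnrichmentConfig = EnrichmentConfig(),
) -> list[ZScoreResult]:
    """Standard score of one region's log coverage against the background.

    z = (log-cov(region) - mean(log-cov(bg))) / sd(log-cov(bg)); p is the
    two-sided standard-normal tail.  Tracks whose background log coverage
    has zero spread are flagged degenerate with p = 1.
    """
    if len(background) < 2:
        raise ValueError("background needs >= 2 intervals")
    b_cov = coverage_matrix(collection, background.intervals).values
    results: list[ZScoreResult] = []
    for idx, track in enumerate(collection):
        signal = track.open()
        region_log = float(log_transform(np.array([mean_coverage(signal, region)]), config)[0])
        b_log = log_transform(b_cov[idx], config)
        mean_log = float(b_log.mean())
        sd_log = float(b_log.std(ddof=1))
        if sd_log == 0.0:
            results.append(
                ZScoreResult(
                    track_id=track.track_id,
                    region_value=region_log,
                    background_mean_log=mean_log,
                    background_sd_log=0.0,
                    z=float("nan"),
                    p_value=1.0,
                    degenerate=True,
                    description=track.description,
                )
            )
            continue
        z = (region_log - mean_log) / sd_log
        p = float(2.0 * stats.norm.sf(abs(z)))
        results.append(
            ZScoreResult(
                track_id=track.track_id,
                region_value=region_log,
                background_mean_log=mean_log,
                background_sd_log=sd_log,
                z=float(z),
                p_value=min(p, 1.0),
                description=track.description,
            )
        )
    return sorted(results, key=lambda r: (r.p_value, r.track_id))
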