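import math

import numpy as np
import pytest
from scipy import stats

from trackrank.annotation import promoters_for, sample_background
from trackrank.enrichment import (
    EnrichmentConfig,
    bonferroni,
    enrich_all,
    fold_difference,
    log_transform,
    single_region_zscore,
    welch_t_test,
)
from trackrank.ranges import GenomicInterval, QuerySet
from trackrank.tracks import ArraySignal, TrackCollection, TrackRecord


class TestConfig:
    def test_defaults(self):
        cfg = EnrichmentConfig()
        assert cfg.n_background == 1000
        assert cfg.profile_halfwidth == 1000
        assert cfg.test_sides == 2

    @pytest.mark.parametrize(
        "kw",
        [
            dict(pseudocount=0.0),
            dict(log_base=1.0),
            dict(n_background=1),
            dict(alpha=0.0),
            dict(alpha=1.0),
            dict(test_sides=3),
        ],
    )
    def test_validation(self, kw):
        with pytest.raises(ValueError):
            EnrichmentConfig(**kw)


class TestLogTransform:
    def test_log2_of_one_is_zero(self):
        cfg = EnrichmentConfig(pseudocount=1.0, log_base=2.0)
        assert log_transform([0.0], cfg)[0] == pytest.approx(0.0)

    def test_log2_of_four(self):
        cfg = EnrichmentConfig(pseudocount=1.0, log_base=2.0)
        assert log_transform([3.0], cfg)[0] == pytest.approx(2.0)

    def test_elementwise_oracle(self):
        cfg = EnrichmentConfig(pseudocount=0.01, log_base=2.0)
        values = [0.0, 1.0, 3.0]
        expected = [math.log(v + 0.01, 2.0) for v in values]
        np.testing.assert_allclose(log_transform(values, cfg), expected, rtol=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform([-0.5])


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # x=[1,2,3,4], y=[2,3,4,5]: equal variances 5/3, t=-1/sqrt(5/6), df=6
        t, df, p = welch_t_test([1, 2, 3, 4], [2, 3, 4, 5])
        assert t == pytest.approx(-1.0 / math.sqrt(5.0 / 6.0), rel=1e-12)
        assert df == pytest.approx(6.0, rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 6.0), rel=1e-12)

    def test_against_scipy_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = rng.normal(size=int(rng.integers(2, 30)))
            y = rng.normal(loc=rng.normal(), size=int(rng.integers(2, 30)))
            t, df, p = welch_t_test(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-12, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12, abs=1e-12)

    def test_sample_size_precondition(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_zero_variance_equal_means(self):
        t, _, p = welch_t_test([2.0, 2.0], [2.0, 2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_zero_variance_different_means(self):
        t, _, p = welch_t_test([2.0, 2.0], [3.0, 3.0])
        assert math.isinf(t) and t < 0
        assert p == 0.0

    def test_swap_negates_t_preserves_p(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=10), rng.normal(loc=0.5, size=15)
        t1, _, p1 = welch_t_test(x, y)
        t2, _, p2 = welch_t_test(y, x)
        assert t2 == pytest.approx(-t1, rel=1e-12)
        assert p2 == pytest.approx(p1, rel=1e-12)

    def test_one_sided(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(loc=1.0, size=12), rng.normal(size=12)
        t, df, p1 = welch_t_test(x, y, sides=1)
        _, _, p2 = welch_t_test(x, y, sides=2)
        assert p1 == pytest.approx(stats.t.sf(t, df), rel=1e-12)
        if t > 0:
            assert p1 == pytest.approx(p2 / 2, rel=1e-12)


class TestBonferroni:
    def test_paper_cap_pattern(self):
        # raw 0.0093 corrected to 1.0 once m pushes the product past 1
        assert bonferroni(0.0093, 358) == 1.0

    def test_paper_product_pattern(self):
        # m recovered as the ratio of the printed pair 6.7e-6 -> 0.0024
        m = round(0.0024 / 6.7e-6)
        assert m == 358
        assert bonferroni(6.7e-6, m) == pytest.approx(0.0024, abs=5e-5)

    def test_identity_at_one(self):
        assert bonferroni(0.5, 1) == 0.5

    def test_monotone(self):
        assert bonferroni(0.01, 5) <= bonferroni(0.02, 5)
        assert bonferroni(0.01, 5) <= bonferroni(0.01, 10)

    def test_domain(self):
        with pytest.raises(ValueError):
            bonferroni(1.5, 2)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


class TestFoldDifference:
    def test_table_ratio(self):
        # ratio of printed query/background coverages, epsilon -> 0
        assert fold_difference(1.3, 0.59, epsilon=1e-12) == pytest.approx(2.2, abs=0.01)

    def test_identity(self):
        assert fold_difference(0.7, 0.7) == pytest.approx(1.0)

    def test_degenerate_zero_zero(self):
        assert fold_difference(0.0, 0.0, epsilon=0.01) == pytest.approx(1.0)


def _promoter_sets(index, truth, n_bg=30, seed=3):
    query = promoters_for(truth.enriched_gene_symbols, index)
    background = sample_background(index, n=n_bg, seed=seed)
    return query, background


class TestEnrichAll:
    def test_planted_track_ranks_first(self, small_collection, small_index):
        collection, truth = small_collection
        query, background = _promoter_sets(small_index, truth)
        results = enrich_all(collection, query, background)
        assert results[0].track_id == truth.enriched_track_ids[0]
        assert results[0].bonferroni_p < 0.05

    def test_query_equals_background(self, small_collection, small_index):
        collection, truth = small_collection
        query, _ = _promoter_sets(small_index, truth)
        results = enrich_all(collection, query, query)
        assert all(r.p_value == pytest.approx(1.0) for r in results)
        assert all(r.t_statistic == pytest.approx(0.0) for r in results)

    def test_bonferroni_uses_tested_family_size(self, small_collection, small_index):
        collection, truth = small_collection
        query, background = _promoter_sets(small_index, truth)
        results = enrich_all(collection, query, background)
        m = len(collection)
        for r in results:
            assert r.bonferroni_p == pytest.approx(min(1.0, r.p_value * m))

    def test_sorted_by_p(self, small_collection, small_index):
        collection, truth = small_collection
        query, background = _promoter_sets(small_index, truth)
        results = enrich_all(collection, query, background)
        ps = [r.p_value for r in results]
        assert ps == sorted(ps)

    def test_all_zero_track_reported_degenerate(self, small_index):
        chroms = {c: np.zeros(n) for c, n in small_index.chrom_sizes.items()}
        dead = TrackRecord(track_id="Z", path="z.bedgraph", signal=ArraySignal(chroms))
        collection = TrackCollection(tracks=[dead])
        query = promoters_for(["GENE0001", "GENE0002"], small_index)
        background = sample_background(small_index, n=5, seed=1)
        (result,) = enrich_all(collection, query, background)
        assert result.degenerate
        assert result.p_value == 1.0

    def test_minimum_sample_sizes(self, small_collection, small_index):
        collection, _ = small_collection
        one = promoters_for(["GENE0001"], small_index)
        background = sample_background(small_index, n=5, seed=1)
        with pytest.raises(ValueError):
            enrich_all(collection, one, background)

    def test_base_invariance(self, small_collection, small_index):
        collection, truth = small_collection
        query, background = _promoter_sets(small_index, truth)
        r2 = enrich_all(collection, query, background, EnrichmentConfig(log_base=2.0))
        re_ = enrich_all(collection, query, background, EnrichmentConfig(log_base=math.e))
        assert [r.track_id for r in r2] == [r.track_id for r in re_]
        for a, b in zip(r2, re_):
            assert a.t_statistic == pytest.approx(b.t_statistic, rel=1e-10, abs=1e-10)
            assert a.p_value == pytest.approx(b.p_value, rel=1e-10, abs=1e-10)

    def test_scale_cancellation(self, small_index):
        """Scaling a track by c with co-scaled pseudocount leaves t, p unchanged."""
        rng = np.random.default_rng(9)
        arrays = {c: rng.random(n) for c, n in small_index.chrom_sizes.items()}
        c = 37.0
        scaled = {k: v * c for k, v in arrays.items()}
        base = TrackCollection(
            tracks=[TrackRecord(track_id="T", path="t", signal=ArraySignal(arrays))]
        )
        times_c = TrackCollection(
            tracks=[TrackRecord(track_id="T", path="t", signal=ArraySignal(scaled))]
        )
        query = promoters_for(["GENE0001", "GENE0003", "GENE0005"], small_index)
        background = sample_background(small_index, n=10, seed=2)
        (r1,) = enrich_all(base, query, background, EnrichmentConfig(pseudocount=0.01))
        (r2,) = enrich_all(times_c, query, background, EnrichmentConfig(pseudocount=0.01 * c))
        assert r1.t_statistic == pytest.approx(r2.t_statistic, rel=1e-9)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)


class TestSingleRegionZScore:
    def _collection(self, arr):
        sig = ArraySignal({"chr1": arr})
        return TrackCollection(tracks=[TrackRecord(track_id="T", path="t", signal=sig)])

    def test_region_at_background_mean(self):
        arr = np.full(10_000, 2.0)
        collection = self._collection(arr)
        background = QuerySet(
            "bg", [GenomicInterval("chr1", i * 100, i * 100 + 50) for i in range(5)]
        )
        # constant track: sd == 0 -> degenerate, p = 1
        (res,) = single_region_zscore(collection, GenomicInterval("chr1", 0, 50), background)
        assert res.degenerate and res.p_value == 1.0

    def test_z_two_formula(self):
        # z = 2 -> p = 2 * (1 - Phi(2)) ~ 0.0455, via direct standard-normal tail
        rng = np.random.default_rng(12)
        arr = rng.random(50_000) + 0.5
        collection = self._collection(arr)
        background = QuerySet(
            "bg", [GenomicInterval("chr1", i * 500, i * 500 + 200) for i in range(20)]
        )
        region = GenomicInterval("chr1", 30_000, 30_200)
        (res,) = single_region_zscore(collection, region, background)
        assert res.p_value == pytest.approx(2 * stats.norm.sf(abs(res.z)), rel=1e-12)

    def test_standard_normal_tail_example(self):
        assert 2 * stats.norm.sf(2.0) == pytest.approx(0.0455, abs=1e-4)

    def test_sorted_by_p(self, small_collection, small_index):
        collection, truth = small_collection
        background = sample_background(small_index, n=20, seed=4)
        region = promoters_for([truth.enriched_gene_symbols[0]], small_index).intervals[0]
        results = single_region_zscore(collection, region, background)
        ps = [r.p_value for r in results]
        assert ps == sorted(ps)
        assert results[0].track_id == truth.enriched_track_ids[0]
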