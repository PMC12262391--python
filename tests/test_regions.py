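"""Greedy region recommendation, block reduction and similarity search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chromsaliency as cs
from chromsaliency.regions import N_BLOCKS
from helpers import matrix_from_rows, max_sum_window_bruteforce


def track_from_scores(per_state, bin_size=200):
    per_state = np.asarray(per_state, dtype=float)
    model = cs.StateModel(labels=tuple(chr(ord("A") + i) for i in range(per_state.shape[1])))
    return cs.ScoreTrack(per_state, "S1", cs.GenomeBins.single(per_state.shape[0], bin_size), model)


class TestRecommendRegions:
    def test_hand_trace_of_greedy_extension(self):
        scores = np.array([0, 0, 5, 1, 0, 0, 0], dtype=float)
        bins = cs.GenomeBins.single(7, 200)
        out = cs.recommend_regions(scores, bins, region_size=600, k=5)
        # seed at bin 2 extends right (1 > 0), then right again (tie -> right)
        assert out[0].start == 400 and out[0].end == 1000
        assert out[0].score == pytest.approx(6.0)

    def test_all_zero_scores_yield_empty_set(self):
        out = cs.recommend_regions(np.zeros(50), cs.GenomeBins.single(50, 200), 1000, k=3)
        assert len(out) == 0

    def test_two_distant_peaks_two_regions(self):
        scores = np.zeros(100)
        scores[10] = 5
        scores[80] = 4
        out = cs.recommend_regions(scores, cs.GenomeBins.single(100, 200), 2000, k=2)
        assert len(out) == 2
        assert out[0].start <= 10 * 200 < out[0].end
        assert out[1].start <= 80 * 200 < out[1].end

    def test_nonoverlap_and_monotone_scores(self):
        rng = np.random.default_rng(8)
        scores = rng.exponential(size=400)
        out = cs.recommend_regions(scores, cs.GenomeBins.single(400, 200), 4000, k=10)
        ranked = list(out)
        for i, a in enumerate(ranked):
            assert (a.end - a.start) == 4000
            for b in ranked[i + 1:]:
                assert not a.overlaps(b)
        aggs = [r.score for r in ranked]
        assert all(x >= y - 1e-12 for x, y in zip(aggs, aggs[1:]))

    @given(st.integers(0, 200))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_rank_one_matches_max_window_on_unimodal_tracks(self, seed):
        rng = np.random.default_rng(seed)
        peak = rng.integers(5, 45)
        x = np.arange(50, dtype=float)
        scores = np.exp(-((x - peak) ** 2) / (2 * rng.uniform(1, 6) ** 2))
        bins = cs.GenomeBins.single(50, 200)
        out = cs.recommend_regions(scores, bins, region_size=5 * 200, k=1)
        start, best = max_sum_window_bruteforce(scores, 5)
        assert out[0].score == pytest.approx(best)

    def test_regions_do_not_cross_chromosomes(self):
        bins = cs.GenomeBins(("chr1", "chr2"), 200, (10, 10))
        scores = np.zeros(20)
        scores[9] = 5  # last bin of chr1
        out = cs.recommend_regions(scores, bins, region_size=1000, k=1)
        assert out[0].chrom == "chr1"
        assert out[0].end <= 10 * 200

    def test_invalid_region_size_raises(self):
        bins = cs.GenomeBins.single(10, 200)
        with pytest.raises(ValueError, match="multiple"):
            cs.recommend_regions(np.ones(10), bins, region_size=500)
        with pytest.raises(ValueError, match="long enough"):
            cs.recommend_regions(np.ones(10), bins, region_size=4000)


class TestReduceRegion:
    def test_identity_pooling_at_25_bins(self):
        rng = np.random.default_rng(0)
        track = track_from_scores(rng.normal(size=(25, 3)))
        bv = cs.reduce_region(track, "chrS", 0, 5000)
        np.testing.assert_allclose(bv.values, track.per_state)

    def test_max_of_two_bins_per_block(self):
        per_state = np.zeros((50, 2))
        per_state[0, 0], per_state[1, 0] = 0.1, 0.9
        track = track_from_scores(per_state)
        bv = cs.reduce_region(track, "chrS", 0, 10_000)
        assert bv.values[0, 0] == pytest.approx(0.9)

    @given(st.integers(0, 100))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_matches_bruteforce_blockwise_max(self, seed):
        rng = np.random.default_rng(seed)
        c = int(rng.integers(1, 5))
        track = track_from_scores(rng.normal(size=(25 * c, 3)))
        bv = cs.reduce_region(track, "chrS", 0, 25 * c * 200)
        for blk in range(N_BLOCKS):
            for i in range(3):
                expect = track.per_state[blk * c : (blk + 1) * c, i].max()
                assert bv.values[blk, i] == pytest.approx(expect)

    def test_always_25_blocks_and_divisibility_error(self):
        rng = np.random.default_rng(1)
        track = track_from_scores(rng.normal(size=(100, 2)))
        assert cs.reduce_region(track, "chrS", 0, 10_000).values.shape[0] == N_BLOCKS
        with pytest.raises(ValueError, match="multiple"):
            cs.reduce_region(track, "chrS", 0, 4_800)


class TestSearchIndex:
    def test_single_window_when_chromosome_equals_region(self):
        track = track_from_scores(np.zeros((25, 2)))
        assert len(cs.build_search_index(track, 5_000)) == 1

    def test_window_count_formula(self):
        # L = 2W, stride = W/2 -> floor((L - W)/stride) + 1 = 3
        track = track_from_scores(np.zeros((100, 2)))
        idx = cs.build_search_index(track, 10_000, stride=5_000)
        assert len(idx) == 3

    def test_every_window_has_25_blocks(self):
        rng = np.random.default_rng(2)
        track = track_from_scores(rng.normal(size=(200, 2)))
        for bv in cs.build_search_index(track, 5_000):
            assert bv.values.shape[0] == N_BLOCKS


class TestSimilarityThreshold:
    def test_degenerate_equal_distances(self):
        track = track_from_scores(np.ones((25, 1)))
        idx = [cs.BlockVector(np.full((25, 1), 3.0), "chrS", s, s + 5000)
               for s in range(0, 30_000, 5_000)]
        q = cs.BlockVector(np.zeros((25, 1)), "chrS", 0, 5000)
        # all distances equal d -> threshold d/2
        d = np.linalg.norm(idx[0].flat() - q.flat())
        with pytest.warns(UserWarning):
            assert cs.similarity_threshold(idx, q) == pytest.approx(d / 2)

    def test_small_index_median_fallback_hand_case(self):
        # distances {0, 10, 10, 10, 10, 20}: mode 10 -> threshold 5
        vals = [0, 10, 10, 10, 10, 20]
        idx = []
        for k, v in enumerate(vals):
            block = np.zeros((25, 1))
            block[0, 0] = v
            idx.append(cs.BlockVector(block, "chrS", k * 5000, (k + 1) * 5000))
        q = cs.BlockVector(np.zeros((25, 1)), "chrS", 0, 5000)
        with pytest.warns(UserWarning, match="median"):
            assert cs.similarity_threshold(idx, q) == pytest.approx(5.0)

    def test_positive_whenever_any_distance_positive(self):
        rng = np.random.default_rng(4)
        track = track_from_scores(rng.exponential(size=(500, 2)))
        idx = cs.build_search_index(track, 5_000)
        q = cs.reduce_region(track, "chrS", 0, 5_000)
        assert cs.similarity_threshold(idx, q) > 0


class TestSimilaritySearch:
    @pytest.fixture
    def planted(self):
        spec = cs.SimulationSpec(n_states=4, m_biosamples=5, n_bins=8_000, seed=11)
        pattern = np.tile(np.array([[0, 1, 1, 0, 2]] * 5), 5)
        spec = cs.plant_recurrent_pattern(spec, pattern, n_copies=3, min_gap=200)
        m = cs.simulate_matrix(spec, model=cs.default_state_model(4))
        return spec, cs.s1_scores(m)

    def test_self_window_found_before_exclusion(self, planted):
        spec, track = planted
        p0 = spec.plants[0].positions[0]
        idx = cs.build_search_index(track, 5_000)
        q = cs.reduce_region(track, "chrS", p0 * 200, p0 * 200 + 5_000)
        self_hits = [bv for bv in idx if bv.start == p0 * 200]
        assert self_hits and np.linalg.norm(self_hits[0].flat() - q.flat()) == 0

    def test_planted_copies_are_top_hits(self, planted):
        spec, track = planted
        p0, p1, p2 = spec.plants[0].positions
        hits = cs.similarity_search(track, "chrS", p0 * 200, p0 * 200 + 5_000, max_hits=5)
        starts = {r.start for r in list(hits)[:2]}
        assert starts == {p1 * 200, p2 * 200}
        assert all(r.score == pytest.approx(0.0) for r in list(hits)[:2])

    def test_shifted_copy_tolerated_by_pooling_at_10kb(self):
        # at 10 kb each block pools 2 bins; an alternating two-state pattern
        # yields the same {state0, state1} pooled content in each block after
        # a 1-bin shift, so the shifted copy stays close while random windows
        # stay far beyond the threshold
        spec = cs.SimulationSpec(n_states=4, m_biosamples=5, n_bins=10_000, seed=29)
        pattern = np.tile(np.array([[0, 1]] * 5), 25)  # 50 bins = 10 kb
        base = 1_000
        states = cs.simulate_matrix(spec, model=cs.default_state_model(4)).states.copy()
        states[:, base : base + 50] = pattern
        shifted = 5_001  # one bin off the 25-bin grid
        states[:, shifted : shifted + 50] = pattern
        m = matrix_from_rows(states, n_states=4)
        track = cs.s1_scores(m)
        q = cs.reduce_region(track, "chrS", base * 200, (base + 50) * 200)
        idx = cs.build_search_index(track, 10_000)
        thr = cs.similarity_threshold(idx, q)
        shifted_window = cs.reduce_region(track, "chrS", 5_000 * 200, 5_050 * 200)
        d_shift = np.linalg.norm(shifted_window.flat() - q.flat())
        rand_window = cs.reduce_region(track, "chrS", 8_000 * 200, 8_050 * 200)
        d_rand = np.linalg.norm(rand_window.flat() - q.flat())
        assert d_shift <= thr < d_rand

    def test_query_size_bounds(self, planted):
        _, track = planted
        with pytest.raises(ValueError, match="supported range"):
            cs.similarity_search(track, "chrS", 0, 4_000)
        with pytest.raises(ValueError, match="supported range"):
            cs.similarity_search(track, "chrS", 0, 200_000)

    def test_results_invariant_to_coordinate_translation(self, planted):
        spec, track = planted
        p0 = spec.plants[0].positions[0]
        hits = cs.similarity_search(track, "chrS", p0 * 200, p0 * 200 + 5_000)
        shifted_track = cs.ScoreTrack(track.per_state, "S1", track.bins, track.model)
        hits2 = cs.similarity_search(shifted_track, "chrS", p0 * 200, p0 * 200 + 5_000)
        assert [(r.start, r.score) for r in hits] == [(r.start, r.score) for r in hits2]


class TestStructuralDefaults:
    def test_structural_constants(self):
        import inspect

        assert N_BLOCKS == 25
        assert cs.SimulationSpec().bin_size == 200
        assert cs.GenomeBins.single(10).bin_size == 200
        sig = inspect.signature(cs.top_differential_regions)
        assert sig.parameters["region_size"].default == 25_000
        assert sig.parameters["k"].default == 100
        from chromsaliency.cli import recommend

        params = {p.name: p.default for p in recommend.params}
        assert params["region_size"] == 10_000
        assert params["k"] == 100
        from chromsaliency.regions import MAX_QUERY_BP, MIN_QUERY_BP

        assert (MIN_QUERY_BP, MAX_QUERY_BP) == (5_000, 100_000)
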