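"""Saliency metrics against brute-force oracles, chance levels, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multisal.heatmap_builder import HeatMap
from multisal.saliency_metrics import (
    FixationPointSet,
    MetricConfig,
    auc_borji,
    auc_judd,
    compare_pair,
    dense_map_to_fixations,
    information_gain,
    map_to_fixations,
    nss,
    shuffled_auc,
)


def _map(values, variant="filtered"):
    return HeatMap(np.asarray(values, dtype=float), variant)


def _points(*xy):
    return FixationPointSet(points=np.array(xy, dtype=float))


def _pairwise_auc(pos, neg):
    """Independent oracle: P(pos > neg) + P(pos == neg)/2 over all pairs."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


class TestMapToFixations:
    def test_points_and_weights_read_off_nonzero_pixels(self):
        values = np.zeros((32, 32))
        values[20, 10] = 0.3
        values[5, 5] = 0.2
        fps = map_to_fixations(_map(values, "raw"))
        got = {tuple(p): w for p, w in zip(fps.points, fps.weights)}
        assert got == {(10.0, 20.0): 0.3, (5.0, 5.0): 0.2}

    def test_empty_map_gives_empty_set(self):
        assert len(map_to_fixations(_map(np.zeros((8, 8)), "raw"))) == 0

    def test_round_trip_with_delta_map(self):
        from multisal.fixation_processing import Fixation
        from multisal.heatmap_builder import build_delta_map

        fixations = [Fixation(3, 4, 0.25), Fixation(10, 2, 0.5)]
        raw = build_delta_map(fixations, 16, 16)
        fps = map_to_fixations(raw)
        rebuilt = build_delta_map(
            [Fixation(x, y, w) for (x, y), w in zip(fps.points, fps.weights)], 16, 16
        )
        np.testing.assert_array_equal(rebuilt.values, raw.values)


class TestNss:
    def test_constant_map_scores_zero(self):
        assert nss(_map(np.full((10, 10), 3.0)), _points((5, 5))) == 0.0

    def test_hand_computed_three_by_three(self):
        values = np.zeros((3, 3))
        values[1, 1] = 9.0
        # mean 1, population sd sqrt(8) = 2.8284...; z(center) = 8 / sqrt(8)
        assert nss(_map(values), _points((1, 1))) == pytest.approx(8 / np.sqrt(8), abs=1e-12)

    def test_fixations_everywhere_average_to_zero(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 1, (6, 6))
        pts = [(x, y) for x in range(6) for y in range(6)]
        assert nss(_map(values), _points(*pts)) == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        a=st.floats(min_value=0.1, max_value=50.0),
        b=st.floats(min_value=0.0, max_value=5.0),
    )
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(7)
        values = rng.uniform(0, 1, (12, 12))
        pts = _points((3, 4), (10, 2), (6, 6))
        base = nss(_map(values), pts)
        assert nss(_map(a * values + b), pts) == pytest.approx(base, rel=1e-9, abs=1e-9)

    def test_duration_weighted_variant(self):
        values = np.zeros((4, 4))
        values[0, 0], values[3, 3] = 4.0, 0.0
        fps = FixationPointSet(points=np.array([[0, 0], [3, 3]]), weights=np.array([3.0, 1.0]))
        unweighted = nss(_map(values), fps)
        weighted = nss(_map(values), fps, weighted=True)
        assert weighted > unweighted  # more weight on the high-saliency pixel


class TestAucJudd:
    def test_fixations_at_strict_maxima_score_one(self):
        values = np.zeros((8, 8))
        values[2, 2] = values[5, 6] = 1.0
        assert auc_judd(_map(values), _points((2, 2), (6, 5))) == pytest.approx(1.0)

    def test_chance_level_on_random_map(self):
        rng = np.random.default_rng(11)
        values = rng.uniform(0, 1, (256, 256))
        pts = _points(*zip(rng.integers(0, 256, 200), rng.integers(0, 256, 200)))
        assert auc_judd(_map(values), pts) == pytest.approx(0.5, abs=0.05)

    def test_matches_pairwise_oracle_on_small_maps(self, rng):
        for _ in range(20):
            values = rng.integers(0, 5, (4, 4)).astype(float)  # ties included
            mask = rng.random((4, 4)) < 0.3
            if not mask.any() or mask.all():
                continue
            rows, cols = np.nonzero(mask)
            pts = _points(*zip(cols, rows))
            expected = _pairwise_auc(values[mask], values[~mask])
            assert auc_judd(_map(values), pts) == pytest.approx(expected, abs=1e-12)

    def test_all_pixels_fixated_rejected(self):
        pts = [(x, y) for x in range(3) for y in range(3)]
        with pytest.raises(ValueError):
            auc_judd(_map(np.eye(3)), _points(*pts))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(gamma=st.floats(min_value=0.2, max_value=5.0))
    def test_invariant_under_monotone_transform(self, gamma):
        rng = np.random.default_rng(13)
        values = rng.uniform(0.01, 1, (16, 16))
        pts = _points((3, 3), (10, 12), (1, 14))
        assert auc_judd(_map(values**gamma), pts) == pytest.approx(
            auc_judd(_map(values), pts), abs=1e-12
        )


class TestAucBorji:
    def test_perfect_ranking_scores_one(self):
        values = np.zeros((16, 16))
        values[4, 4] = 1.0
        assert auc_borji(_map(values), _points((4, 4)), n_splits=10, rng_seed=0) == pytest.approx(1.0)

    def test_chance_level_on_random_map(self):
        rng = np.random.default_rng(17)
        values = rng.uniform(0, 1, (128, 128))
        pts = _points(*zip(rng.integers(0, 128, 150), rng.integers(0, 128, 150)))
        assert auc_borji(_map(values), pts, n_splits=100, rng_seed=5) == pytest.approx(0.5, abs=0.05)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(19)
        values = rng.uniform(0, 1, (32, 32))
        pts = _points((4, 4), (20, 9))
        a = auc_borji(_map(values), pts, n_splits=20, rng_seed=99)
        b = auc_borji(_map(values), pts, n_splits=20, rng_seed=99)
        assert a == b


class TestShuffledAuc:
    def test_center_bias_cancels_when_pool_shares_distribution(self):
        # center-biased map; positives and pool drawn from the SAME central
        # Gaussian: the shuffled AUC must sit at chance despite the bias
        n = 96
        yy, xx = np.mgrid[0:n, 0:n]
        center_map = np.exp(-(((xx - n / 2) ** 2 + (yy - n / 2) ** 2) / (2 * 20**2)))
        rng = np.random.default_rng(23)

        def draw(k):
            pts = rng.normal(n / 2, 12, size=(k, 2))
            return np.clip(pts, 0, n - 1)

        pos = FixationPointSet(points=draw(300))
        pool = FixationPointSet(points=draw(3000))
        val = shuffled_auc(_map(center_map), pos, pool, n_splits=100, rng_seed=3)
        assert val == pytest.approx(0.5, abs=0.03)

    def test_positives_above_pool_score_one(self):
        values = np.zeros((16, 16))
        values[2, 2] = 1.0
        pos = _points((2, 2))
        pool = _points((10, 10), (12, 3), (5, 8))
        assert shuffled_auc(_map(values), pos, pool, n_splits=5, rng_seed=0) == 1.0

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            shuffled_auc(_map(np.eye(4)), _points((1, 1)), _points(), n_splits=5)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(29)
        values = rng.uniform(0, 1, (32, 32))
        pos = _points((4, 4), (20, 9), (15, 15))
        pool = _points(*zip(rng.integers(0, 32, 40), rng.integers(0, 32, 40)))
        a = shuffled_auc(_map(values), pos, pool, n_splits=15, rng_seed=7)
        b = shuffled_auc(_map(values), pos, pool, n_splits=15, rng_seed=7)
        assert a == b


class TestInformationGain:
    def test_identical_maps_gain_zero(self):
        rng = np.random.default_rng(31)
        values = rng.uniform(0, 1, (10, 10))
        m = _map(values)
        assert information_gain(m, m, _points((3, 3), (7, 2))) == 0.0

    def test_doubled_probability_gains_one_bit(self):
        # p_test = 2 p_base at the fixation pixel (uniform admixture off)
        base = np.full((4, 4), 1.0 / 16.0)
        test = np.full((4, 4), 7.0 / 120.0)  # 15 pixels share 7/8 ...
        test[1, 1] = 1.0 / 8.0  # ... and the fixated pixel holds 2/16
        got = information_gain(_map(test), _map(base), _points((1, 1)), eps=0.0)
        assert got == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_computation_on_5x5(self):
        rng = np.random.default_rng(37)
        a, b = rng.uniform(0, 1, (5, 5)), rng.uniform(0, 1, (5, 5))
        pts = [(1, 1), (4, 2), (0, 3)]
        eps = 1.0 / 25.0
        # independent direct computation of the regularized log-ratio
        pa = (a / a.sum() + eps) / (1 + 25 * eps)
        pb = (b / b.sum() + eps) / (1 + 25 * eps)
        expected = np.mean([np.log2(pa[y, x]) - np.log2(pb[y, x]) for x, y in pts])
        got = information_gain(_map(a), _map(b), _points(*pts))
        assert got == pytest.approx(expected, abs=1e-12)


class TestComparePair:
    def _pair(self, seed, n=48):
        from multisal.fixation_processing import Fixation
        from multisal.heatmap_builder import GaussianKernelSpec, build_delta_map, smooth_map

        rng = np.random.default_rng(seed)
        fixations = [
            Fixation(rng.uniform(5, n - 5), rng.uniform(5, n - 5), rng.uniform(0.1, 0.4))
            for _ in range(12)
        ]
        raw = build_delta_map(fixations, n, n)
        return raw, smooth_map(raw, GaussianKernelSpec(radius=9, sigma=3))

    def test_self_comparison_is_perfect(self):
        # equal-duration fixations spaced far apart (>> kernel sigma): every
        # fixated pixel is a strict maximum of the filtered map, so the
        # self-comparison ranks perfectly
        from multisal.fixation_processing import Fixation
        from multisal.heatmap_builder import GaussianKernelSpec, build_delta_map, smooth_map

        fixations = [Fixation(x, y, 0.3) for x in (12, 36, 60) for y in (12, 60)]
        raw = build_delta_map(fixations, 72, 72)
        filt = smooth_map(raw, GaussianKernelSpec(radius=9, sigma=3))
        res = compare_pair(raw, filt, raw, filt, config=MetricConfig(n_splits=5))
        assert res.values["ig"] == 0.0
        assert res.values["auc_judd"] == pytest.approx(1.0)

    def test_disjoint_attractors_give_negative_nss(self):
        from multisal.fixation_processing import Fixation
        from multisal.heatmap_builder import GaussianKernelSpec, build_delta_map, smooth_map

        k = GaussianKernelSpec(radius=9, sigma=3)
        gt_raw = build_delta_map([Fixation(10, 10, 0.3)], 64, 64)
        test_raw = build_delta_map([Fixation(50, 50, 0.3)], 64, 64)
        res = compare_pair(
            gt_raw, smooth_map(gt_raw, k), test_raw, smooth_map(test_raw, k),
            config=MetricConfig(n_splits=5),
        )
        assert res.values["nss"] < 0

    def test_exactly_five_metrics_reported(self):
        raw, filt = self._pair(2)
        res = compare_pair(raw, filt, raw, filt, config=MetricConfig(n_splits=5))
        assert set(res.values) == {"nss", "auc_judd", "auc_borji", "sauc", "ig"}


def test_dense_map_fixation_extraction_picks_top_pixels():
    values = np.zeros((10, 10))
    values[3, 7] = 5.0
    fps = dense_map_to_fixations(values, top_fraction=0.01)
    assert len(fps) == 1
    assert tuple(fps.points[0]) == (7.0, 3.0)
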