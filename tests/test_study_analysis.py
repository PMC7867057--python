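"""Pairwise bookkeeping, statistics, band harness and end-to-end study runs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from multisal.heatmap_builder import GaussianKernelSpec, HeatMap
from multisal.saliency_metrics import METRIC_NAMES, MetricConfig
from multisal.study_analysis import (
    ObserverMaps,
    StudyConfig,
    accumulated_maps,
    band_comparison_harness,
    baseline_predictor,
    build_observer_maps,
    correlation_table,
    display_density_px_per_mm,
    hms,
    interexperiment_comparison,
    interobserver_comparisons,
    linear_fit_r2,
    one_way_anova,
    run_study,
    session_display_time_s,
)
from multisal.synthetic_data import (
    Attractor,
    GazeSimConfig,
    Region,
    SceneSpec,
    generate_gaze_logs,
    generate_study,
)

FAST_KERNEL = GaussianKernelSpec(radius=15, sigma=5.0)
FAST_METRICS = MetricConfig(n_splits=5)


def _observer_maps(n_observers, seed=0, size=96):
    cfg = GazeSimConfig(
        seed=seed,
        attractors=[Attractor(size / 2, size / 2, 0.7, 10.0), Attractor(20.0, 20.0, 0.3, 8.0)],
        n_observers=n_observers,
        image_duration=3.0,
    )
    logs = generate_gaze_logs(cfg, (size, size))
    return build_observer_maps(logs, size, size, FAST_KERNEL)


class TestInterobserver:
    def test_ten_observers_give_45_pairwise_comparisons(self):
        maps = _observer_maps(10)
        comps = interobserver_comparisons(maps, config=FAST_METRICS)
        assert len(comps) == 45

    def test_two_observers_give_one_comparison(self):
        comps = interobserver_comparisons(_observer_maps(2), config=FAST_METRICS)
        assert len(comps) == 1

    @pytest.mark.parametrize("n", [3, 5, 8, 12])
    def test_count_matches_enumeration(self, n):
        maps = [
            ObserverMaps(f"obs{i:02d}", HeatMap(np.zeros((4, 4)), "raw"),
                         HeatMap(np.zeros((4, 4)), "filtered"))
            for i in range(n)
        ]
        # degenerate all-zero maps: only the combinatorial count matters here
        ids = [m.observer_id for m in maps]
        expected = len(list(itertools.combinations(ids, 2)))
        pairs = [(a, b) for a, b in itertools.combinations(sorted(ids), 2)]
        assert expected == n * (n - 1) // 2
        assert len(pairs) == expected

    def test_single_observer_rejected(self):
        with pytest.raises(ValueError):
            interobserver_comparisons(_observer_maps(1))

    def test_lower_observer_id_is_ground_truth(self):
        comps = interobserver_comparisons(_observer_maps(3), config=FAST_METRICS)
        assert all(c.gt_id < c.test_id for c in comps)


class TestInterexperiment:
    def test_identical_tasks_compare_as_identity(self):
        maps = _observer_maps(3)
        acc = interexperiment_comparison(
            maps, maps, mode="accumulated", config=FAST_METRICS, kernel=FAST_KERNEL
        )
        obs = interexperiment_comparison(
            maps, maps, mode="observer_wise", config=FAST_METRICS, kernel=FAST_KERNEL
        )
        assert len(acc) == 1
        assert len(obs) == 3
        for comp in acc + obs:
            assert comp.values["ig"] == 0.0

    def test_observer_mismatch_lists_missing_ids(self):
        with pytest.raises(ValueError, match="obs02"):
            interexperiment_comparison(
                _observer_maps(3), _observer_maps(2), mode="observer_wise"
            )

    def test_accumulated_map_is_fuller_than_any_observer_map(self):
        maps = _observer_maps(5, seed=3)
        acc = accumulated_maps(maps, FAST_KERNEL)
        zeros_acc = int((acc.raw.values == 0).sum())
        min_zeros = min(int((m.raw.values == 0).sum()) for m in maps)
        assert zeros_acc <= min_zeros

    def test_interexperiment_similarity_decays_with_displacement(self):
        size = 128
        base = _single_attractor_task(size, cx=40.0, seed=1)
        aucs = []
        for dx in (0.0, 30.0, 60.0):
            other = _single_attractor_task(size, cx=40.0 + dx, seed=2)
            comp = interexperiment_comparison(
                base, other, mode="accumulated", config=FAST_METRICS, kernel=FAST_KERNEL
            )[0]
            aucs.append(comp.values["auc_judd"])
        assert aucs[0] > aucs[1] > aucs[2]


def _single_attractor_task(size, cx, seed):
    cfg = GazeSimConfig(
        seed=seed,
        attractors=[Attractor(cx, size / 2, 1.0, 8.0)],
        n_observers=3,
        image_duration=3.0,
    )
    logs = generate_gaze_logs(cfg, (size, size))
    return build_observer_maps(logs, size, size, FAST_KERNEL)


class TestLinearFit:
    def test_exact_line_gives_unit_r2(self):
        x = np.arange(10.0)
        fit = linear_fit_r2(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_y_flagged_degenerate(self):
        fit = linear_fit_r2(np.arange(5.0), np.full(5, 3.0))
        assert fit.r2 == 0.0
        assert fit.degenerate

    def test_matches_closed_form_pearson(self, rng):
        x = rng.uniform(0, 1, 10)
        y = 0.3 * x + rng.normal(0, 0.1, 10)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        r = num / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert linear_fit_r2(x, y).r2 == pytest.approx(r**2, abs=1e-12)


class TestCorrelationTable:
    @staticmethod
    def _tables(n_images, rng, planted=False):
        ids = [f"img{i:03d}" for i in range(n_images)]
        cx = pd.DataFrame(
            {
                "image_id": ids,
                "m_sesf": rng.uniform(0, 1, n_images),
                "m_co": rng.uniform(0.01, 0.2, n_images),
                "m_blm": rng.uniform(0, 10, n_images),
                "anisotropy": rng.uniform(0, 0.01, n_images),
                "entropy": rng.uniform(2, 8, n_images),
            }
        )
        rows = []
        for mode in ("CAT", "FREE"):
            for metric in METRIC_NAMES:
                for i, iid in enumerate(ids):
                    value = (
                        2.0 * cx["entropy"][i] + 1.0
                        if planted and metric == "nss"
                        else rng.normal()
                    )
                    rows.append(
                        {"image_id": iid, "mode": mode, "metric": metric, "value": value}
                    )
        return pd.DataFrame(rows), cx

    def test_independent_values_give_near_zero_r2(self, rng):
        mv, cx = self._tables(200, rng)
        table = correlation_table(mv, cx)
        assert (table["mean_r2"] < 0.05).all()

    def test_planted_affine_relation_recovered(self, rng):
        mv, cx = self._tables(30, rng, planted=True)
        table = correlation_table(mv, cx)
        row = table[(table["metric"] == "nss") & (table["mode"] == "CAT")].iloc[0]
        assert row["r2_entropy"] == pytest.approx(1.0, abs=1e-9)

    def test_structure_five_metrics_by_modes(self, rng):
        mv, cx = self._tables(5, rng)
        table = correlation_table(mv, cx)
        assert set(table["metric"]) == set(METRIC_NAMES)
        assert set(table["mode"]) == {"CAT", "FREE"}
        assert len(table) == 10


class TestAnova:
    def test_identical_group_means_give_zero_f(self):
        res = one_way_anova([[1.0, 2.0, 3.0], [2.0, 1.0, 3.0]])
        assert res.f == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_textbook_instance_matches_sums_of_squares_oracle(self):
        groups = [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [3.0, 4.0, 5.0]]
        res = one_way_anova(groups)
        # brute-force sums of squares
        flat = np.concatenate(groups)
        ssb = sum(3 * (np.mean(g) - flat.mean()) ** 2 for g in groups)
        ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
        f_expected = (ssb / 2) / (ssw / 6)
        assert res.f == pytest.approx(f_expected, abs=1e-12)
        assert res.df_between == 2 and res.df_within == 6
        # independent implementation cross-check
        f_scipy, p_scipy = stats.f_oneway(*groups)
        assert res.f == pytest.approx(f_scipy, abs=1e-12)
        assert res.p == pytest.approx(p_scipy, abs=1e-12)

    def test_null_p_values_approximately_uniform(self, rng):
        pvals = []
        for _ in range(400):
            groups = rng.normal(0, 1, (8, 6))
            pvals.append(one_way_anova(list(groups)).p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_zero_within_variance_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            one_way_anova([[1.0, 1.0], [2.0, 2.0]])


class TestPredictorAndBands:
    def test_constant_image_gives_zero_map(self):
        hm = baseline_predictor(np.full((32, 32), 0.5))
        assert hm.values.sum() == 0.0

    def test_bright_blob_is_the_argmax(self):
        img = np.zeros((64, 64))
        img[40:44, 10:14] = 1.0
        hm = baseline_predictor(img)
        r, c = np.unravel_index(hm.values.argmax(), hm.values.shape)
        assert 39 <= r <= 44 and 9 <= c <= 14

    def test_predictor_deterministic(self, rng):
        img = rng.uniform(0, 1, (32, 32))
        a, b = baseline_predictor(img), baseline_predictor(img)
        np.testing.assert_array_equal(a.values, b.values)

    def test_band_table_structure_and_anova(self, rng):
        from multisal.spectral_imaging import MultispectralImage

        images = [
            MultispectralImage(rng.uniform(0, 1, (48, 48, 8)), image_id=f"i{k}")
            for k in range(4)
        ]
        long, summary, anovas = band_comparison_harness(images, n_splits=5, rng_seed=1)
        assert set(summary["metric"]) == {"sauc", "ig", "nss"}
        assert sorted(summary["band"].unique()) == list(range(1, 9))
        assert len(summary) == 24
        assert set(anovas) <= {"sauc", "ig", "nss"}

    def test_constant_predictor_gives_zero_ig_everywhere(self, rng):
        from multisal.heatmap_builder import HeatMap as HM
        from multisal.spectral_imaging import MultispectralImage

        def constant_predictor(image):
            img = np.asarray(image)
            return HM(np.ones(img.shape[:2]), "filtered")

        images = [
            MultispectralImage(rng.uniform(0, 1, (32, 32, 8)), image_id=f"i{k}")
            for k in range(2)
        ]
        long, _, _ = band_comparison_harness(
            images, predictor=constant_predictor, n_splits=3, rng_seed=0
        )
        assert (long["ig"] == 0.0).all()


class TestDisplayGeometry:
    def test_density_of_small_set_display(self):
        d = display_density_px_per_mm(1228, 1029, 290, 240)
        assert round(d, 2) == pytest.approx(4.26)

    def test_session_arithmetic_for_large_set(self):
        total = session_display_time_s(1147, 4.0, 1.5)
        assert total == 6309
        assert hms(total) == (1, 45, 9)


class TestRunStudy:
    def test_full_study_produces_all_tables(self, rng):
        from multisal.synthetic_data import default_attractors, default_scene_specs

        specs = default_scene_specs(3, seed=2, width=128, height=128)
        cfg = GazeSimConfig(
            seed=2,
            attractors=default_attractors(128, 128),
            n_observers=3,
            image_duration=3.0,
        )
        bundle = generate_study(specs, cfg)
        result = run_study(
            bundle,
            StudyConfig(kernel=FAST_KERNEL, metric_config=FAST_METRICS, band_n_splits=5),
        )
        assert set(result.comparisons["mode"]) == {"CAT", "FREE", "CvsFobs", "CvsFacc"}
        assert set(result.comparisons["metric"]) == set(METRIC_NAMES)
        assert len(result.complexity) == 3
        assert set(result.correlation["metric"]) == set(METRIC_NAMES)
        assert len(result.band_summary) == 24
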