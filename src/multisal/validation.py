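"""Seeded validation experiments on synthetic data.

These are the package's calibration checks, each a small self-contained
experiment returning numbers with known expected behaviour:

* chance calibration — random maps scored against random fixations must
  sit at the chance level of each metric (AUC 0.5, NSS 0, IG 0);
* mass conservation — the filtered heat map of interior fixations must
  carry exactly the total fixation time;
* attractor recovery — the peak of the accumulated filtered map must
  land near the planted dominant attractor;
* independence null — when gaze is simulated independently of scene
  content, heat-map comparison metrics must not correlate with image
  complexity (all mean r-squared near zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .complexity_metrics import score_image
from .fixation_processing import fixations_from_log
from .heatmap_builder import (
    GaussianKernelSpec,
    HeatMap,
    accumulate_maps,
    build_delta_map,
    smooth_map,
)
from .saliency_metrics import (
    FixationPointSet,
    MetricConfig,
    auc_borji,
    auc_judd,
    compare_pair,
    information_gain,
    map_to_fixations,
    nss,
    shuffled_auc,
)
from .spectral_imaging import render_rgb
from .study_analysis import accumulated_argmax, build_observer_maps, correlation_table
from .synthetic_data import (
    Attractor,
    GazeSimConfig,
    default_scene_specs,
    generate_gaze_logs,
    generate_scene,
)


def chance_calibration(
    seed: int = 0,
    n_trials: int = 20,
    size: int = 128,
    n_fixations: int = 200,
) -> dict[str, float]:
    """Mean metric values for i.i.d. uniform maps and random fixations.

    Expected: every AUC variant near 0.5, NSS and IG near 0.
    """
    rng = np.random.default_rng(seed)
    out = {"auc_judd": [], "auc_borji": [], "sauc": [], "nss": [], "ig": []}
    for _ in range(n_trials):
        test = HeatMap(rng.uniform(0, 1, (size, size)), "filtered")
        baseline = HeatMap(rng.uniform(0, 1, (size, size)), "filtered")
        pts = FixationPointSet(
            points=np.stack(
                [rng.integers(0, size, n_fixations), rng.integers(0, size, n_fixations)],
                axis=1,
            ).astype(float)
        )
        pool = FixationPointSet(
            points=np.stack(
                [rng.integers(0, size, 5 * n_fixations), rng.integers(0, size, 5 * n_fixations)],
                axis=1,
            ).astype(float)
        )
        out["auc_judd"].append(auc_judd(test, pts))
        out["auc_borji"].append(auc_borji(test, pts, n_splits=10, rng_seed=rng))
        out["sauc"].append(shuffled_auc(test, pts, pool, n_splits=10, rng_seed=rng))
        out["nss"].append(nss(test, pts))
        out["ig"].append(information_gain(test, baseline, pts))
    return {k: float(np.mean(v)) for k, v in out.items()}


def mass_conservation_error(seed: int = 0, size: int = 256, n_fixations: int = 40) -> float:
    """Relative error between filtered-map mass and total fixation time.

    Fixations are placed at least one kernel radius from every border, so
    with a unit-sum kernel and zero padding the mass must be conserved.
    """
    kernel = GaussianKernelSpec()
    rng = np.random.default_rng(seed)
    margin = kernel.radius
    from .fixation_processing import Fixation

    fixations = [
        Fixation(
            x=float(rng.uniform(margin, size - margin)),
            y=float(rng.uniform(margin, size - margin)),
            duration=float(rng.uniform(0.1, 0.5)),
        )
        for _ in range(n_fixations)
    ]
    raw = build_delta_map(fixations, size + 2 * margin, size + 2 * margin)
    filtered = smooth_map(raw, kernel)
    total = sum(f.duration for f in fixations)
    return abs(filtered.values.sum() - total) / total


@dataclass
class RecoveryConditions:
    """Conditions for the attractor-recovery experiment."""

    n_observers: int = 5
    size: int = 192
    spread_px: float = 20.0
    dropout: float = 0.05
    dominant_weight: float = 0.6
    tolerance_px: float = 40.0  # 2 kernel sigmas


def attractor_recovery_rate(
    n_runs: int = 100,
    seed: int = 0,
    conditions: RecoveryConditions | None = None,
    kernel: GaussianKernelSpec | None = None,
) -> float:
    """Fraction of runs whose accumulated-map peak lands on the attractor.

    Each run simulates ``n_observers`` viewing one image with a dominant
    attractor; success means the argmax of the accumulated filtered map
    lies within ``tolerance_px`` of it.
    """
    c = conditions or RecoveryConditions()
    kernel = kernel or GaussianKernelSpec()
    size = c.size
    hits = 0
    for run in range(n_runs):
        run_seed = (seed * 100_003 + run) % (2**31 - 1)
        rng = np.random.default_rng(run_seed)
        dominant = Attractor(
            float(rng.uniform(60, size - 60)),
            float(rng.uniform(60, size - 60)),
            c.dominant_weight,
            c.spread_px,
        )
        others = [
            Attractor(
                float(rng.uniform(20, size - 20)),
                float(rng.uniform(20, size - 20)),
                (1 - c.dominant_weight) / 2,
                c.spread_px,
            )
            for _ in range(2)
        ]
        cfg = GazeSimConfig(
            seed=run_seed,
            attractors=[dominant, *others],
            n_observers=c.n_observers,
            validity_dropout_rate=c.dropout,
        )
        logs = generate_gaze_logs(cfg, (size, size))
        x, y = accumulated_argmax(logs, size, size, kernel)
        if np.hypot(x - dominant.x, y - dominant.y) <= c.tolerance_px:
            hits += 1
    return hits / n_runs


def independence_null(
    n_images: int = 200,
    seed: int = 0,
    size: int = 96,
    n_observers: int = 2,
    kernel: GaussianKernelSpec | None = None,
    metric_config: MetricConfig | None = None,
) -> pd.DataFrame:
    """Correlation table for complexity-independent gaze on many scenes.

    Scenes vary in complexity; gaze attractors are drawn independently of
    scene content, so every (metric, complexity) correlation is spurious
    and the mean r-squared values must be near zero.
    """
    kernel = kernel or GaussianKernelSpec(radius=60, sigma=20.0)
    metric_config = metric_config or MetricConfig(n_splits=10)
    # the gaze stream must be independent of the scene stream, or the
    # "null" would be contaminated by their shared draws
    rng = np.random.default_rng([seed, 17])
    specs = default_scene_specs(n_images, seed, width=size, height=size)

    complexity_rows = []
    metric_rows = []
    fixation_sets: dict[str, FixationPointSet] = {}
    maps_per_image = {}
    for i, spec in enumerate(specs):
        image_id = f"img{i:03d}"
        scene = generate_scene(spec, image_id=image_id)
        scores = score_image(render_rgb(scene).as_float())
        complexity_rows.append({"image_id": image_id, **scores.as_dict()})
        # gaze independent of the scene: attractor positions are random
        attractors = [
            Attractor(float(rng.uniform(10, size - 10)), float(rng.uniform(10, size - 10)), w, 10.0)
            for w in (0.6, 0.4)
        ]
        cfg = GazeSimConfig(
            seed=int(rng.integers(0, 2**31 - 1)),
            attractors=attractors,
            n_observers=n_observers,
            image_duration=4.0,
        )
        logs = generate_gaze_logs(cfg, (size, size), image_id=image_id)
        oms = build_observer_maps(logs, size, size, kernel)
        maps_per_image[image_id] = oms
        fixation_sets[image_id] = map_to_fixations(accumulate_maps([m.raw for m in oms]))

    for image_id, oms in maps_per_image.items():
        pool_pts = [
            f.points for iid, f in fixation_sets.items() if iid != image_id and len(f)
        ]
        pool = FixationPointSet(points=np.concatenate(pool_pts)) if pool_pts else None
        a, b = oms[0], oms[1]
        comp = compare_pair(
            a.raw, a.filtered, b.raw, b.filtered,
            negative_pool=pool, config=metric_config,
            gt_id=a.observer_id, test_id=b.observer_id,
        )
        for metric, value in comp.values.items():
            metric_rows.append(
                {"image_id": image_id, "mode": "FREE", "metric": metric, "value": value}
            )

    return correlation_table(pd.DataFrame(metric_rows), pd.DataFrame(complexity_rows))
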