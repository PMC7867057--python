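"""Inter-observer and inter-experiment heat-map comparisons.

For every scene: all 45 observer pairs within each task (CAT, FREE), the
accumulated-map comparison between tasks (CvsFacc), and the observer-wise
between-task comparison (CvsFobs).  Each comparison yields the five
metrics (NSS, AUC-Judd, AUC-Borji, shuffled AUC, IG); shuffled-AUC
negatives are pooled from the other scenes' fixations.  Writes the
per-image metric means to results/comparisons.csv and prints the
per-mode averages (the bar-chart summary of the study).
"""

import json
from pathlib import Path

import pandas as pd

from multisal.gaze_io import read_gaze_log
from multisal.heatmap_builder import GaussianKernelSpec, accumulate_maps
from multisal.saliency_metrics import MetricConfig, map_to_fixations
from multisal.study_analysis import (
    build_observer_maps,
    interexperiment_comparison,
    interobserver_comparisons,
    mean_metric_values,
)
from multisal.spectral_imaging import load_cube
import numpy as np

from multisal.saliency_metrics import FixationPointSet

RESULTS = Path(__file__).resolve().parent.parent / "results"
KERNEL = GaussianKernelSpec(radius=100, sigma=20.0)
METRICS = MetricConfig(n_splits=20, rng_seed=7)


def main() -> None:
    study = RESULTS / "study"
    manifest_path = study / "manifest.json"
    if not manifest_path.exists():
        raise SystemExit("run analysis/01_simulate_study.py first")
    manifest = json.loads(manifest_path.read_text())

    maps = {}
    fix_sets = {}
    for entry in manifest["logs"]:
        key = (entry["image_id"], entry["task"])
        maps.setdefault(key, []).append(read_gaze_log(study / entry["file"]))
    for key, logs in maps.items():
        h, w = load_cube(study / f"{key[0]}.tif").shape
        maps[key] = build_observer_maps(logs, w, h, KERNEL)
        fix_sets[key] = map_to_fixations(accumulate_maps([m.raw for m in maps[key]]))

    image_ids = manifest["image_ids"]
    rows = []
    for image_id in image_ids:
        pool_pts = [
            f.points
            for (iid, task), f in fix_sets.items()
            if iid != image_id and task == "free" and len(f)
        ]
        pool = FixationPointSet(points=np.concatenate(pool_pts)) if pool_pts else None
        for task, mode in (("categorization", "CAT"), ("free", "FREE")):
            comps = interobserver_comparisons(maps[(image_id, task)], pool, METRICS)
            for metric, value in mean_metric_values(comps).items():
                rows.append({"image_id": image_id, "mode": mode, "metric": metric,
                             "value": value, "n_pairs": len(comps)})
        for mode_name, mode in (("observer_wise", "CvsFobs"), ("accumulated", "CvsFacc")):
            comps = interexperiment_comparison(
                maps[(image_id, "categorization")], maps[(image_id, "free")],
                mode=mode_name, negative_pool=pool, config=METRICS, kernel=KERNEL,
            )
            for metric, value in mean_metric_values(comps).items():
                rows.append({"image_id": image_id, "mode": mode, "metric": metric,
                             "value": value, "n_pairs": len(comps)})

    df = pd.DataFrame(rows)
    out = RESULTS / "comparisons.csv"
    df.to_csv(out, index=False)
    print(f"wrote {len(df)} per-image metric means to {out}")
    summary = df.pivot_table(index="metric", columns="mode", values="value")
    print("\nmean metric value per comparison mode (higher = more similar):")
    print(summary.round(3).to_string())


if __name__ == "__main__":
    main()
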