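"""Build per-observer and accumulated heat maps from the simulated logs.

Reads the TSV gaze logs written by 01_simulate_study.py, runs the fixation
pipeline (event durations -> fixation filter -> validity filter ->
binocular mean), places duration-weighted deltas and smooths them with the
R = 100 px, sigma = 20 px Gaussian.  Writes raw and filtered maps (float32
TIFF) plus one overlay PNG per scene under results/heatmaps/.
"""

import json
from pathlib import Path

from multisal.gaze_io import read_gaze_log
from multisal.heatmap_builder import GaussianKernelSpec, accumulate_maps, smooth_map
from multisal.heatmap_io import render_overlay, save_heatmap
from multisal.spectral_imaging import load_cube, render_rgb
from multisal.study_analysis import build_observer_maps

RESULTS = Path(__file__).resolve().parent.parent / "results"
KERNEL = GaussianKernelSpec(radius=100, sigma=20.0)


def main() -> None:
    study = RESULTS / "study"
    manifest_path = study / "manifest.json"
    if not manifest_path.exists():
        raise SystemExit("run analysis/01_simulate_study.py first")
    manifest = json.loads(manifest_path.read_text())
    outdir = RESULTS / "heatmaps"
    outdir.mkdir(parents=True, exist_ok=True)

    by_key: dict[tuple[str, str], list] = {}
    for entry in manifest["logs"]:
        log = read_gaze_log(study / entry["file"])
        by_key.setdefault((entry["image_id"], entry["task"]), []).append(log)

    n_maps = 0
    for (image_id, task), logs in sorted(by_key.items()):
        cube = load_cube(study / f"{image_id}.tif")
        h, w = cube.shape
        oms = build_observer_maps(logs, w, h, KERNEL)
        for m in oms:
            save_heatmap(m.raw, outdir / f"{image_id}_{task}_{m.observer_id}_raw.tif")
            save_heatmap(m.filtered, outdir / f"{image_id}_{task}_{m.observer_id}_filtered.tif")
            n_maps += 2
        acc = accumulate_maps([m.raw for m in oms])
        acc_filtered = smooth_map(acc, KERNEL)
        save_heatmap(acc, outdir / f"{image_id}_{task}_accumulated_raw.tif")
        save_heatmap(acc_filtered, outdir / f"{image_id}_{task}_accumulated_filtered.tif")
        n_maps += 2
        if task == "free":
            render_overlay(
                acc_filtered,
                render_rgb(cube).pixels,
                outdir / f"{image_id}_{task}_overlay.png",
            )
        total_time = acc.values.sum()
        print(f"{image_id}/{task}: {len(oms)} observers, "
              f"accumulated fixation time {total_time:.1f} s")
    print(f"wrote {n_maps} heat maps to {outdir}")


if __name__ == "__main__":
    main()
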