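"""Synthetic scenes and gaze logs with known ground truth.

The generator emulates the two ingredients of a gaze-recording study so
the whole pipeline is testable without recorded data:

* **scenes** — 8-band multispectral cubes built from rectangular regions,
  each with a per-band mean intensity profile and i.i.d. Gaussian texture
  noise.  A "vegetation"-like region is simply one whose NIR bands (7-8)
  are brighter than its visible bands, mimicking the chlorophyll
  reflectance rise.
* **gaze logs** — binocular sample streams at 60 Hz alternating fixation
  and saccade events.  Fixations land on Gaussian "attractors" (known
  ground-truth salient spots) chosen by weight; the two eyes sit at the
  true gaze point plus/minus half a Gaussian binocular offset, so their
  mean recovers the true point exactly.  A configurable fraction of
  fixation samples is flagged invalid (tracking dropouts), and an
  optional fraction of fixations is placed off-screen to exercise bounds
  handling downstream.

Everything is driven by integer seeds: the same seed reproduces the same
bundle bit for bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .gaze_io import GazeLog, write_gaze_log
from .spectral_imaging import DEFAULT_BAND_META, N_BANDS, MultispectralImage, save_cube

TASKS = ("free", "categorization")


@dataclass
class Region:
    """Axis-aligned rectangle [x0, x1) x [y0, y1) with a band profile."""

    x0: int
    y0: int
    x1: int
    y1: int
    band_means: tuple[float, ...]
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError("region has zero area")
        if len(self.band_means) != N_BANDS:
            raise ValueError(f"band_means must have {N_BANDS} entries")
        if min(self.band_means) < 0 or max(self.band_means) > 1:
            raise ValueError("band means must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SceneSpec:
    """Recipe for one synthetic multispectral scene."""

    seed: int
    width: int
    height: int
    regions: list[Region]
    band_meta: tuple[tuple[float, float], ...] = DEFAULT_BAND_META

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("scene dimensions must be positive")
        if len(self.band_meta) != N_BANDS:
            raise ValueError(f"band_meta must list {N_BANDS} bands")


@dataclass
class Attractor:
    """A Gaussian gaze attractor: location, selection weight, spread (px)."""

    x: float
    y: float
    weight: float
    spread: float = 20.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("attractor weight must be >= 0")
        if self.spread < 0:
            raise ValueError("attractor spread must be >= 0")


@dataclass
class GazeSimConfig:
    """Study conditions for the gaze simulator.

    Defaults follow the recording setup being emulated: 60 Hz binocular
    sampling, 6 s display per image, fixations of 150-400 ms and saccades
    of 20-80 ms (typical scene-viewing magnitudes, drawn uniformly), a
    2 px binocular offset SD and a 5% validity dropout rate.
    """

    seed: int
    attractors: list[Attractor]
    n_observers: int = 10
    sampling_rate: float = 60.0
    image_duration: float = 6.0
    fixation_duration_range: tuple[float, float] = (0.15, 0.40)
    saccade_duration_range: tuple[float, float] = (0.02, 0.08)
    binocular_offset_sd: float = 2.0
    validity_dropout_rate: float = 0.05
    offscreen_fraction: float = 0.0  # fraction of fixations placed off-image

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not 0.0 <= self.validity_dropout_rate <= 1.0:
            raise ValueError("validity_dropout_rate must lie in [0, 1]")
        if not 0.0 <= self.offscreen_fraction <= 1.0:
            raise ValueError("offscreen_fraction must lie in [0, 1]")
        if not self.attractors:
            raise ValueError("need at least one attractor")
        total = sum(a.weight for a in self.attractors)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"attractor weights must sum to 1, got {total}")


def generate_scene(spec: SceneSpec, image_id: str = "") -> MultispectralImage:
    """Paint the regions in order (later regions win on overlap) plus noise.

    Pixels covered by no region are 0 in every band.  All values are
    clipped to [0, 1].  Region rectangles are recorded in the image
    metadata so masks are recoverable.
    """
    rng = np.random.default_rng(spec.seed)
    cube = np.zeros((spec.height, spec.width, N_BANDS), dtype=np.float64)
    for region in spec.regions:
        x0, x1 = max(0, region.x0), min(spec.width, region.x1)
        y0, y1 = max(0, region.y0), min(spec.height, region.y1)
        if x1 <= x0 or y1 <= y0:
            raise ValueError("region lies outside the scene")
        block = np.tile(np.asarray(region.band_means), (y1 - y0, x1 - x0, 1))
        if region.noise_sd > 0:
            block = block + rng.normal(0.0, region.noise_sd, size=block.shape)
        cube[y0:y1, x0:x1, :] = block
    cube = np.clip(cube, 0.0, 1.0)
    meta = {
        "seed": spec.seed,
        "regions": [
            {
                "x0": r.x0,
                "y0": r.y0,
                "x1": r.x1,
                "y1": r.y1,
                "band_means": list(r.band_means),
                "noise_sd": r.noise_sd,
            }
            for r in spec.regions
        ],
    }
    return MultispectralImage(cube=cube, band_meta=spec.band_meta, image_id=image_id, meta=meta)


def _round2(x: float) -> float:
    # positions/timestamps are stored to 0.01 in the TSV dialect; rounding
    # here keeps in-memory logs identical to their round-tripped files
    return round(x, 2)


def _build_timeline(
    cfg: GazeSimConfig, image_size: tuple[int, int], rng: np.random.Generator
) -> list[list]:
    """Alternating fixation/saccade events: [movement, start_s, end_s, pos]."""
    width, height = image_size
    events: list[list] = []
    t = 0.0
    fixating = True
    prev_fix_pos: np.ndarray | None = None
    weights = np.array([a.weight for a in cfg.attractors])
    while t < cfg.image_duration:
        if fixating:
            dur = rng.uniform(*cfg.fixation_duration_range)
            a = cfg.attractors[int(rng.choice(len(cfg.attractors), p=weights))]
            pos = np.array([a.x, a.y]) + rng.normal(0.0, a.spread, size=2)
            if cfg.offscreen_fraction > 0 and rng.random() < cfg.offscreen_fraction:
                pos = np.array([width + 50.0, height + 50.0])
            else:
                pos = np.clip(pos, 0.0, [width - 1.0, height - 1.0])
            events.append(["fixation", t, min(t + dur, cfg.image_duration), pos])
            prev_fix_pos = pos
        else:
            dur = rng.uniform(*cfg.saccade_duration_range)
            events.append(["saccade", t, min(t + dur, cfg.image_duration), prev_fix_pos])
        t += dur
        fixating = not fixating

    # saccade positions: midpoint between the neighbouring fixations
    for k, ev in enumerate(events):
        if ev[0] == "saccade":
            nxt = events[k + 1][3] if k + 1 < len(events) else ev[3]
            ev[3] = (ev[3] + nxt) / 2.0
    return events


def simulate_event_timeline(
    cfg: GazeSimConfig, image_size: tuple[int, int], observer_index: int = 0
) -> list[list]:
    """Ground-truth event timeline for one observer.

    Uses the same seed stream as :func:`generate_gaze_log`, so the
    returned events are exactly those underlying the observer's samples.
    """
    rng = np.random.default_rng([cfg.seed, observer_index])
    return _build_timeline(cfg, image_size, rng)


def generate_gaze_log(
    cfg: GazeSimConfig,
    image_size: tuple[int, int],
    observer_index: int = 0,
    observer_id: str | None = None,
    image_id: str = "",
    task: str = "free",
) -> GazeLog:
    """One observer's binocular sample stream for one image.

    The event timeline alternates fixation and saccade events (durations
    uniform in their configured ranges) until the display time is
    exhausted; samples are then read off the timeline at the sampling
    rate.  Fixation samples repeat the event's position exactly; saccade
    samples interpolate linearly between the surrounding fixations.
    """
    width, height = image_size
    if width <= 0 or height <= 0:
        raise ValueError("image size must be positive")
    rng = np.random.default_rng([cfg.seed, observer_index])
    events = _build_timeline(cfg, image_size, rng)

    # --- samples --------------------------------------------------------
    dt_ms = 1000.0 / cfg.sampling_rate
    n_samples = int(math.floor(cfg.image_duration * cfg.sampling_rate))
    rows = []
    ev_idx = 0
    offsets = {}  # per-event binocular offset, drawn once per event
    for i in range(n_samples):
        t_s = i / cfg.sampling_rate
        while ev_idx + 1 < len(events) and t_s >= events[ev_idx][2]:
            ev_idx += 1
        movement, _, _, pos = events[ev_idx]
        if ev_idx not in offsets:
            offsets[ev_idx] = rng.normal(0.0, cfg.binocular_offset_sd, size=2)
        off = offsets[ev_idx]
        left = pos - off / 2.0
        right = pos + off / 2.0
        validity = 1
        if movement == "fixation" and rng.random() < cfg.validity_dropout_rate:
            validity = 0
        rows.append(
            {
                "timestamp_ms": _round2(i * dt_ms),
                "left_x": _round2(left[0]),
                "left_y": _round2(left[1]),
                "right_x": _round2(right[0]),
                "right_y": _round2(right[1]),
                "movement": movement,
                "validity": validity,
                "pupil_left": 3.0,
                "pupil_right": 3.0,
                "distance_mm": 600.0,
            }
        )
    samples = pd.DataFrame(rows)
    return GazeLog(
        observer_id=observer_id or f"obs{observer_index:02d}",
        image_id=image_id,
        task=task,
        samples=samples,
    )


def generate_gaze_logs(cfg: GazeSimConfig, image_size: tuple[int, int], image_id: str = "", task: str = "free") -> list[GazeLog]:
    """One log per observer (observer i uses the seed stream (seed, i))."""
    return [
        generate_gaze_log(cfg, image_size, observer_index=i, image_id=image_id, task=task)
        for i in range(cfg.n_observers)
    ]


@dataclass
class StudyBundle:
    """A complete synthetic study: images plus per-task, per-observer logs."""

    images: list[MultispectralImage]
    logs: dict[str, dict[str, list[GazeLog]]]  # task -> image_id -> logs
    attractors: dict[str, dict[str, list[Attractor]]]  # task -> image_id -> truth
    manifest: dict = field(default_factory=dict)

    @property
    def image_ids(self) -> list[str]:
        return [im.image_id for im in self.images]


def _task_attractors(attractors: list[Attractor], task: str) -> list[Attractor]:
    """Tasks share attractor locations but weight them differently.

    The categorization task reverses the free-viewing weight order (and
    renormalizes), a simple deterministic way of shifting emphasis
    between the same candidate targets.
    """
    if task == "free":
        return list(attractors)
    weights = [a.weight for a in reversed(attractors)]
    total = sum(weights)
    return [replace(a, weight=w / total) for a, w in zip(attractors, weights)]


def generate_study(scene_specs: list[SceneSpec], cfg: GazeSimConfig) -> StudyBundle:
    """Images plus ``free`` and ``categorization`` log sets for each image."""
    if not scene_specs:
        raise ValueError("need at least one scene")
    if cfg.n_observers < 2:
        raise ValueError("need >= 2 observers for pairwise analysis")
    images = [
        generate_scene(spec, image_id=f"img{i:03d}") for i, spec in enumerate(scene_specs)
    ]
    logs: dict[str, dict[str, list[GazeLog]]] = {t: {} for t in TASKS}
    attractors: dict[str, dict[str, list[Attractor]]] = {t: {} for t in TASKS}
    for i, image in enumerate(images):
        size = (image.shape[1], image.shape[0])
        for t_idx, task in enumerate(TASKS):
            task_attr = _task_attractors(cfg.attractors, task)
            task_cfg = replace(cfg, attractors=task_attr, seed=cfg.seed + 1000 * i + 500 * t_idx)
            logs[task][image.image_id] = generate_gaze_logs(
                task_cfg, size, image_id=image.image_id, task=task
            )
            attractors[task][image.image_id] = task_attr
    manifest = {
        "n_images": len(images),
        "n_observers": cfg.n_observers,
        "tasks": list(TASKS),
        "seed": cfg.seed,
        "image_ids": [im.image_id for im in images],
    }
    return StudyBundle(images=images, logs=logs, attractors=attractors, manifest=manifest)


def write_study(bundle: StudyBundle, outdir: str | Path) -> Path:
    """Persist a bundle: TIFF cubes + sidecars, TSV logs, JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for image in bundle.images:
        save_cube(image, outdir / f"{image.image_id}.tif")
    entries = []
    for task, per_image in bundle.logs.items():
        for image_id, logs in per_image.items():
            for log in logs:
                name = f"{image_id}_{task}_{log.observer_id}.tsv"
                write_gaze_log(log, outdir / name)
                entries.append(
                    {"image_id": image_id, "task": task, "observer_id": log.observer_id, "file": name}
                )
    manifest = dict(bundle.manifest)
    manifest["logs"] = entries
    manifest["attractors"] = {
        task: {
            image_id: [
                {"x": a.x, "y": a.y, "weight": a.weight, "spread": a.spread} for a in attrs
            ]
            for image_id, attrs in per_image.items()
        }
        for task, per_image in bundle.attractors.items()
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def default_scene_specs(
    n_scenes: int,
    seed: int,
    width: int = 192,
    height: int = 192,
    noise_sd: float = 0.05,
) -> list[SceneSpec]:
    """Convenience recipes: background + 2 material regions per scene.

    Each scene has a full-frame background, one "built"-like region
    (flat-ish visible profile) and one "vegetation"-like region whose
    NIR bands 7-8 are elevated above its visible bands.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for s in range(n_scenes):
        bg = tuple(np.round(rng.uniform(0.2, 0.5, size=N_BANDS), 3))
        built = tuple(np.round(rng.uniform(0.4, 0.8, size=N_BANDS), 3))
        veg_vis = rng.uniform(0.1, 0.3, size=6)
        veg_nir = rng.uniform(0.6, 0.9, size=2)
        veg = tuple(np.round(np.concatenate([veg_vis, veg_nir]), 3))
        w3, h3 = width // 3, height // 3
        specs.append(
            SceneSpec(
                seed=int(rng.integers(0, 2**31 - 1)),
                width=width,
                height=height,
                regions=[
                    Region(0, 0, width, height, bg, noise_sd),
                    Region(w3 // 2, h3 // 2, w3 // 2 + w3, h3 // 2 + h3, built, noise_sd),
                    Region(width - w3 - w3 // 2, height - h3 - h3 // 2, width - w3 // 2, height - h3 // 2, veg, noise_sd),
                ],
            )
        )
    return specs


def default_attractors(width: int, height: int, spread: float = 20.0) -> list[Attractor]:
    """Three attractors: dominant center, two weaker corners."""
    return [
        Attractor(width * 0.5, height * 0.5, 0.6, spread),
        Attractor(width * 0.25, height * 0.3, 0.25, spread),
        Attractor(width * 0.75, height * 0.7, 0.15, spread),
    ]
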