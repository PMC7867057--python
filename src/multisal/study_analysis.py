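"""Study-level analyses over heat maps: inter-observer and inter-experiment
comparisons, complexity correlation, and per-band saliency prediction.

Three desk-scale experiments are orchestrated here:

1. **inter-observer** — within one task, every unordered pair of the n
   observers' maps is compared (n(n-1)/2 pairs; the lower observer id is
   the ground truth), and per-image metric means are reported;
2. **inter-experiment** — the two tasks are compared per image, either on
   the accumulated maps (one comparison per image, "C vs Facc") or
   observer-wise ("C vs Fobs": one comparison per observer per image,
   plus the per-image mean);
3. **complexity correlation** — for every (heat-map metric, complexity
   metric) pair, per-image metric values are regressed linearly on the
   complexity scores and the r-squared collected into a table whose cells
   hold the mean and SD of r-squared across the five complexity metrics;
4. **band comparison** — a saliency predictor runs on the RGB rendering
   and on each of the 8 spectral bands; each band map is scored against
   the RGB map (sAUC, IG, NSS) and a one-way ANOVA across the 8 band
   groups tests whether the bands differ.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .fixation_processing import fixations_from_log
from .heatmap_builder import (
    GaussianKernelSpec,
    HeatMap,
    accumulate_maps,
    build_delta_map,
    smooth_map,
)
from .saliency_metrics import (
    METRIC_NAMES,
    FixationPointSet,
    MetricConfig,
    PairComparison,
    compare_pair,
    dense_map_to_fixations,
    information_gain,
    map_to_fixations,
    nss,
    shuffled_auc,
)
from .spectral_imaging import MultispectralImage, extract_band, render_rgb
from .synthetic_data import StudyBundle

COMPLEXITY_METRICS = ("m_sesf", "m_co", "m_blm", "anisotropy", "entropy")
COMPARISON_MODES = ("CvsFobs", "CvsFacc", "CAT", "FREE")


# ---------------------------------------------------------------------------
# display geometry / session arithmetic
# ---------------------------------------------------------------------------

def display_density_px_per_mm(
    width_px: float, height_px: float, width_mm: float, height_mm: float
) -> float:
    """Mean of the horizontal and vertical display densities (px/mm)."""
    if min(width_px, height_px, width_mm, height_mm) <= 0:
        raise ValueError("dimensions must be positive")
    return (width_px / width_mm + height_px / height_mm) / 2.0


def session_display_time_s(n_images: int, display_s: float, interstimulus_s: float) -> int:
    """Total display time of a session, rounded half-up to whole seconds."""
    if n_images < 0:
        raise ValueError("n_images must be >= 0")
    total = n_images * (display_s + interstimulus_s)
    return int(math.floor(total + 0.5))


def hms(seconds: int) -> tuple[int, int, int]:
    """Whole seconds -> (hours, minutes, seconds)."""
    return seconds // 3600, (seconds % 3600) // 60, seconds % 60


# ---------------------------------------------------------------------------
# map construction per observer / accumulated
# ---------------------------------------------------------------------------

@dataclass
class ObserverMaps:
    """Raw + filtered map pair for one observer (or the accumulation)."""

    observer_id: str
    raw: HeatMap
    filtered: HeatMap


def build_observer_maps(
    logs,
    width: int,
    height: int,
    kernel: GaussianKernelSpec | None = None,
) -> list[ObserverMaps]:
    """Logs -> fixations -> per-observer raw and filtered heat maps."""
    kernel = kernel or GaussianKernelSpec()
    out = []
    for log in logs:
        fixations = fixations_from_log(log)
        raw = build_delta_map(fixations, width, height)
        raw.observer_ids = (log.observer_id,)
        raw.image_id, raw.task = log.image_id, log.task
        out.append(ObserverMaps(log.observer_id, raw, smooth_map(raw, kernel)))
    return out


def accumulated_maps(observer_maps: Sequence[ObserverMaps], kernel: GaussianKernelSpec | None = None) -> ObserverMaps:
    """Accumulate the raw maps across observers, then smooth (canonical order)."""
    raw = accumulate_maps([m.raw for m in observer_maps])
    return ObserverMaps("accumulated", raw, smooth_map(raw, kernel or GaussianKernelSpec()))


# ---------------------------------------------------------------------------
# inter-observer / inter-experiment comparisons
# ---------------------------------------------------------------------------

def accumulated_argmax(
    logs, width: int, height: int, kernel: GaussianKernelSpec | None = None
) -> tuple[float, float]:
    """(x, y) of the peak of the accumulated filtered heat map.

    The standard recovery check for synthetic studies: with a dominant
    attractor planted by the generator, the peak should land near it.
    """
    oms = build_observer_maps(logs, width, height, kernel)
    acc = accumulate_maps([m.raw for m in oms])
    filtered = smooth_map(acc, kernel or GaussianKernelSpec())
    row, col = np.unravel_index(np.argmax(filtered.values), filtered.shape)
    return float(col), float(row)


def interobserver_comparisons(
    observer_maps: Sequence[ObserverMaps],
    negative_pool: FixationPointSet | None = None,
    config: MetricConfig | None = None,
) -> list[PairComparison]:
    """All unordered observer pairs, lower observer id as ground truth."""
    if len(observer_maps) < 2:
        raise ValueError("need >= 2 observers for pairwise comparison")
    ordered = sorted(observer_maps, key=lambda m: m.observer_id)
    results = []
    for a, b in itertools.combinations(ordered, 2):
        results.append(
            compare_pair(
                a.raw, a.filtered, b.raw, b.filtered,
                negative_pool=negative_pool, config=config,
                gt_id=a.observer_id, test_id=b.observer_id,
            )
        )
    return results


def interexperiment_comparison(
    maps_task_a: Sequence[ObserverMaps],
    maps_task_b: Sequence[ObserverMaps],
    mode: str = "accumulated",
    negative_pool: FixationPointSet | None = None,
    config: MetricConfig | None = None,
    kernel: GaussianKernelSpec | None = None,
) -> list[PairComparison]:
    """Compare the two tasks for one image.

    ``"accumulated"``: one comparison between the accumulated maps.
    ``"observer_wise"``: each observer's task-A map against their own
    task-B map (observer sets must match).
    """
    if mode == "accumulated":
        acc_a = accumulated_maps(maps_task_a, kernel)
        acc_b = accumulated_maps(maps_task_b, kernel)
        return [
            compare_pair(
                acc_a.raw, acc_a.filtered, acc_b.raw, acc_b.filtered,
                negative_pool=negative_pool, config=config,
                gt_id="taskA_acc", test_id="taskB_acc",
            )
        ]
    if mode == "observer_wise":
        by_id_a = {m.observer_id: m for m in maps_task_a}
        by_id_b = {m.observer_id: m for m in maps_task_b}
        missing = sorted(set(by_id_a) ^ set(by_id_b))
        if missing:
            raise ValueError(f"observer sets differ between tasks: {missing}")
        results = []
        for oid in sorted(by_id_a):
            a, b = by_id_a[oid], by_id_b[oid]
            results.append(
                compare_pair(
                    a.raw, a.filtered, b.raw, b.filtered,
                    negative_pool=negative_pool, config=config,
                    gt_id=f"A:{oid}", test_id=f"B:{oid}",
                )
            )
        return results
    raise ValueError(f"unknown mode {mode!r}")


def mean_metric_values(comparisons: Sequence[PairComparison]) -> dict[str, float]:
    """Mean of each metric over a list of pair comparisons (NaNs ignored)."""
    out = {}
    for name in METRIC_NAMES:
        vals = np.array([c.values[name] for c in comparisons], dtype=float)
        vals = vals[~np.isnan(vals)]
        out[name] = float(vals.mean()) if len(vals) else float("nan")
    return out


# ---------------------------------------------------------------------------
# linear fits / correlation table / ANOVA
# ---------------------------------------------------------------------------

@dataclass
class LinearFit:
    slope: float
    intercept: float
    r2: float
    degenerate: bool = False


def linear_fit_r2(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Least-squares line and squared Pearson correlation.

    A constant x or y has no meaningful correlation: r2 is reported as 0
    with the degenerate flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return LinearFit(slope=0.0, intercept=float(np.mean(y)), r2=0.0, degenerate=True)
    fit = stats.linregress(x, y)
    return LinearFit(slope=float(fit.slope), intercept=float(fit.intercept), r2=float(fit.rvalue**2))


def correlation_table(
    metric_values: pd.DataFrame,
    complexity_scores: pd.DataFrame,
) -> pd.DataFrame:
    """Mean (SD) of r-squared per heat-map metric and comparison mode.

    ``metric_values``: long-format per-image means with columns
    ``image_id, mode, metric, value``.  ``complexity_scores``: one row
    per image_id with the five complexity metric columns.  For every
    (metric, mode, complexity metric) triple an r-squared is computed
    across images; cells aggregate mean and SD over the five complexity
    metrics.
    """
    required = {"image_id", "mode", "metric", "value"}
    if not required.issubset(metric_values.columns):
        raise ValueError(f"metric_values needs columns {sorted(required)}")
    if len(complexity_scores["image_id"].unique()) < 3:
        raise ValueError("need >= 3 images for correlation")
    rows = []
    cx = complexity_scores.set_index("image_id")
    for (metric, mode), group in metric_values.groupby(["metric", "mode"]):
        per_image = group.groupby("image_id")["value"].mean()
        ids = [i for i in per_image.index if i in cx.index]
        r2s = {}
        for cmetric in COMPLEXITY_METRICS:
            col = cx.loc[ids, cmetric].astype(float)
            ok = ~(col.isna() | per_image.loc[ids].isna())
            if ok.sum() < 3:
                continue
            r2s[cmetric] = linear_fit_r2(col[ok].to_numpy(), per_image.loc[ids][ok].to_numpy()).r2
        vals = np.array(list(r2s.values()))
        rows.append(
            {
                "metric": metric,
                "mode": mode,
                "mean_r2": float(vals.mean()) if len(vals) else float("nan"),
                "sd_r2": float(vals.std()) if len(vals) else float("nan"),
                **{f"r2_{k}": v for k, v in r2s.items()},
            }
        )
    return pd.DataFrame(rows).sort_values(["metric", "mode"]).reset_index(drop=True)


@dataclass
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int

    def __post_init__(self) -> None:
        if self.f < 0:
            raise ValueError("F must be >= 0")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA from sums of squares.

    F = (SSB / (k-1)) / (SSW / (N-k)); p from the F(k-1, N-k)
    distribution.  Zero within-group variance everywhere leaves F
    undefined and raises.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs >= 2 values")
    n_total = sum(len(a) for a in arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = n_total - len(arrays)
    if ssw <= 0:
        raise ValueError("zero within-group variance: F undefined")
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(f=float(f), p=p, df_between=df_b, df_within=df_w)


# ---------------------------------------------------------------------------
# saliency predictor + band comparison
# ---------------------------------------------------------------------------

def baseline_predictor(image: np.ndarray, blur_fraction: float = 1.0 / 6.0) -> HeatMap:
    """Deterministic local-contrast saliency map.

    Absolute difference between the grayscale image and its wide-Gaussian
    blurred version (sigma = ``blur_fraction`` x min(H, W)), min-max
    normalized to [0, 1].  A constant image yields an all-zero map.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.max() > 1.0:
        img = img / 255.0
    sigma = blur_fraction * min(img.shape)
    blurred = ndimage.gaussian_filter(img, sigma=sigma, mode="nearest")
    sal = np.abs(img - blurred)
    rng_ = sal.max() - sal.min()
    values = (sal - sal.min()) / rng_ if rng_ > 0 else np.zeros_like(sal)
    return HeatMap(values=values, variant="filtered", meta={"predictor": "local_contrast"})


BAND_METRICS = ("sauc", "ig", "nss")


def band_comparison_harness(
    ms_images: Sequence[MultispectralImage],
    predictor: Callable[[np.ndarray], HeatMap] = baseline_predictor,
    metrics: Sequence[str] = BAND_METRICS,
    top_fraction: float = 0.01,
    n_splits: int = 20,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, AnovaResult]]:
    """Per-band vs RGB saliency comparison with one-way ANOVA per metric.

    For every image the predictor produces one map from the RGB rendering
    and one from each of the 8 bands.  With the RGB map as ground truth
    (pseudo-fixations: its top ``top_fraction`` pixels), each band map is
    scored with sAUC (negative pool: pseudo-fixations of the *other*
    images), NSS, and IG.  IG follows the "RGB minus band" sign
    convention: positive means the RGB map carries more information
    about its own salient locations than the band map does.

    Returns (long per-image table, band summary with mean/sd per metric,
    ANOVA per metric across the 8 band groups).  Images on which the
    predictor fails are skipped and logged in the long table's absence.
    """
    rgb_maps: list[HeatMap] = []
    fix_sets: list[FixationPointSet] = []
    usable: list[MultispectralImage] = []
    for ms in ms_images:
        try:
            pred = predictor(render_rgb(ms).as_float())
        except Exception:  # predictor failure: skip the image
            continue
        rgb_maps.append(pred)
        fix_sets.append(dense_map_to_fixations(pred.values, top_fraction))
        usable.append(ms)

    records = []
    for i, ms in enumerate(usable):
        gt_map, gt_fix = rgb_maps[i], fix_sets[i]
        pool_points = (
            np.concatenate([f.points for j, f in enumerate(fix_sets) if j != i])
            if len(usable) > 1
            else None
        )
        pool = FixationPointSet(points=pool_points) if pool_points is not None else None
        for band in range(1, 9):
            band_map = predictor(extract_band(ms, band))
            row = {"image_id": ms.image_id or f"img{i}", "band": band}
            if "sauc" in metrics:
                row["sauc"] = (
                    shuffled_auc(band_map, gt_fix, pool, n_splits, rng_seed)
                    if pool is not None
                    else float("nan")
                )
            if "ig" in metrics:
                # RGB-minus-band: information the RGB map holds over the band map
                row["ig"] = information_gain(gt_map, band_map, gt_fix)
            if "nss" in metrics:
                row["nss"] = nss(band_map, gt_fix)
            records.append(row)
    long = pd.DataFrame(records)

    summary_rows = []
    anovas: dict[str, AnovaResult] = {}
    for metric in metrics:
        if metric not in long.columns:
            continue
        by_band = long.groupby("band")[metric]
        for band, vals in by_band:
            summary_rows.append(
                {"band": band, "metric": metric,
                 "mean": float(vals.mean()), "sd": float(vals.std(ddof=0))}
            )
        groups = [g.dropna().to_numpy() for _, g in by_band]
        if all(len(g) >= 2 for g in groups):
            try:
                anovas[metric] = one_way_anova(groups)
            except ValueError:
                pass
    summary = pd.DataFrame(summary_rows)
    return long, summary, anovas


# ---------------------------------------------------------------------------
# full study orchestration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Knobs for a full desk-scale study run."""

    kernel: GaussianKernelSpec = field(default_factory=GaussianKernelSpec)
    metric_config: MetricConfig = field(default_factory=MetricConfig)
    complexity_levels: int = 3
    complexity_bins: int = 16
    band_n_splits: int = 20
    seed: int = 0


@dataclass
class StudyResult:
    comparisons: pd.DataFrame        # image_id, mode, metric, value (per-image means)
    complexity: pd.DataFrame         # image_id + five complexity columns
    correlation: pd.DataFrame        # Table-2-style mean/sd r2
    band_long: pd.DataFrame
    band_summary: pd.DataFrame
    band_anova: dict[str, AnovaResult]


def _study_negative_pool(per_image_fix: dict[str, FixationPointSet], image_id: str) -> FixationPointSet | None:
    points = [f.points for iid, f in per_image_fix.items() if iid != image_id and len(f)]
    if not points:
        return None
    return FixationPointSet(points=np.concatenate(points))


def run_study(bundle: StudyBundle, config: StudyConfig | None = None) -> StudyResult:
    """Execute the three analyses on a synthetic study bundle."""
    from .complexity_metrics import score_image  # local import avoids cycles

    config = config or StudyConfig()
    kernel = config.kernel

    # per-task, per-image observer maps
    maps: dict[str, dict[str, list[ObserverMaps]]] = {}
    acc_fix: dict[str, dict[str, FixationPointSet]] = {}
    for task, per_image in bundle.logs.items():
        maps[task] = {}
        acc_fix[task] = {}
        for image_id, logs in per_image.items():
            h, w = bundle.images[bundle.image_ids.index(image_id)].shape
            oms = build_observer_maps(logs, w, h, kernel)
            maps[task][image_id] = oms
            acc_fix[task][image_id] = map_to_fixations(accumulate_maps([m.raw for m in oms]))

    rows = []
    for image_id in bundle.image_ids:
        # negative pool: accumulated fixations of the other images (free task)
        pool = _study_negative_pool(acc_fix["free"], image_id)
        # inter-observer, per task
        for task, mode in (("categorization", "CAT"), ("free", "FREE")):
            comps = interobserver_comparisons(maps[task][image_id], pool, config.metric_config)
            for metric, value in mean_metric_values(comps).items():
                rows.append({"image_id": image_id, "mode": mode, "metric": metric, "value": value})
        # inter-experiment
        for mode_name, mode in (("observer_wise", "CvsFobs"), ("accumulated", "CvsFacc")):
            comps = interexperiment_comparison(
                maps["categorization"][image_id], maps["free"][image_id],
                mode=mode_name, negative_pool=pool, config=config.metric_config, kernel=kernel,
            )
            for metric, value in mean_metric_values(comps).items():
                rows.append({"image_id": image_id, "mode": mode, "metric": metric, "value": value})
    comparisons = pd.DataFrame(rows)

    complexity_rows = []
    for image in bundle.images:
        scores = score_image(
            render_rgb(image).as_float(), config.complexity_levels, config.complexity_bins
        )
        complexity_rows.append({"image_id": image.image_id, **scores.as_dict()})
    complexity = pd.DataFrame(complexity_rows)

    correlation = correlation_table(comparisons, complexity)
    band_long, band_summary, band_anova = band_comparison_harness(
        bundle.images, n_splits=config.band_n_splits, rng_seed=config.seed
    )
    return StudyResult(
        comparisons=comparisons,
        complexity=complexity,
        correlation=correlation,
        band_long=band_long,
        band_summary=band_summary,
        band_anova=band_anova,
    )
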