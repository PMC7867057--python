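"""Heat-map comparison metrics: NSS, AUC-Judd, AUC-Borji, shuffled AUC, IG.

Maps are compared two by two, one acting as ground truth and the other as
test.  Ground-truth fixation *locations* come from the raw delta map (one
point per nonzero pixel, weighted by accumulated fixation time); the test
map is always the filtered (smoothed) one.

The AUC family treats fixation pixels as positives and differs only in
the negatives: AUC-Judd uses every non-fixation pixel, AUC-Borji samples
random pixels uniformly, and the shuffled AUC samples fixations recorded
on *other* images, which cancels a shared center bias.  All three sweep
the threshold over every distinct score and report the trapezoidal area
under the resulting ROC, which equals the Mann-Whitney pairwise
statistic with ties credited one half.

NSS z-scores the test map over all pixels (population SD) and averages
the z-values at fixation pixels.  Information gain regularizes both maps
into probability distributions and averages log2 p_test - log2 p_baseline
over fixation pixels (bits per fixation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .heatmap_builder import HeatMap

_CONSTANT_SD = 1e-12

METRIC_NAMES = ("nss", "auc_judd", "auc_borji", "sauc", "ig")


@dataclass
class FixationPointSet:
    """Ground-truth fixation locations with optional duration weights."""

    points: np.ndarray  # (N, 2) array of (x, y) pixel positions
    weights: np.ndarray | None = None  # seconds, > 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=np.float64)
            if len(self.weights) != len(self.points):
                raise ValueError("weights must match points")
            if len(self.weights) and self.weights.min() <= 0:
                raise ValueError("weights must be > 0")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class PairComparison:
    """The five metric values for one (ground truth, test) map pair."""

    gt_id: str
    test_id: str
    values: dict[str, float] = field(default_factory=dict)
    direction_note: str = "gt->test"

    def __post_init__(self) -> None:
        for k in ("auc_judd", "auc_borji", "sauc"):
            v = self.values.get(k)
            if v is not None and not np.isnan(v) and not (0.0 <= v <= 1.0):
                raise ValueError(f"{k} out of [0, 1]: {v}")


def map_to_fixations(raw: HeatMap) -> FixationPointSet:
    """One point per nonzero pixel of a raw delta map, weighted by its value."""
    if raw.variant != "raw":
        raise ValueError("map_to_fixations expects a raw delta map")
    rows, cols = np.nonzero(raw.values)
    points = np.stack([cols, rows], axis=1).astype(np.float64)
    weights = raw.values[rows, cols] if len(rows) else None
    return FixationPointSet(points=points, weights=weights)


def dense_map_to_fixations(values: np.ndarray, top_fraction: float = 0.01) -> FixationPointSet:
    """Top-valued pixels of a dense saliency map as a pseudo-fixation set.

    Model-predicted maps are dense; thresholding at the ``top_fraction``
    quantile yields a positive set playing the role raw deltas play for
    measured maps.
    """
    values = np.asarray(values, dtype=np.float64)
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    n = max(1, int(round(values.size * top_fraction)))
    flat_idx = np.argpartition(values.ravel(), -n)[-n:]
    rows, cols = np.unravel_index(flat_idx, values.shape)
    return FixationPointSet(points=np.stack([cols, rows], axis=1).astype(np.float64))


def _fixation_indices(test: HeatMap, fix: FixationPointSet) -> tuple[np.ndarray, np.ndarray]:
    rows = np.floor(fix.points[:, 1] + 0.5).astype(int)
    cols = np.floor(fix.points[:, 0] + 0.5).astype(int)
    h, w = test.shape
    if len(rows) and (
        rows.min() < 0 or rows.max() >= h or cols.min() < 0 or cols.max() >= w
    ):
        raise ValueError("fixation points fall outside the map")
    return rows, cols


def nss(test: HeatMap, gt_fix: FixationPointSet, weighted: bool = False) -> float:
    """Normalized scanpath saliency: mean z-scored test value at fixations.

    The test map is z-scored with its population standard deviation; a
    constant map (SD ~ 0) scores 0 by convention.  Fixations are
    unweighted by default; ``weighted=True`` weights them by duration.
    """
    if len(gt_fix) == 0:
        raise ValueError("NSS needs a nonempty fixation set")
    v = test.values
    sd = float(v.std())
    if sd < _CONSTANT_SD:
        return 0.0
    z = (v - v.mean()) / sd
    rows, cols = _fixation_indices(test, gt_fix)
    at_fix = z[rows, cols]
    if weighted and gt_fix.weights is not None:
        return float(np.average(at_fix, weights=gt_fix.weights))
    return float(at_fix.mean())


def _auc_from_scores(pos: np.ndarray, neg: np.ndarray) -> float:
    """Trapezoidal ROC area with every distinct score as a threshold.

    The exhaustive sweep makes the area exactly P(pos > neg) +
    P(pos == neg)/2 over all positive/negative pairs (ties credited one
    half; verified against that pairwise oracle in the tests).
    """
    n_pos, n_neg = len(pos), len(neg)
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    tpr = (n_pos - np.searchsorted(pos_sorted, thresholds, side="left")) / n_pos
    fpr = (n_neg - np.searchsorted(neg_sorted, thresholds, side="left")) / n_neg
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    return float(np.trapezoid(tpr, fpr))


def auc_judd(test: HeatMap, gt_fix: FixationPointSet) -> float:
    """AUC with all non-fixation pixels as negatives."""
    if len(gt_fix) == 0:
        raise ValueError("AUC needs a nonempty fixation set")
    rows, cols = _fixation_indices(test, gt_fix)
    mask = np.zeros(test.shape, dtype=bool)
    mask[rows, cols] = True
    pos = test.values[mask]
    neg = test.values[~mask]
    if neg.size == 0:
        raise ValueError("fixations cover every pixel; no negatives left")
    return _auc_from_scores(pos, neg)


def auc_borji(
    test: HeatMap,
    gt_fix: FixationPointSet,
    n_splits: int = 100,
    rng_seed: int | np.random.Generator = 0,
) -> float:
    """AUC with uniformly sampled random pixels as negatives.

    Each split draws as many negatives as there are positives, without
    replacement; the mean AUC over splits is returned.  Seeded and
    reproducible.
    """
    if len(gt_fix) == 0:
        raise ValueError("AUC needs a nonempty fixation set")
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    rng = np.random.default_rng(rng_seed)
    rows, cols = _fixation_indices(test, gt_fix)
    pos = test.values[rows, cols]
    flat = test.values.ravel()
    n = min(len(pos), flat.size)
    aucs = [
        _auc_from_scores(pos, flat[rng.choice(flat.size, size=n, replace=False)])
        for _ in range(n_splits)
    ]
    return float(np.mean(aucs))


def shuffled_auc(
    test: HeatMap,
    gt_fix: FixationPointSet,
    negative_pool: FixationPointSet,
    n_splits: int = 100,
    rng_seed: int | np.random.Generator = 0,
) -> float:
    """AUC with negatives sampled from fixations on other images.

    Drawing negatives from the pooled fixation distribution of the rest
    of the study cancels any spatial bias (e.g. center bias) common to
    all images.  Sampling is without replacement when the pool allows.
    """
    if len(gt_fix) == 0:
        raise ValueError("AUC needs a nonempty fixation set")
    if len(negative_pool) == 0:
        raise ValueError("negative pool is empty")
    rng = np.random.default_rng(rng_seed)
    rows, cols = _fixation_indices(test, gt_fix)
    pos = test.values[rows, cols]
    pool_rows, pool_cols = _fixation_indices(test, negative_pool)
    pool_scores = test.values[pool_rows, pool_cols]
    n = len(pos)
    replace = len(pool_scores) < n
    aucs = [
        _auc_from_scores(pos, pool_scores[rng.choice(len(pool_scores), size=n, replace=replace)])
        for _ in range(n_splits)
    ]
    return float(np.mean(aucs))


def _regularized_pdf(values: np.ndarray, eps: float) -> np.ndarray:
    """Map -> probability distribution with a uniform admixture.

    Every pixel receives an extra ``eps`` share of the map's total mass
    (default 1/(H*W), see :func:`information_gain`), then the result is
    renormalized to sum to 1.  An all-zero map becomes uniform.
    """
    v = np.asarray(values, dtype=np.float64)
    total = v.sum()
    if total <= 0:
        return np.full(v.shape, 1.0 / v.size)
    p = v + total * eps
    return p / p.sum()


def information_gain(
    test: HeatMap,
    baseline: HeatMap,
    gt_fix: FixationPointSet,
    eps: float | None = None,
) -> float:
    """Bits per fixation gained by the test map over the baseline map.

    Both maps are regularized into probability distributions (each pixel
    gains ``eps`` of the map's mass, default eps = 1/(H*W)) and the mean
    of log2 p_test - log2 p_baseline over fixation pixels is returned.
    Positive means the test map concentrates more probability on the
    fixated locations than the baseline does.
    """
    if test.shape != baseline.shape:
        raise ValueError("test and baseline maps must share a shape")
    if len(gt_fix) == 0:
        raise ValueError("IG needs a nonempty fixation set")
    if eps is None:
        eps = 1.0 / test.values.size
    p_test = _regularized_pdf(test.values, eps)
    p_base = _regularized_pdf(baseline.values, eps)
    rows, cols = _fixation_indices(test, gt_fix)
    return float(np.mean(np.log2(p_test[rows, cols]) - np.log2(p_base[rows, cols])))


@dataclass
class MetricConfig:
    n_splits: int = 100
    rng_seed: int = 0
    ig_eps: float | None = None
    nss_weighted: bool = False


def compare_pair(
    gt_raw: HeatMap,
    gt_filtered: HeatMap,
    test_raw: HeatMap,
    test_filtered: HeatMap,
    negative_pool: FixationPointSet | None = None,
    config: MetricConfig | None = None,
    gt_id: str = "gt",
    test_id: str = "test",
) -> PairComparison:
    """All five metrics for one ordered (ground truth, test) map pair.

    Ground-truth fixations are read off the gt raw delta map; NSS and the
    AUC family score the test *filtered* map against them; IG uses the gt
    filtered map as the baseline.  The shuffled AUC needs a negative pool
    (fixations from other images) and is NaN when none is supplied.
    """
    if gt_filtered.shape != test_filtered.shape:
        raise ValueError("map shapes must match")
    config = config or MetricConfig()
    fix = map_to_fixations(gt_raw)
    values = {
        "nss": nss(test_filtered, fix, weighted=config.nss_weighted),
        "auc_judd": auc_judd(test_filtered, fix),
        "auc_borji": auc_borji(test_filtered, fix, config.n_splits, config.rng_seed),
        "sauc": (
            shuffled_auc(test_filtered, fix, negative_pool, config.n_splits, config.rng_seed)
            if negative_pool is not None and len(negative_pool)
            else float("nan")
        ),
        "ig": information_gain(test_filtered, gt_filtered, fix, config.ig_eps),
    }
    return PairComparison(gt_id=gt_id, test_id=test_id, values=values)
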