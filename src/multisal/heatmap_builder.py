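"""Fixation heat maps: raw delta maps, Gaussian smoothing, accumulation.

A heat map is a nonnegative H x W array whose intensity at a pixel is the
accumulated fixation time (seconds) there.  The *raw* variant places unit
pixel deltas whose heights equal fixation durations; the *filtered*
variant is its linear convolution with a unit-sum Gaussian kernel
(default radius R = 100 px, sigma = 20 px) under zero padding, so mass is
conserved for fixations at least R px from every border.  Accumulation
across observers sums the raw maps pixelwise; by linearity
accumulate-then-smooth equals smooth-then-accumulate, and the former is
canonical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .fixation_processing import Fixation

log = logging.getLogger(__name__)


@dataclass
class GaussianKernelSpec:
    """Smoothing kernel: window half-size R (px) and standard deviation (px).

    The window is (2R+1) x (2R+1) and the kernel is normalized to unit
    sum so that filtering preserves total fixation time.  R must be at
    least 3 sigma so the truncated tails are negligible.
    """

    radius: int = 100
    sigma: float = 20.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.radius < 3 * self.sigma:
            raise ValueError("radius must be >= 3 sigma")

    @property
    def fwhm(self) -> float:
        return fwhm_px(self.sigma)

    def halfmax_visual_angle(self, density_px_per_mm: float, distance_mm: float) -> float:
        return visual_angle_deg(self.fwhm, density_px_per_mm, distance_mm)


@dataclass
class HeatMap:
    """H x W nonnegative intensity array plus provenance."""

    values: np.ndarray
    variant: str  # "raw" | "filtered"
    observer_ids: tuple[str, ...] = ()
    image_id: str = ""
    task: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("heat map must be 2-D")
        if self.variant not in ("raw", "filtered"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.values.size and self.values.min() < 0:
            raise ValueError("heat map values must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def build_delta_map(fixations: list[Fixation], width: int, height: int) -> HeatMap:
    """Place unit-pixel deltas of height = fixation duration (s).

    Fixation coordinates are rounded half-up to the nearest pixel.
    Out-of-bounds fixations are discarded (their count is logged); the
    map's sum equals the total in-bounds fixation time.
    """
    if width <= 0 or height <= 0:
        raise ValueError("map dimensions must be positive")
    values = np.zeros((height, width), dtype=np.float64)
    dropped = 0
    for f in fixations:
        col = int(math.floor(f.x + 0.5))
        row = int(math.floor(f.y + 0.5))
        if 0 <= col < width and 0 <= row < height:
            values[row, col] += f.duration
        else:
            dropped += 1
    if dropped:
        log.info("build_delta_map: discarded %d out-of-bounds fixation(s)", dropped)
    observers = tuple(dict.fromkeys(f.observer_id for f in fixations if f.observer_id))
    image_id = fixations[0].image_id if fixations else ""
    task = fixations[0].task if fixations else ""
    return HeatMap(
        values=values,
        variant="raw",
        observer_ids=observers,
        image_id=image_id,
        task=task,
        meta={"dropped_out_of_bounds": dropped},
    )


def make_kernel(spec: GaussianKernelSpec) -> np.ndarray:
    """Unit-sum isotropic Gaussian on a (2R+1) x (2R+1) window."""
    r = spec.radius
    ax = np.arange(-r, r + 1, dtype=np.float64)
    g1 = np.exp(-(ax**2) / (2.0 * spec.sigma**2))
    kernel = np.outer(g1, g1)
    return kernel / kernel.sum()


def smooth_map(raw: HeatMap, spec: GaussianKernelSpec | None = None) -> HeatMap:
    """Linear convolution of a raw map with the Gaussian kernel.

    Zero padding: mass falling off the image vanishes, so the filtered
    sum equals the raw sum whenever every delta sits >= R px from the
    borders.
    """
    if raw.variant != "raw":
        raise ValueError("smooth_map expects a raw map")
    spec = spec or GaussianKernelSpec()
    kernel = make_kernel(spec)
    values = signal.oaconvolve(raw.values, kernel, mode="same")
    values = np.clip(values, 0.0, None)  # FFT round-off can dip below zero
    return HeatMap(
        values=values,
        variant="filtered",
        observer_ids=raw.observer_ids,
        image_id=raw.image_id,
        task=raw.task,
        meta={**raw.meta, "kernel_radius": spec.radius, "kernel_sigma": spec.sigma},
    )


def accumulate_maps(raw_maps: list[HeatMap]) -> HeatMap:
    """Pixelwise sum of per-observer raw maps (the accumulated map)."""
    if not raw_maps:
        raise ValueError("need at least one map to accumulate")
    shape = raw_maps[0].shape
    for m in raw_maps:
        if m.variant != "raw":
            raise ValueError("accumulate_maps expects raw maps")
        if m.shape != shape:
            raise ValueError(f"shape mismatch: {m.shape} vs {shape}")
    values = np.sum([m.values for m in raw_maps], axis=0)
    observers = tuple(dict.fromkeys(o for m in raw_maps for o in m.observer_ids))
    return HeatMap(
        values=values,
        variant="raw",
        observer_ids=observers,
        image_id=raw_maps[0].image_id,
        task=raw_maps[0].task,
    )


def fwhm_px(sigma: float) -> float:
    """Full width at half maximum of a Gaussian: 2 sqrt(2 ln 2) sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return 2.0 * math.sqrt(2.0 * math.log(2.0)) * sigma


def visual_angle_deg(extent_px: float, density_px_per_mm: float, distance_mm: float) -> float:
    """Visual angle subtended by an on-screen extent, in degrees.

    2 arctan(extent / (2 d)) with the extent converted to mm via the
    display pixel density and d the viewing distance.
    """
    if extent_px < 0:
        raise ValueError("extent must be >= 0")
    if density_px_per_mm <= 0 or distance_mm <= 0:
        raise ValueError("density and distance must be > 0")
    extent_mm = extent_px / density_px_per_mm
    return math.degrees(2.0 * math.atan2(extent_mm, 2.0 * distance_mm))
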