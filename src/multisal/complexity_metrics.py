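"""Image-complexity metrics: self-similarity, complexity, Birkhoff-like
measure, anisotropy and entropy.

These five scores summarize how ordered or cluttered a scene is:

* **self-similarity** (M_SeSf, in [0, 1]): a spatial pyramid cuts the
  image into 4^k equally sized sections at level k; each section gets a
  HOG (histogram of oriented gradients, magnitude-weighted, L1-normed)
  and the metric is the median histogram-intersection similarity between
  every level-3 section and its level-2 parent;
* **complexity** (M_Co >= 0): mean over pixels of the maximum per-channel
  gradient magnitude G_max(x, y) = max(||grad R||, ||grad G||, ||grad B||);
* **Birkhoff-like metric** (M_BLM): the order/complexity ratio
  M_SeSf / M_Co — undefined (None) for a gradient-free image;
* **anisotropy**: population variance of all pooled level-3 HOG bin
  values — low when gradient energy spreads evenly over orientations;
* **entropy** (bits, in [0, 8]): Shannon entropy of the 256-bin 8-bit
  grayscale histogram.

Gradients are central differences (replicated borders for G_max,
periodic borders for per-section HOGs); HOG orientations are unsigned
*edge* orientations (gradient direction rotated by 90°), binned over
[0°, 180°) into 16 bins by default.
A section with no gradient energy falls back to a flagged uniform
histogram, so a constant image scores M_SeSf = 1 and anisotropy = 0
rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_BINS = 16
DEFAULT_LEVELS = 3


@dataclass
class HogDescriptor:
    """L1-normalized orientation histogram of one image section."""

    histogram: np.ndarray
    fallback: bool = False  # True when the section had no gradient energy

    def __post_init__(self) -> None:
        self.histogram = np.asarray(self.histogram, dtype=np.float64)
        if self.histogram.min() < 0:
            raise ValueError("histogram entries must be >= 0")
        if abs(self.histogram.sum() - 1.0) > 1e-9:
            raise ValueError("histogram must be L1-normalized")


@dataclass
class SectionPyramid:
    """Levels 0..L of equally sized sections; level k holds a 2^k x 2^k grid.

    Section (i, j) at level k spans rows [i*th, (i+1)*th) and columns
    [j*tw, (j+1)*tw) with th = floor(H / 2^k), tw = floor(W / 2^k);
    remainder pixels on the right/bottom are discarded.  Its parent at
    level k-1 is section (i // 2, j // 2).
    """

    image: np.ndarray
    levels: int = DEFAULT_LEVELS

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        h, w = self.image.shape[:2]
        if h < 2**self.levels or w < 2**self.levels:
            raise ValueError(
                f"image {h}x{w} too small for a {self.levels}-level pyramid"
            )

    def grid(self, level: int) -> int:
        return 2**level

    def section(self, level: int, i: int, j: int) -> np.ndarray:
        g = self.grid(level)
        h, w = self.image.shape[:2]
        th, tw = h // g, w // g
        return self.image[i * th : (i + 1) * th, j * tw : (j + 1) * tw]

    def parent_index(self, i: int, j: int) -> tuple[int, int]:
        return i // 2, j // 2


def build_pyramid(image: np.ndarray, levels: int = DEFAULT_LEVELS) -> SectionPyramid:
    """Section pyramid over a grayscale image (see :class:`SectionPyramid`)."""
    return SectionPyramid(image=image, levels=levels)


def _central_gradient(
    channel: np.ndarray, mode: str = "edge"
) -> tuple[np.ndarray, np.ndarray]:
    """Central differences: (d/dy, d/dx).

    ``mode="edge"`` replicates borders (used for G_max, keeping the
    complexity metric flip-symmetric); ``mode="wrap"`` pads periodically
    (used for per-section HOGs, making a texture tiled on the section
    grid exactly self-similar).
    """
    p = np.pad(np.asarray(channel, dtype=np.float64), 1, mode=mode)
    gy = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0
    gx = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0
    return gy, gx


def hog(section: np.ndarray, bins: int = DEFAULT_BINS) -> HogDescriptor:
    """Magnitude-weighted unsigned-orientation histogram of one section.

    Orientation is the *edge* orientation (gradient angle + 90°) modulo
    180°, so a vertical edge loads the 90° bin.  A section with zero
    total gradient magnitude yields a flagged uniform histogram.
    """
    section = np.asarray(section, dtype=np.float64)
    if section.size == 0:
        raise ValueError("section is empty")
    gy, gx = _central_gradient(section, mode="wrap")
    magnitude = np.hypot(gx, gy)
    total = magnitude.sum()
    if total <= 0:
        return HogDescriptor(histogram=np.full(bins, 1.0 / bins), fallback=True)
    orientation = np.mod(np.arctan2(gy, gx) + np.pi / 2.0, np.pi)  # edge orientation
    idx = np.minimum((orientation / np.pi * bins).astype(int), bins - 1)
    hist = np.bincount(idx.ravel(), weights=magnitude.ravel(), minlength=bins)
    return HogDescriptor(histogram=hist / total)


def hik(h1: np.ndarray | HogDescriptor, h2: np.ndarray | HogDescriptor) -> float:
    """Histogram intersection kernel: sum of bin-wise minima, in [0, 1]."""
    a = h1.histogram if isinstance(h1, HogDescriptor) else np.asarray(h1, dtype=np.float64)
    b = h2.histogram if isinstance(h2, HogDescriptor) else np.asarray(h2, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("histograms must have equal length")
    return float(np.minimum(a, b).sum())


def _level_hogs(pyr: SectionPyramid, level: int, bins: int) -> dict[tuple[int, int], HogDescriptor]:
    g = pyr.grid(level)
    return {(i, j): hog(pyr.section(level, i, j), bins) for i in range(g) for j in range(g)}


def self_similarity(
    image: np.ndarray, levels: int = DEFAULT_LEVELS, bins: int = DEFAULT_BINS
) -> float:
    """Median HIK between each deepest-level section HOG and its parent's HOG."""
    pyr = build_pyramid(_to_gray(image), levels)
    return _self_similarity_from_pyramid(pyr, bins)


def _self_similarity_from_pyramid(pyr: SectionPyramid, bins: int) -> float:
    child_hogs = _level_hogs(pyr, pyr.levels, bins)
    parent_hogs = _level_hogs(pyr, pyr.levels - 1, bins)
    sims = [
        hik(child_hogs[(i, j)], parent_hogs[pyr.parent_index(i, j)])
        for (i, j) in sorted(child_hogs)
    ]
    return float(np.median(sims))


def gradient_field(rgb_image: np.ndarray) -> np.ndarray:
    """Pixelwise maximum per-channel gradient magnitude G_max.

    A single-channel image is treated as R = G = B (identical channels,
    so the max is just that channel's gradient magnitude).
    """
    img = np.asarray(rgb_image, dtype=np.float64)
    if img.ndim == 2:
        img = img[:, :, None]
    mags = []
    for c in range(img.shape[2]):
        gy, gx = _central_gradient(img[:, :, c])
        mags.append(np.hypot(gx, gy))
    return np.max(mags, axis=0)


def complexity(rgb_image: np.ndarray) -> float:
    """M_Co: mean of G_max over all pixels."""
    return float(gradient_field(rgb_image).mean())


def birkhoff(m_sesf: float, m_co: float) -> float | None:
    """Order/complexity ratio M_SeSf / M_Co; None when M_Co == 0."""
    if m_co < 0:
        raise ValueError("M_Co must be >= 0")
    if m_co == 0:
        return None
    return m_sesf / m_co


def anisotropy(
    image: np.ndarray, levels: int = DEFAULT_LEVELS, bins: int = DEFAULT_BINS
) -> float:
    """Population variance of all pooled deepest-level HOG bin values."""
    pyr = build_pyramid(_to_gray(image), levels)
    return _anisotropy_from_pyramid(pyr, bins)


def _anisotropy_from_pyramid(pyr: SectionPyramid, bins: int) -> float:
    hogs = _level_hogs(pyr, pyr.levels, bins)
    pooled = np.concatenate([h.histogram for h in hogs.values()])
    return float(pooled.var())


def entropy(image: np.ndarray) -> float:
    """Shannon entropy (bits) of the 8-bit grayscale histogram."""
    gray = _to_gray(image)
    if gray.dtype == np.uint8:
        levels = gray
    else:
        g = np.asarray(gray, dtype=np.float64)
        if g.size and g.max() > 1.0:  # already on a 0..255 scale
            g = g / 255.0
        levels = np.floor(np.clip(g, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    counts = np.bincount(levels.ravel(), minlength=256)
    p = counts[counts > 0] / levels.size
    return float(-(p * np.log2(p)).sum())


def _to_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 3:
        return image.astype(np.float64).mean(axis=2)
    return image


@dataclass
class ComplexityScores:
    """The five per-image complexity metrics."""

    m_sesf: float
    m_co: float
    m_blm: float | None  # None when M_Co == 0 (undefined, not infinite)
    anisotropy: float
    entropy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.m_sesf <= 1.0:
            raise ValueError("M_SeSf must lie in [0, 1]")
        if self.m_co < 0:
            raise ValueError("M_Co must be >= 0")
        if self.anisotropy < 0:
            raise ValueError("anisotropy must be >= 0")
        if not 0.0 <= self.entropy <= 8.0 + 1e-12:
            raise ValueError("entropy must lie in [0, 8] bits")

    def as_dict(self) -> dict[str, float | None]:
        return {
            "m_sesf": self.m_sesf,
            "m_co": self.m_co,
            "m_blm": self.m_blm,
            "anisotropy": self.anisotropy,
            "entropy": self.entropy,
        }


def score_image(
    rgb_image: np.ndarray, levels: int = DEFAULT_LEVELS, bins: int = DEFAULT_BINS
) -> ComplexityScores:
    """All five metrics in one pass over a shared pyramid."""
    pyr = build_pyramid(_to_gray(rgb_image), levels)
    m_sesf = _self_similarity_from_pyramid(pyr, bins)
    m_co = complexity(rgb_image)
    return ComplexityScores(
        m_sesf=m_sesf,
        m_co=m_co,
        m_blm=birkhoff(m_sesf, m_co),
        anisotropy=_anisotropy_from_pyramid(pyr, bins),
        entropy=entropy(rgb_image),
    )
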