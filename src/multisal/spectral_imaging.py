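"""Eight-band multispectral image cubes and their RGB renderings.

A capture is an H x W x 8 cube of reflectance-like values in [0, 1], one
slice per band-pass filter.  Six bands sit in the visible range and two in
the near infrared; the color rendering picks bands 6, 4 and 2 (1-based) as
the R, G and B channels and white-balances each channel independently.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

log = logging.getLogger(__name__)

N_BANDS = 8

#: Central wavelength (nm) and bandwidth (nm) of each band-pass filter.
DEFAULT_BAND_META: tuple[tuple[float, float], ...] = (
    (425.0, 50.0),
    (482.0, 56.0),
    (530.0, 24.0),
    (570.0, 50.0),
    (615.0, 100.0),
    (680.0, 50.0),
    (770.0, 102.0),
    (833.0, 125.0),
)

#: 1-based band numbers mapped to the R, G and B channels of the rendering.
RGB_BANDS: tuple[int, int, int] = (6, 4, 2)


@dataclass
class MultispectralImage:
    """An 8-band image cube with values in [0, 1] plus band metadata."""

    cube: np.ndarray
    band_meta: tuple[tuple[float, float], ...] = DEFAULT_BAND_META
    image_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=np.float64)
        if self.cube.ndim != 3 or self.cube.shape[2] != N_BANDS:
            raise ValueError(f"cube must be H x W x {N_BANDS}, got {self.cube.shape}")
        if len(self.band_meta) != N_BANDS:
            raise ValueError(f"band_meta must list {N_BANDS} bands")
        if self.cube.size and (self.cube.min() < 0 or self.cube.max() > 1):
            raise ValueError("cube values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cube.shape[:2]


@dataclass
class RgbImage:
    """8-bit color rendering of a cube, with band provenance."""

    pixels: np.ndarray  # H x W x 3 uint8
    source_bands: tuple[int, int, int] = RGB_BANDS
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("RGB image must be H x W x 3")
        if self.pixels.dtype != np.uint8:
            raise ValueError("RGB image must be 8-bit")

    def as_float(self) -> np.ndarray:
        """Channels scaled back to [0, 1] floats."""
        return self.pixels.astype(np.float64) / 255.0


def average_frames(frames: list[np.ndarray]) -> np.ndarray:
    """Pixelwise mean of repeated captures of one band (noise reduction).

    Three frames per filter are averaged during capture; any positive
    number of equally shaped frames is accepted.
    """
    if not frames:
        raise ValueError("need at least one frame")
    arrays = [np.asarray(f, dtype=np.float64) for f in frames]
    shape = arrays[0].shape
    for a in arrays[1:]:
        if a.shape != shape:
            raise ValueError(f"frame shape mismatch: {a.shape} vs {shape}")
    return np.mean(arrays, axis=0)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def render_rgb(ms: MultispectralImage, mode: str = "minmax") -> RgbImage:
    """Render a false-color RGB image from bands 6 (R), 4 (G) and 2 (B).

    Each channel is normalized independently to [0, 1] (a manual white
    balance) and then quantized to 8 bits with half-up rounding.

    Parameters
    ----------
    mode:
        ``"minmax"`` maps the channel's min and max to 0 and 255;
        ``"max"`` divides by the channel maximum only.

    A constant channel (max == min, nothing to normalize) is set to 0 and
    a warning is emitted.
    """
    if mode not in ("minmax", "max"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    h, w = ms.shape
    out = np.zeros((h, w, 3), dtype=np.uint8)
    for ch, band in enumerate(RGB_BANDS):
        plane = extract_band(ms, band)
        lo, hi = float(plane.min()), float(plane.max())
        if mode == "max":
            lo = 0.0
        if hi - lo <= 0:
            warnings.warn(
                f"band {band} is constant; channel {'RGB'[ch]} set to 0",
                stacklevel=2,
            )
            continue
        norm = (plane - lo) / (hi - lo)
        out[:, :, ch] = _round_half_up(norm * 255.0).astype(np.uint8)
    return RgbImage(pixels=out, source_bands=RGB_BANDS, image_id=ms.image_id)


def extract_band(ms: MultispectralImage, k: int) -> np.ndarray:
    """Return band ``k`` (1-based, 1..8) as an H x W array, values unchanged."""
    if not 1 <= k <= N_BANDS:
        raise ValueError(f"band number must be in 1..{N_BANDS}, got {k}")
    return ms.cube[:, :, k - 1]


def subdivide(image: np.ndarray, grid_rows: int, grid_cols: int) -> list[np.ndarray]:
    """Cut an image into a rows x cols grid of equally sized sub-images.

    Tile size is (floor(H / rows), floor(W / cols)); remainder pixels on
    the right and bottom edges are discarded.  Tiles are returned in
    row-major order.  Works on 2-D grayscale and H x W x C arrays alike.
    """
    if grid_rows < 1 or grid_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    image = np.asarray(image)
    h, w = image.shape[:2]
    th, tw = h // grid_rows, w // grid_cols
    if th < 1 or tw < 1:
        raise ValueError(
            f"grid {grid_rows}x{grid_cols} yields sub-images smaller than 1 px "
            f"for a {h}x{w} image"
        )
    tiles = []
    for i in range(grid_rows):
        for j in range(grid_cols):
            tiles.append(image[i * th : (i + 1) * th, j * tw : (j + 1) * tw])
    return tiles


def save_cube(ms: MultispectralImage, path: str | Path) -> None:
    """Write a cube as multi-band float32 TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, ms.cube.astype(np.float32))
    sidecar = {
        "image_id": ms.image_id,
        "band_meta": [list(b) for b in ms.band_meta],
        "meta": ms.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_cube(path: str | Path) -> MultispectralImage:
    """Read a cube written by :func:`save_cube`."""
    path = Path(path)
    cube = np.asarray(tifffile.imread(path), dtype=np.float64)
    sidecar_path = path.with_suffix(".json")
    band_meta = DEFAULT_BAND_META
    image_id, meta = "", {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        band_meta = tuple(tuple(b) for b in sidecar.get("band_meta", DEFAULT_BAND_META))
        image_id = sidecar.get("image_id", "")
        meta = sidecar.get("meta", {})
    return MultispectralImage(cube=cube, band_meta=band_meta, image_id=image_id, meta=meta)
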