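"""Persistence for heat maps: lossless TIFF, sparse CSV, PNG overlays."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from matplotlib import colormaps

from .heatmap_builder import HeatMap


def save_heatmap(hm: HeatMap, path: str | Path) -> None:
    """Write a heat map as single-band float32 TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, hm.values.astype(np.float32))
    sidecar = {
        "variant": hm.variant,
        "observer_ids": list(hm.observer_ids),
        "image_id": hm.image_id,
        "task": hm.task,
        "meta": hm.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_heatmap(path: str | Path) -> HeatMap:
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=np.float64)
    sidecar_path = path.with_suffix(".json")
    kw = {"variant": "raw", "observer_ids": (), "image_id": "", "task": "", "meta": {}}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        kw = {
            "variant": sidecar.get("variant", "raw"),
            "observer_ids": tuple(sidecar.get("observer_ids", ())),
            "image_id": sidecar.get("image_id", ""),
            "task": sidecar.get("task", ""),
            "meta": sidecar.get("meta", {}),
        }
    return HeatMap(values=values, **kw)


def raw_map_to_sparse_csv(hm: HeatMap, path: str | Path) -> None:
    """Raw delta maps are sparse; store only nonzero pixels as (x, y, value)."""
    rows, cols = np.nonzero(hm.values)
    pd.DataFrame({"x": cols, "y": rows, "value": hm.values[rows, cols]}).to_csv(
        path, index=False
    )


def render_overlay(
    hm: HeatMap,
    background: np.ndarray,
    path: str | Path | None = None,
    alpha: float = 0.6,
    cmap: str = "jet",
) -> np.ndarray:
    """Alpha-blend a heat map over an RGB background (8-bit), optionally to PNG."""
    bg = np.asarray(background, dtype=np.float64)
    if bg.dtype != np.float64 or bg.max() > 1.0:
        bg = bg / 255.0
    if bg.ndim == 2:
        bg = np.stack([bg] * 3, axis=-1)
    v = hm.values
    vmax = v.max()
    norm = v / vmax if vmax > 0 else v
    colors = colormaps[cmap](norm)[:, :, :3]
    weight = alpha * norm[:, :, None]
    blended = (1 - weight) * bg + weight * colors
    out = np.floor(blended * 255.0 + 0.5).astype(np.uint8)
    if path is not None:
        iio.imwrite(Path(path), out)
    return out
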