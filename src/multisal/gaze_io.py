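"""Reading and writing eyetracker sample logs.

The canonical dialect is a UTF-8 TSV with one header row.  Each data row is
one binocular sample: timestamp (ms), left/right gaze position (image
pixels, 0-based, x = column, y = row), the device's movement label
(fixation / saccade / other), binocular validity (1 = both eyes tracked),
and optional pupil sizes (mm) and viewing distance (mm).

Timestamps are stored to 0.01 ms and positions to 0.01 px; a round trip
through :func:`write_gaze_log` / :func:`read_gaze_log` is lossless at that
precision.  Parsing is locale-independent (decimal point).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MOVEMENT_LABELS = ("fixation", "saccade", "other")

MANDATORY_COLUMNS = [
    "timestamp_ms",
    "left_x",
    "left_y",
    "right_x",
    "right_y",
    "movement",
    "validity",
]
OPTIONAL_COLUMNS = ["pupil_left", "pupil_right", "distance_mm"]
ID_COLUMNS = ["observer_id", "image_id", "task"]

_FLOAT_FORMATS = {
    "timestamp_ms": "%.2f",
    "left_x": "%.2f",
    "left_y": "%.2f",
    "right_x": "%.2f",
    "right_y": "%.2f",
    "pupil_left": "%.3f",
    "pupil_right": "%.3f",
    "distance_mm": "%.2f",
}


@dataclass
class ImportConfig:
    """Screen-to-image coordinate mapping and header remapping.

    The device records in screen coordinates; the image occupies a window
    at ``(offset_x, offset_y)`` scaled by ``scale`` (screen px per image
    px).  Defaults assume the log is already image-relative.  ``column_map``
    renames alternative vendor headers to the canonical names.
    """

    offset_x: float = 0.0
    offset_y: float = 0.0
    scale: float = 1.0
    column_map: dict[str, str] = field(default_factory=dict)


@dataclass
class GazeLog:
    """Ordered binocular samples for one observer viewing one image."""

    observer_id: str
    image_id: str
    task: str
    samples: pd.DataFrame  # columns per MANDATORY_COLUMNS (+ optional)

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"gaze log is missing mandatory columns: {missing}")
        t = self.samples["timestamp_ms"].to_numpy()
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("sample timestamps must be strictly increasing")
        if len(t) and not np.isfinite(t).all():
            raise ValueError("timestamps must be finite")
        bad = set(self.samples["movement"]) - set(MOVEMENT_LABELS)
        if bad:
            raise ValueError(f"unknown movement labels: {sorted(bad)}")
        v = self.samples["validity"].to_numpy()
        if len(v) and not np.isin(v, (0, 1)).all():
            raise ValueError("validity must be 0 or 1")

    def __len__(self) -> int:
        return len(self.samples)


def read_gaze_log(path: str | Path, config: ImportConfig | None = None) -> GazeLog:
    """Parse a TSV gaze log.

    Unknown movement labels map to ``"other"``; a file with a header and no
    data rows yields an empty (valid) log.  Out-of-order timestamps and
    missing mandatory columns raise ``ValueError``.
    """
    config = config or ImportConfig()
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"observer_id": str, "image_id": str, "task": str})
    if config.column_map:
        df = df.rename(columns=config.column_map)
    for col in ID_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r} in {path}")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s) {missing} in {path}")

    if len(df):
        observer_id = str(df["observer_id"].iloc[0])
        image_id = str(df["image_id"].iloc[0])
        task = str(df["task"].iloc[0])
    else:
        observer_id = image_id = task = ""

    samples = df[[c for c in MANDATORY_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]].copy()
    samples["movement"] = [
        m if m in MOVEMENT_LABELS else "other" for m in samples["movement"].astype(str)
    ]
    samples["validity"] = samples["validity"].astype(int) if len(samples) else samples["validity"]
    # screen -> image coordinates
    for col in ("left_x", "right_x"):
        samples[col] = (samples[col] - config.offset_x) / config.scale
    for col in ("left_y", "right_y"):
        samples[col] = (samples[col] - config.offset_y) / config.scale
    return GazeLog(observer_id=observer_id, image_id=image_id, task=task, samples=samples)


def write_gaze_log(log: GazeLog, path: str | Path) -> None:
    """Write a log in the canonical TSV dialect.

    Optional columns that are absent from the log are omitted from the
    file; an empty log produces a header-only file.
    """
    path = Path(path)
    cols = MANDATORY_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in log.samples.columns]
    out = log.samples[cols].copy()
    for col in cols:
        if col in _FLOAT_FORMATS:
            out[col] = [_FLOAT_FORMATS[col] % v for v in out[col]]
    out.insert(0, "task", log.task)
    out.insert(0, "image_id", log.image_id)
    out.insert(0, "observer_id", log.observer_id)
    out.to_csv(path, sep="\t", index=False)
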