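"""From raw 60 Hz samples to validated fixation events.

The device labels every sample as fixation or saccade and repeats one
fixation across many consecutive samples.  Processing therefore proceeds
in movement events, not samples:

1. coalesce runs of samples that share a movement label, a validity flag
   and (to within half a pixel) a gaze position into single events;
2. duration of event i = start timestamp of event i+1 minus start of
   event i; the final event has no successor and is dropped;
3. keep fixation events whose binocular validity is positive;
4. fixation position = component-wise mean of the left- and right-eye
   positions; durations converted to seconds.

Any change of label, validity or position opens a new event, so a lost or
invalid sample in mid-fixation splits it in two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaze_io import GazeLog

#: Samples closer than this (px, either eye, both axes) continue a run.
POSITION_TOL_PX = 0.5


@dataclass
class EyeMovementEvent:
    movement: str
    start_ms: float
    duration_ms: float
    left_pos: tuple[float, float]   # (x, y), mean over the run's samples
    right_pos: tuple[float, float]
    validity: int

    def __post_init__(self) -> None:
        if self.duration_ms < 0:
            raise ValueError("event duration must be >= 0")


@dataclass
class Fixation:
    """A validated fixation: binocular mean position and duration."""

    x: float
    y: float
    duration: float  # seconds
    observer_id: str = ""
    image_id: str = ""
    task: str = ""

    def __post_init__(self) -> None:
        if not (self.duration > 0):
            raise ValueError("fixation duration must be > 0")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("fixation position must be finite")


def _runs(samples: pd.DataFrame, position_tol: float) -> list[slice]:
    """Boundaries of coalesced movement runs as slices into the samples."""
    n = len(samples)
    if n == 0:
        return []
    mov = samples["movement"].to_numpy()
    val = samples["validity"].to_numpy()
    pos = samples[["left_x", "left_y", "right_x", "right_y"]].to_numpy(dtype=float)
    breaks = [0]
    for i in range(1, n):
        if (
            mov[i] != mov[i - 1]
            or val[i] != val[i - 1]
            or np.abs(pos[i] - pos[i - 1]).max() >= position_tol
        ):
            breaks.append(i)
    breaks.append(n)
    return [slice(a, b) for a, b in zip(breaks[:-1], breaks[1:])]


def compute_event_durations(
    log: GazeLog, position_tol: float = POSITION_TOL_PX
) -> list[EyeMovementEvent]:
    """Coalesce samples into movement events and difference their starts.

    Event i's duration is the difference between the start timestamps of
    events i+1 and i; the last event is dropped (no successor).  A log
    with fewer than two distinct events yields an empty list.
    """
    runs = _runs(log.samples, position_tol)
    if len(runs) < 2:
        return []
    t = log.samples["timestamp_ms"].to_numpy(dtype=float)
    pos = log.samples[["left_x", "left_y", "right_x", "right_y"]].to_numpy(dtype=float)
    mov = log.samples["movement"].to_numpy()
    val = log.samples["validity"].to_numpy()

    events = []
    starts = [t[r.start] for r in runs]
    for i, r in enumerate(runs[:-1]):
        mean_pos = pos[r].mean(axis=0)
        events.append(
            EyeMovementEvent(
                movement=str(mov[r.start]),
                start_ms=starts[i],
                duration_ms=starts[i + 1] - starts[i],
                left_pos=(mean_pos[0], mean_pos[1]),
                right_pos=(mean_pos[2], mean_pos[3]),
                validity=int(val[r.start]),
            )
        )
    return events


def extract_fixations(
    events: list[EyeMovementEvent],
    observer_id: str = "",
    image_id: str = "",
    task: str = "",
) -> list[Fixation]:
    """Filter events to valid fixations and average the two eyes.

    Only events labelled ``fixation`` with positive binocular validity
    survive (the two filters commute).  Zero-duration events are dropped:
    a fixation must span at least one inter-sample interval.
    """
    fixations = []
    for ev in events:
        if ev.movement != "fixation" or ev.validity != 1 or ev.duration_ms <= 0:
            continue
        fixations.append(
            Fixation(
                x=(ev.left_pos[0] + ev.right_pos[0]) / 2.0,
                y=(ev.left_pos[1] + ev.right_pos[1]) / 2.0,
                duration=ev.duration_ms / 1000.0,
                observer_id=observer_id,
                image_id=image_id,
                task=task,
            )
        )
    return fixations


def fixations_from_log(log: GazeLog, position_tol: float = POSITION_TOL_PX) -> list[Fixation]:
    """Full pipeline for one log: events -> filters -> binocular means."""
    events = compute_event_durations(log, position_tol)
    return extract_fixations(events, log.observer_id, log.image_id, log.task)


def fixations_to_frame(fixations: list[Fixation]) -> pd.DataFrame:
    """Fixation list as a CSV-ready table."""
    return pd.DataFrame(
        [
            {
                "observer_id": f.observer_id,
                "image_id": f.image_id,
                "task": f.task,
                "x": f.x,
                "y": f.y,
                "duration_s": f.duration,
            }
            for f in fixations
        ],
        columns=["observer_id", "image_id", "task", "x", "y", "duration_s"],
    )
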