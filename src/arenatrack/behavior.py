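"""Behavioral parameters from tracks: speed, movement bouts, zone
occupancy, per-recording and time-binned summaries, preference
proportions, and validation against reference annotation.

Movement segmentation uses velocity hysteresis: a movement event
starts when the trailing windowed mean speed exceeds the start
threshold (0.5 mm/s over 10 frames by default) and stops when it
drops below the stop threshold (0.1 mm/s). The trailing window has a
fixed denominator, with the slots before the start of the recording
counting as zero speed; the initial state is not-moving (subjects are
placed in the arena anesthetized).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import Calibration, Zone, assign_zones
from .track import Track

__all__ = [
    "MovementParams",
    "MovementEvent",
    "compute_speed",
    "segment_movement",
    "moving_state_array",
    "summarize_behavior",
    "preference_proportion",
    "validate_against_reference",
]


@dataclass(frozen=True)
class MovementParams:
    """Hysteresis thresholds of the movement-event segmenter."""

    start_speed_mm_s: float = 0.5
    stop_speed_mm_s: float = 0.1
    window_frames: int = 10

    def __post_init__(self):
        if not (0 <= self.stop_speed_mm_s < self.start_speed_mm_s):
            raise ValueError("need 0 <= stop_speed < start_speed")
        if self.window_frames < 1:
            raise ValueError("window_frames must be >= 1")


@dataclass(frozen=True)
class MovementEvent:
    state: str  # "moving" or "not_moving"
    start_time_s: float
    end_time_s: float

    @property
    def duration_s(self) -> float:
        return self.end_time_s - self.start_time_s


def compute_speed(track: Track, cal: Calibration | None = None) -> np.ndarray:
    """Per-sample speed (mm/s): step distance over step time.

    The first sample has speed 0; steps involving an invalid (NaN)
    position contribute 0. ``cal`` is accepted for interface symmetry
    but positions are already in mm.
    """
    if len(track) < 2:
        return np.zeros(len(track))
    dts = np.diff(track.time_s)
    if (dts <= 0).any():
        raise ValueError("track timestamps must be strictly increasing")
    dx = np.diff(track.x_mm)
    dy = np.diff(track.y_mm)
    step = np.hypot(dx, dy)
    speed = np.zeros(len(track))
    speed[1:] = np.where(np.isnan(step), 0.0, step / dts)
    return speed


def _trailing_means(speeds: np.ndarray, window: int) -> np.ndarray:
    """Fixed-denominator trailing mean; pre-series slots count as zero."""
    c = np.concatenate([[0.0], np.cumsum(speeds)])
    lo = np.maximum(np.arange(1, len(speeds) + 1) - window, 0)
    return (c[1:] - c[lo]) / window


def moving_state_array(speeds: np.ndarray, params: MovementParams = MovementParams()) -> np.ndarray:
    """Boolean per-sample moving state under the hysteresis rule."""
    n = len(speeds)
    if n == 0:
        return np.zeros(0, dtype=bool)
    if n < params.window_frames:
        warnings.warn(
            "speed series shorter than the averaging window; "
            "whole recording classified as not moving"
        )
        return np.zeros(n, dtype=bool)
    wm = _trailing_means(np.asarray(speeds, dtype=float), params.window_frames)
    out = np.empty(n, dtype=bool)
    moving = False
    start, stop = params.start_speed_mm_s, params.stop_speed_mm_s
    for i in range(n):
        if not moving and wm[i] > start:
            moving = True
        elif moving and wm[i] < stop:
            moving = False
        out[i] = moving
    return out


def segment_movement(
    speeds: np.ndarray,
    params: MovementParams = MovementParams(),
    times_s: np.ndarray | None = None,
    dt_s: float = 1.0,
) -> list[MovementEvent]:
    """Alternating moving/not-moving events tiling the recording.

    Each sample owns the interval [t_i, t_i + dt); events are maximal
    runs of the per-sample state, so their durations sum exactly to
    n_samples * dt. The event open at the end of the recording is
    closed at the final sample regardless of window state.
    """
    state = moving_state_array(speeds, params)
    n = len(state)
    if n == 0:
        return []
    if times_s is None:
        times_s = np.arange(n) * dt_s
    else:
        times_s = np.asarray(times_s, dtype=float)
        dt_s = times_s[1] - times_s[0] if n > 1 else dt_s
    events = []
    run_start = 0
    for i in range(1, n + 1):
        if i == n or state[i] != state[run_start]:
            events.append(
                MovementEvent(
                    "moving" if state[run_start] else "not_moving",
                    float(times_s[run_start]),
                    float(times_s[i - 1] + dt_s),
                )
            )
            run_start = i
    return events


def summarize_behavior(
    track: Track,
    zones: list[Zone],
    cal: Calibration,
    params: MovementParams = MovementParams(),
    bin_width_s: float | None = None,
) -> pd.DataFrame:
    """Per-subject behavioral summary, optionally per time bin.

    Returns one row per bin (a single row when ``bin_width_s`` is
    None) with columns: arena_id, bin_start_s, duration per zone,
    duration moving / not moving (overall and per zone), activity
    ratio (moving / not moving, NaN when not moving is zero),
    distance moved, movement velocity (distance while moving over
    moving duration) and detected duration. Durations count samples
    with a valid position times the frame period, so zone durations
    and moving + not-moving both sum exactly to the detected duration.
    Bins are half-open [t, t + bin), anchored at the recording start.
    """
    n = len(track)
    dt = cal.dt_s
    speeds = compute_speed(track, cal)
    moving = moving_state_array(speeds, params)
    zone_of = assign_zones(track.positions_mm, zones)
    valid = track.valid
    step = np.zeros(n)
    if n > 1:
        s = np.hypot(np.diff(track.x_mm), np.diff(track.y_mm))
        step[1:] = np.where(np.isnan(s), 0.0, s)

    if bin_width_s is None:
        bin_idx = np.zeros(n, dtype=int)
        bin_starts = [float(track.time_s[0]) if n else 0.0]
    else:
        t0 = track.time_s[0] if n else 0.0
        bin_idx = ((track.time_s - t0) // bin_width_s).astype(int)
        bin_starts = [float(t0 + b * bin_width_s) for b in range(bin_idx.max() + 1 if n else 0)]

    zone_labels = sorted({z.label for z in zones}, key=_zone_key)
    rows = []
    for b, bstart in enumerate(bin_starts):
        sel = (bin_idx == b) & valid
        row: dict = {"arena_id": track.arena_id, "bin_start_s": bstart}
        for lab in zone_labels:
            in_z = sel & (zone_of == lab)
            row[f"duration_{_short(lab)}_s"] = in_z.sum() * dt
            row[f"duration_moving_{_short(lab)}_s"] = (in_z & moving).sum() * dt
            row[f"duration_not_moving_{_short(lab)}_s"] = (in_z & ~moving).sum() * dt
        dur_mov = (sel & moving).sum() * dt
        dur_not = (sel & ~moving).sum() * dt
        dist = float(step[bin_idx == b].sum())
        dist_moving = float(step[sel & moving].sum())
        row.update(
            duration_moving_s=dur_mov,
            duration_not_moving_s=dur_not,
            activity_ratio=(dur_mov / dur_not) if dur_not > 0 else math.nan,
            distance_mm=dist,
            movement_velocity_mm_s=(dist_moving / dur_mov) if dur_mov > 0 else math.nan,
            detected_duration_s=sel.sum() * dt,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _short(label: str) -> str:
    return {"reference_leaf": "ref", "test_leaf": "test", "off_leaf": "off"}[label]


def _zone_key(label: str) -> int:
    return ["reference_leaf", "test_leaf", "off_leaf"].index(label)


def preference_proportion(
    summary: pd.Series | pd.DataFrame,
    denominator: str = "total_time",
    zone: str = "ref",
) -> float:
    """Proportion of time in one leaf zone.

    ``denominator`` is ``total_time`` (detected duration; the screening
    metric) or ``on_leaf_time`` (time on either leaf). NaN when the
    denominator is zero.
    """
    if isinstance(summary, pd.DataFrame):
        if len(summary) != 1:
            raise ValueError("pass a single summary row (or aggregate bins first)")
        summary = summary.iloc[0]
    num = float(summary[f"duration_{zone}_s"])
    if denominator == "total_time":
        den = float(summary["detected_duration_s"])
    elif denominator == "on_leaf_time":
        den = float(summary["duration_ref_s"] + summary["duration_test_s"])
    else:
        raise ValueError("denominator must be 'total_time' or 'on_leaf_time'")
    return num / den if den > 0 else math.nan


def validate_against_reference(
    auto_values,
    reference_values,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation of an automatically scored parameter with reference
    (e.g. manually annotated) values, paired by arena.

    Returns (r, r^2). Needs at least 3 pairs.
    """
    a = np.asarray(auto_values, dtype=float)
    b = np.asarray(reference_values, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired inputs differ in length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    if method == "pearson":
        r = sps.pearsonr(a, b).statistic
    elif method == "spearman":
        r = sps.spearmanr(a, b).statistic
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), float(r**2)
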