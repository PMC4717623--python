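"""Trajectory assembly: one track per arena from per-frame detections.

Each arena holds a single sealed-in subject, so linking reduces to
candidate selection (nearest to the last accepted position) plus a
missing-sample policy for frames with no detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Track", "GapPolicy", "link_track", "qc_filter_dead", "path_length"]


@dataclass
class Track:
    """Time-stamped positions of one arena's subject.

    ``detected`` marks frames with an accepted detection; ``imputed``
    marks gap-filled samples (imputed implies not detected). Frames
    that are neither detected nor imputed carry NaN positions.
    """

    arena_id: int
    frame_index: np.ndarray
    time_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    detected: np.ndarray
    imputed: np.ndarray

    def __post_init__(self):
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        n = len(self.frame_index)
        for name in ("time_s", "x_mm", "y_mm", "detected", "imputed"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"track field {name} has inconsistent length")
        if n > 1 and not (np.diff(self.frame_index) > 0).all():
            raise ValueError("frame indices must be strictly increasing")
        if (self.imputed & self.detected).any():
            raise ValueError("a sample cannot be both detected and imputed")

    def __len__(self) -> int:
        return len(self.frame_index)

    @property
    def valid(self) -> np.ndarray:
        """Samples with a usable position (detected or imputed)."""
        return self.detected | self.imputed

    @property
    def positions_mm(self) -> np.ndarray:
        return np.column_stack([self.x_mm, self.y_mm])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "arena_id": self.arena_id,
                "frame": self.frame_index,
                "time_s": self.time_s,
                "x_mm": self.x_mm,
                "y_mm": self.y_mm,
                "detected": self.detected,
                "imputed": self.imputed,
            }
        )


@dataclass(frozen=True)
class GapPolicy:
    """Missing-sample policy.

    Up to ``max_gap_frames`` consecutive missed frames are imputed
    (``hold_last`` repeats the last position; ``linear`` interpolates
    once the gap closes); longer gaps stay undetected. The default of
    14 frames is about 4 s at 3.5 frames/s. A trailing gap never
    closes, so it is held (up to the same length) in either mode.
    """

    max_gap_frames: int = 14
    mode: str = "hold_last"  # or "linear"

    def __post_init__(self):
        if self.mode not in ("hold_last", "linear"):
            raise ValueError("gap mode must be 'hold_last' or 'linear'")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be non-negative")


def link_track(
    detections_by_frame,
    arena_id: int,
    gap_policy: GapPolicy = GapPolicy(),
    n_frames: int | None = None,
    frame_rate_hz: float = 3.5,
    arena_center_mm=(0.0, 0.0),
) -> Track:
    """Assemble one track from per-frame candidate detections.

    ``detections_by_frame`` maps frame index -> list of detections
    (anything with ``x_mm``/``y_mm`` attributes or (x, y) pairs; an
    ``area_px`` attribute breaks distance ties, larger first, then
    lower list index). Per frame the candidate nearest the last
    accepted position is chosen (nearest the arena center on the first
    frame). An empty input yields an empty track.
    """
    if n_frames is None:
        n_frames = (max(detections_by_frame) + 1) if detections_by_frame else 0
    dt = 1.0 / frame_rate_hz
    frames = np.arange(n_frames)
    x = np.full(n_frames, np.nan)
    y = np.full(n_frames, np.nan)
    detected = np.zeros(n_frames, dtype=bool)
    imputed = np.zeros(n_frames, dtype=bool)

    last_pos = np.asarray(arena_center_mm, dtype=float)
    have_fix = False
    gap: list[int] = []
    for f in range(n_frames):
        cands = detections_by_frame.get(f, [])
        if cands:
            best = min(
                range(len(cands)),
                key=lambda i: (
                    _dist(_xy(cands[i]), last_pos),
                    -getattr(cands[i], "area_px", 0),
                    i,
                ),
            )
            px, py = _xy(cands[best])
            if gap and len(gap) <= gap_policy.max_gap_frames and have_fix:
                _fill_gap(x, y, imputed, gap, gap_policy.mode, (px, py))
            gap = []
            x[f], y[f] = px, py
            detected[f] = True
            last_pos = np.array([px, py])
            have_fix = True
        else:
            gap.append(f)
    # trailing gap: hold the last fix
    if gap and len(gap) <= gap_policy.max_gap_frames and have_fix:
        _fill_gap(x, y, imputed, gap, "hold_last", None)

    return Track(arena_id, frames, frames * dt, x, y, detected, imputed)


def _xy(d):
    if hasattr(d, "x_mm"):
        return float(d.x_mm), float(d.y_mm)
    return float(d[0]), float(d[1])


def _dist(a, b):
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def _fill_gap(x, y, imputed, gap, mode, next_pos):
    f0 = gap[0] - 1  # last frame with a position
    if f0 < 0:
        return
    if mode == "hold_last" or next_pos is None:
        for f in gap:
            x[f], y[f] = x[f0], y[f0]
            imputed[f] = True
    else:  # linear interpolation between the two closing fixes
        f1 = gap[-1] + 1
        for f in gap:
            w = (f - f0) / (f1 - f0)
            x[f] = x[f0] + w * (next_pos[0] - x[f0])
            y[f] = y[f0] + w * (next_pos[1] - y[f0])
            imputed[f] = True


def path_length(track: Track) -> float:
    """Total path length (mm) over consecutive valid positions."""
    v = track.valid
    xs, ys = track.x_mm[v], track.y_mm[v]
    if len(xs) < 2:
        return 0.0
    return float(np.hypot(np.diff(xs), np.diff(ys)).sum())


def qc_filter_dead(
    tracks: list[Track], min_total_movement_mm: float = 1.4
) -> tuple[list[Track], list[Track]]:
    """Discard subjects that never moved (considered dead).

    A track whose total path length over the whole recording is below
    ``min_total_movement_mm`` (default: one body length) is discarded.
    Returns (kept, discarded); the two lists partition the input.
    """
    kept, discarded = [], []
    for t in tracks:
        (kept if path_length(t) >= min_total_movement_mm else discarded).append(t)
    return kept, discarded
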