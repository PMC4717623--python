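"""Per-frame subject detection against a dynamic background model.

Backlit wells image the subject as a compact dark blob. Detection is
dark-contrast thresholding of (background - frame), optional binary
median smoothing, 8-connected component extraction and size filtering,
reporting each surviving component's centroid in mm.

"Dynamic subtraction" is an exponential running-average background
with a configurable per-frame rate, optionally frozen under pixels
currently occupied by a subject so the model does not absorb the
animal during long feeding bouts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import Calibration, PlateLayout

__all__ = [
    "DetectionParams",
    "Detection",
    "update_background",
    "estimate_background",
    "detect_subjects",
    "arena_masks",
    "detect_stack",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds of the blob detector.

    Defaults follow a live multi-arena insect setup: dark contrast
    8-255 gray levels, subject size 10-160 px, medium smoothing.
    """

    contrast_min: int = 8
    contrast_max: int = 255
    size_min_px: int = 10
    size_max_px: int = 160
    smoothing: str = "medium"  # or "none"
    background_update_rate: float = 0.05

    def __post_init__(self):
        if not (0 < self.contrast_min <= self.contrast_max <= 255):
            raise ValueError("need 0 < contrast_min <= contrast_max <= 255")
        if not (0 < self.size_min_px <= self.size_max_px):
            raise ValueError("need 0 < size_min_px <= size_max_px")
        if self.smoothing not in ("none", "medium"):
            raise ValueError("smoothing must be 'none' or 'medium'")
        if not (0 < self.background_update_rate <= 1):
            raise ValueError("background_update_rate must be in (0, 1]")


@dataclass(frozen=True)
class Detection:
    """A single accepted blob in one frame of one arena."""

    arena_id: int
    frame_index: int
    x_mm: float
    y_mm: float
    area_px: int


def update_background(
    background: np.ndarray,
    frame: np.ndarray,
    rate: float,
    freeze_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Exponential running-average update of the background model.

    ``new = (1 - rate) * background + rate * frame`` per pixel; pixels
    in ``freeze_mask`` keep their old value. Rate 1 replaces the
    background with the frame; a static scene is a fixed point.
    """
    if background.shape != frame.shape:
        raise ValueError("background and frame shapes differ")
    if not (0 < rate <= 1):
        raise ValueError("rate must be in (0, 1]")
    bg = np.asarray(background, dtype=float)
    new = (1.0 - rate) * bg + rate * np.asarray(frame, dtype=float)
    if freeze_mask is not None:
        new[freeze_mask] = bg[freeze_mask]
    return new


def estimate_background(frames: list[np.ndarray]) -> np.ndarray:
    """Pixelwise median over a sample of frames (robust initializer)."""
    return np.median(np.stack([np.asarray(f, dtype=float) for f in frames]), axis=0)


def detect_subjects(
    frame: np.ndarray,
    background: np.ndarray,
    params: DetectionParams,
    arena_mask: np.ndarray,
    cal: Calibration,
    arena_id: int = 0,
    frame_index: int = 0,
) -> list[Detection]:
    """Detect dark blobs in one arena of one frame.

    Candidate pixels have ``background - frame`` within
    [contrast_min, contrast_max] inside the arena mask; "medium"
    smoothing applies one 3x3 binary median pass; 8-connected
    components outside [size_min, size_max] px are discarded. Each
    surviving component is reported with its pixel centroid converted
    to mm. An empty list is a valid result.
    """
    diff = np.asarray(background, dtype=float) - np.asarray(frame, dtype=float)
    cand = (diff >= params.contrast_min) & (diff <= params.contrast_max) & arena_mask
    if params.smoothing == "medium":
        cand = ndimage.median_filter(cand, size=3)
    labels, n = ndimage.label(cand, structure=_EIGHT)
    if n == 0:
        return []
    out = []
    areas = ndimage.sum_labels(cand, labels, index=np.arange(1, n + 1))
    coms = ndimage.center_of_mass(cand, labels, index=np.arange(1, n + 1))
    for area, (cy, cx) in zip(areas, coms):
        if params.size_min_px <= area <= params.size_max_px:
            x_mm, y_mm = cal.px_to_mm([cx, cy])
            out.append(Detection(arena_id, frame_index, float(x_mm), float(y_mm), int(area)))
    return out


def arena_masks(layout: PlateLayout, cal: Calibration, margin_mm: float = 0.3) -> dict:
    """Boolean well-interior mask per arena id, at image resolution."""
    H, W = cal.image_height_px, cal.image_width_px
    yy, xx = np.mgrid[0:H, 0:W]
    xm = (xx + 0.5) / cal.px_per_mm
    ym = (yy + 0.5) / cal.px_per_mm
    r = layout.well_diameter_mm / 2.0 + margin_mm
    masks = {}
    for aid, (cx, cy) in enumerate(layout.well_centers):
        masks[aid] = (xm - cx) ** 2 + (ym - cy) ** 2 <= r**2
    return masks


def detect_stack(
    frames,
    layout: PlateLayout,
    cal: Calibration,
    params: DetectionParams = DetectionParams(),
    background: np.ndarray | None = None,
    freeze_under_subject: bool = True,
) -> dict[int, dict[int, list[Detection]]]:
    """Run detection over a frame stack for every arena.

    ``frames`` yields (frame_index, image). If no initial background
    is given the first frame is used (with the usual caveat that any
    subject present is absorbed until the model adapts). Returns
    {arena_id: {frame_index: [Detection, ...]}}.
    """
    masks = arena_masks(layout, cal)
    out: dict[int, dict[int, list[Detection]]] = {aid: {} for aid in masks}
    bg = None if background is None else np.asarray(background, dtype=float)
    for f, img in frames:
        if bg is None:
            bg = np.asarray(img, dtype=float)
        occupied = np.zeros(img.shape, dtype=bool)
        for aid, mask in masks.items():
            dets = detect_subjects(img, bg, params, mask, cal, arena_id=aid, frame_index=f)
            out[aid][f] = dets
            if freeze_under_subject and dets:
                diff = bg - img
                occupied |= mask & (diff >= params.contrast_min)
        bg = update_background(
            bg, img, params.background_update_rate,
            freeze_mask=occupied if freeze_under_subject else None,
        )
    return out
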