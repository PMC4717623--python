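"""Spatial conventions for multi-well arena imaging.

Pixel/millimetre calibration, plate layouts, zone polygons and
point-in-zone assignment. The coordinate convention throughout the
package is: origin at the top-left of the image, x rightward, y
downward, millimetres after calibration. Positions refer to pixel
centers, i.e. the center of pixel column ``i`` lies at
``(i + 0.5) / px_per_mm`` mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import Point, Polygon

__all__ = [
    "Calibration",
    "PlateLayout",
    "Zone",
    "ZoneConfigError",
    "ZONE_LABELS",
    "make_calibration",
    "subject_pixel_area",
    "assign_zone",
    "assign_zones",
    "half_disc_zones",
    "make_plate_layout",
]

#: Fixed precedence for boundary ties: leaf zones before the off-leaf zone.
ZONE_LABELS = ("reference_leaf", "test_leaf", "off_leaf")


class ZoneConfigError(ValueError):
    """Raised when a zone configuration is internally inconsistent."""


@dataclass(frozen=True)
class Calibration:
    """Mapping between image pixels and physical millimetres.

    Calibration is isotropic: horizontal and vertical px/mm must agree
    within 1 % or construction fails (anisotropy is rejected rather
    than averaged).
    """

    image_width_px: int
    image_height_px: int
    field_width_mm: float
    field_height_mm: float
    frame_rate_hz: float

    @property
    def px_per_mm(self) -> float:
        return self.image_width_px / self.field_width_mm

    @property
    def px_per_mm2(self) -> float:
        """Pixels per square millimetre (e.g. 163.84 at 12.8 px/mm)."""
        return self.px_per_mm**2

    @property
    def pixel_width_um(self) -> float:
        return 1000.0 / self.px_per_mm

    @property
    def dt_s(self) -> float:
        """Frame period in seconds."""
        return 1.0 / self.frame_rate_hz

    def mm_to_px(self, xy_mm):
        """Convert mm coordinates to (fractional) pixel indices."""
        return np.asarray(xy_mm, dtype=float) * self.px_per_mm - 0.5

    def px_to_mm(self, xy_px):
        """Convert pixel indices (pixel centers) to mm coordinates."""
        return (np.asarray(xy_px, dtype=float) + 0.5) / self.px_per_mm


def make_calibration(
    image_width_px: int,
    image_height_px: int,
    field_width_mm: float,
    field_height_mm: float,
    frame_rate_hz: float,
) -> Calibration:
    """Build a :class:`Calibration`, rejecting anisotropic setups.

    Raises
    ------
    ValueError
        If any argument is non-positive, or if the horizontal and
        vertical px/mm scales disagree by more than 1 %.
    """
    args = (image_width_px, image_height_px, field_width_mm, field_height_mm, frame_rate_hz)
    if any(a <= 0 for a in args):
        raise ValueError("all calibration arguments must be positive")
    sx = image_width_px / field_width_mm
    sy = image_height_px / field_height_mm
    if abs(sx - sy) / sx > 0.01:
        raise ValueError(
            f"anisotropic calibration: horizontal {sx:.4f} px/mm vs "
            f"vertical {sy:.4f} px/mm differ by more than 1%"
        )
    return Calibration(
        image_width_px=int(image_width_px),
        image_height_px=int(image_height_px),
        field_width_mm=float(field_width_mm),
        field_height_mm=float(field_height_mm),
        frame_rate_hz=float(frame_rate_hz),
    )


def subject_pixel_area(length_mm: float, width_mm: float, cal: Calibration) -> int:
    """Expected pixel footprint of a length x width subject in full view.

    Computed as ``round(length * width * px_per_mm^2)``; a 1.4 x 0.3 mm
    insect at 12.8 px/mm covers about 69 pixels.
    """
    if length_mm < 0 or width_mm < 0:
        raise ValueError("subject dimensions must be non-negative")
    return int(round(length_mm * width_mm * cal.px_per_mm2))


@dataclass(frozen=True)
class PlateLayout:
    """Grid of circular wells (arenas) on the imaged field."""

    n_rows: int
    n_cols: int
    well_diameter_mm: float
    well_centers: tuple  # of (x_mm, y_mm)

    @property
    def n_wells(self) -> int:
        return len(self.well_centers)

    def arena_ids(self) -> list[int]:
        return list(range(self.n_wells))


def make_plate_layout(
    n_rows: int,
    n_cols: int,
    well_diameter_mm: float,
    field_width_mm: float,
    field_height_mm: float,
    pitch_mm: float | None = None,
) -> PlateLayout:
    """Lay out an ``n_rows x n_cols`` grid of wells centered on the field.

    ``pitch_mm`` defaults to the largest center spacing that keeps all
    wells inside the field with a half-well margin. Wells must fit
    inside the field and must not overlap.
    """
    r = well_diameter_mm / 2.0
    if pitch_mm is None:
        px = (field_width_mm - well_diameter_mm - r) / max(n_cols - 1, 1)
        py = (field_height_mm - well_diameter_mm - r) / max(n_rows - 1, 1)
        pitch_mm = min(px, py)
    if pitch_mm < well_diameter_mm:
        raise ValueError("wells overlap: pitch smaller than well diameter")
    w = (n_cols - 1) * pitch_mm
    h = (n_rows - 1) * pitch_mm
    x0 = (field_width_mm - w) / 2.0
    y0 = (field_height_mm - h) / 2.0
    centers = []
    for i in range(n_rows):
        for j in range(n_cols):
            cx = x0 + j * pitch_mm
            cy = y0 + i * pitch_mm
            if cx - r < 0 or cx + r > field_width_mm or cy - r < 0 or cy + r > field_height_mm:
                raise ValueError("well outside field; reduce pitch or well count")
            centers.append((cx, cy))
    return PlateLayout(n_rows, n_cols, float(well_diameter_mm), tuple(centers))


@dataclass(frozen=True)
class Zone:
    """A labelled polygonal zone inside one arena, in mm coordinates."""

    arena_id: int
    label: str  # one of ZONE_LABELS
    polygon: tuple  # of (x_mm, y_mm), >= 3 vertices, simple
    scheme: str  # "two_zone" or "three_zone"

    def __post_init__(self):
        if self.label not in ZONE_LABELS:
            raise ZoneConfigError(f"unknown zone label {self.label!r}")
        if self.scheme not in ("two_zone", "three_zone"):
            raise ZoneConfigError(f"unknown zone scheme {self.scheme!r}")
        if len(self.polygon) < 3:
            raise ZoneConfigError("zone polygon needs at least 3 vertices")
        poly = Polygon(self.polygon)
        if not poly.is_valid or not poly.is_simple:
            raise ZoneConfigError(f"zone polygon for {self.label!r} is not simple")

    @property
    def shape(self) -> Polygon:
        return Polygon(self.polygon)


def _ordered(zones: Sequence[Zone]) -> list[Zone]:
    """Zones sorted by the fixed precedence (leaf zones before off_leaf)."""
    return sorted(zones, key=lambda z: ZONE_LABELS.index(z.label))


def _check_one_scheme(zones: Sequence[Zone]) -> None:
    schemes = {z.scheme for z in zones}
    arenas = {z.arena_id for z in zones}
    if len(schemes) > 1:
        raise ZoneConfigError("zones from multiple schemes passed together")
    if len(arenas) > 1:
        raise ZoneConfigError("zones from multiple arenas passed together")


def assign_zone(point_mm, zones: Sequence[Zone]) -> str | None:
    """Assign a point to a zone of one arena/scheme, or ``None``.

    Boundary points count as inside; when a point lies on a shared
    boundary, the zone earlier in the fixed precedence
    (reference_leaf, test_leaf, off_leaf) wins. A point strictly inside
    two zones of one scheme is a configuration error.
    """
    _check_one_scheme(zones)
    p = Point(point_mm)
    strictly_in = [z for z in zones if z.shape.contains(p)]
    # off_leaf is allowed to underlie the leaf zones (precedence resolves it)
    strict_leaf = [z for z in strictly_in if z.label != "off_leaf"]
    if len(strict_leaf) > 1:
        raise ZoneConfigError(
            f"point {tuple(point_mm)} lies strictly inside overlapping zones "
            f"{[z.label for z in strict_leaf]}"
        )
    for z in _ordered(zones):
        if z.shape.covers(p):
            return z.label
    return None


def assign_zones(points_mm: np.ndarray, zones: Sequence[Zone]) -> np.ndarray:
    """Vectorized zone assignment for an (n, 2) array of mm points.

    Returns an object array of labels; ``None`` where no zone covers the
    point (possible in the two-zone scheme). NaN positions map to None.
    Same precedence rule as :func:`assign_zone`.
    """
    _check_one_scheme(zones)
    pts = np.asarray(points_mm, dtype=float)
    labels = np.full(len(pts), None, dtype=object)
    valid = ~np.isnan(pts).any(axis=1)
    if not valid.any():
        return labels
    geoms = shapely.points(pts[valid])
    out = np.full(valid.sum(), None, dtype=object)
    # later-precedence zones first so earlier ones overwrite them
    for z in reversed(_ordered(zones)):
        covered = shapely.covers(z.shape, geoms)
        out[covered] = z.label
    labels[valid] = out
    return labels


def _half_disc(center, radius, side: str, n_vertices: int = 32) -> tuple:
    """Polygonal half-disc (flat edge vertical through the center)."""
    cx, cy = center
    if side == "left":
        angles = np.linspace(math.pi / 2, 3 * math.pi / 2, n_vertices)
    elif side == "right":
        angles = np.linspace(-math.pi / 2, math.pi / 2, n_vertices)
    else:
        raise ValueError("side must be 'left' or 'right'")
    pts = [(cx + radius * math.cos(a), cy + radius * math.sin(a)) for a in angles]
    return tuple(pts)


def _circle(center, radius, n_vertices: int = 48) -> tuple:
    cx, cy = center
    angles = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    return tuple((cx + radius * math.cos(a), cy + radius * math.sin(a)) for a in angles)


def half_disc_zones(
    arena_id: int,
    well_center,
    well_diameter_mm: float,
    disc_diameter_mm: float = 6.0,
    scheme: str = "three_zone",
    reference_side: str = "left",
) -> list[Zone]:
    """Standard two-choice arena zones: two half leaf discs in one well.

    The two halves of a punched leaf disc sit flat-edge to flat-edge at
    the well center, reference on ``reference_side``. In the three-zone
    scheme an off_leaf zone spanning the whole well underlies them
    (precedence assigns leaf points to the leaf zones first), so the
    scheme jointly covers the arena. The two-zone scheme has only the
    two halves, emulating coarse half/half annotation.
    """
    r = disc_diameter_mm / 2.0
    other = "right" if reference_side == "left" else "left"
    # small gap between the two flat edges so interiors never overlap
    cx, cy = well_center
    eps = 1e-6
    ref_c = (cx - eps, cy) if reference_side == "left" else (cx + eps, cy)
    test_c = (cx + eps, cy) if reference_side == "left" else (cx - eps, cy)
    zones = [
        Zone(arena_id, "reference_leaf", _half_disc(ref_c, r, reference_side), scheme),
        Zone(arena_id, "test_leaf", _half_disc(test_c, r, other), scheme),
    ]
    if scheme == "three_zone":
        zones.append(
            Zone(arena_id, "off_leaf", _circle(well_center, well_diameter_mm / 2.0), scheme)
        )
    return zones
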