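"""File formats: track CSV, zone configuration, summaries, provenance.

All tabular data are plain CSV; zone and run configuration are JSON.
The track CSV schema (columns ``arena_id, frame, time_s, x_mm, y_mm,
detected, imputed``) is also the entry point for users bringing
trajectories exported from third-party trackers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Zone
from .track import Track

__all__ = [
    "TRACK_COLUMNS",
    "read_tracks",
    "write_tracks",
    "read_zones",
    "write_zones",
    "zones_to_csv",
]

TRACK_COLUMNS = ["arena_id", "frame", "time_s", "x_mm", "y_mm", "detected", "imputed"]


class SchemaError(ValueError):
    """A file does not conform to its documented schema."""


def write_tracks(tracks: list[Track], path) -> None:
    df = pd.concat([t.to_dataframe() for t in tracks], ignore_index=True)
    df.to_csv(path, index=False)


def read_tracks(path) -> list[Track]:
    """Read a track CSV into one :class:`Track` per arena.

    Raises :class:`SchemaError` naming the missing column or the
    offending line on malformed input.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"track file {path} is missing required column(s): {missing}")
    for col in ("frame", "time_s", "x_mm", "y_mm"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise SchemaError(f"track file {path}, line {line}: non-numeric value in {col!r}")
    tracks = []
    for aid, grp in df.groupby("arena_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            Track(
                arena_id=int(aid),
                frame_index=grp["frame"].to_numpy(int),
                time_s=grp["time_s"].to_numpy(float),
                x_mm=grp["x_mm"].to_numpy(float),
                y_mm=grp["y_mm"].to_numpy(float),
                detected=grp["detected"].astype(bool).to_numpy(),
                imputed=grp["imputed"].astype(bool).to_numpy(),
            )
        )
    return tracks


def write_zones(zone_map: dict[int, list[Zone]], path) -> None:
    """Write per-arena zone polygons as JSON (mm coordinates)."""
    doc = {
        "format": "arenatrack-zones-v1",
        "arenas": {
            str(aid): [
                {"label": z.label, "scheme": z.scheme, "polygon": [list(p) for p in z.polygon]}
                for z in zones
            ]
            for aid, zones in zone_map.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_zones(path) -> dict[int, list[Zone]]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "arenatrack-zones-v1":
        raise SchemaError(f"{path}: not an arenatrack zone file")
    out = {}
    for aid, zones in doc["arenas"].items():
        out[int(aid)] = [
            Zone(int(aid), z["label"], tuple(map(tuple, z["polygon"])), z["scheme"])
            for z in zones
        ]
    return out


def zones_to_csv(zone_map: dict[int, list[Zone]], path) -> None:
    """Flat CSV export of zone vertices for audit."""
    rows = []
    for aid, zones in zone_map.items():
        for z in zones:
            for i, (x, y) in enumerate(z.polygon):
                rows.append(
                    {"arena_id": aid, "label": z.label, "scheme": z.scheme,
                     "vertex": i, "x_mm": x, "y_mm": y}
                )
    pd.DataFrame(rows).to_csv(path, index=False)
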