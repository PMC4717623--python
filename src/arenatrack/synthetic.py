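"""Synthetic two-choice arenas: behavioral-state agents and frame rendering.

The generator plays two roles: it supplies ground truth against which
the detection/tracking/behavior stages are validated, and it emulates
the study conditions of a parallel two-choice host-plant preference
assay (one ~1.4 x 0.3 mm insect per backlit well, two half leaf discs
per well, multi-hour recordings at a few frames per second).

The behavioral model is a discrete-time Markov chain at frame
resolution over four states -- feeding on the reference leaf, feeding
on the test leaf, walking, and resting off-leaf -- with within-state
Gaussian speeds. Walking is a persistent (correlated heading) random
walk reflected at the well wall; feeding/resting adds only a small
positional jitter, below the movement-stop threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely.geometry import Point
from shapely.ops import nearest_points

from .geometry import Calibration, PlateLayout, Zone, half_disc_zones
from .track import Track

__all__ = [
    "STATES",
    "FEED_REF",
    "FEED_TEST",
    "WALK",
    "OFF_LEAF",
    "AgentParams",
    "GroundTruth",
    "Appearance",
    "simulate_agent",
    "simulate_plate",
    "render_frames",
    "preset_cur3_vs_rmx",
    "preset_no_preference",
]

log = logging.getLogger(__name__)

FEED_REF, FEED_TEST, WALK, OFF_LEAF = 0, 1, 2, 3
STATES = ("feed_ref", "feed_test", "walk", "off_leaf")

#: zone label implied by each behavioral state (walk is unconstrained)
STATE_ZONE = {FEED_REF: "reference_leaf", FEED_TEST: "test_leaf"}


@dataclass(frozen=True)
class AgentParams:
    """Parameters of the behavioral-state agent.

    ``transition`` is a 4x4 row-stochastic per-frame matrix over
    (feed_ref, feed_test, walk, off_leaf). ``preference_bias`` is the
    probability weight toward the test leaf on leaf entry and is only
    used by the preset constructors that build the matrix; the matrix
    itself is authoritative during simulation.
    """

    transition: tuple  # 4x4 nested tuple, rows sum to 1
    walk_speed_mm_s: float = 0.9
    walk_speed_sd_mm_s: float = 0.3
    feed_jitter_mm_s: float = 0.02
    turn_sd_rad: float = 0.6
    preference_bias: float = 0.5
    seed: int = 0

    def __post_init__(self):
        T = np.asarray(self.transition, dtype=float)
        if T.shape != (4, 4) or (T < 0).any():
            raise ValueError("transition must be a non-negative 4x4 matrix")
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if self.walk_speed_mm_s <= 0:
            raise ValueError("walk speed must be positive")
        if self.feed_jitter_mm_s < 0:
            raise ValueError("feed jitter must be non-negative")

    @property
    def transition_matrix(self) -> np.ndarray:
        return np.asarray(self.transition, dtype=float)


@dataclass
class GroundTruth:
    """Per-frame truth for one simulated arena."""

    arena_id: int
    states: np.ndarray  # int codes, one per frame
    positions_mm: np.ndarray  # (n_frames, 2)
    zone_labels: np.ndarray  # object array, zone occupied per frame
    genotype_pair: tuple = ("reference", "test")

    @property
    def state_names(self) -> np.ndarray:
        return np.asarray(STATES, dtype=object)[self.states]


def _chain_matrix(
    dt: float,
    p_leave_walk_per_s: float,
    feed_bout_mean_s: tuple[float, float],
    rest_bout_mean_s: float,
    preference_bias: float,
    p_rest_frac: float = 0.55,
) -> tuple:
    """Build a per-frame transition matrix from bout-scale quantities."""
    p_leave = min(p_leave_walk_per_s * dt, 1.0)
    p_rest = p_leave * p_rest_frac
    p_feed = p_leave - p_rest
    p_ft = p_feed * preference_bias
    p_fr = p_feed - p_ft
    end_fr = min(dt / feed_bout_mean_s[0], 1.0)
    end_ft = min(dt / feed_bout_mean_s[1], 1.0)
    end_off = min(dt / rest_bout_mean_s, 1.0)
    T = np.array(
        [
            [1 - end_fr, 0.0, end_fr, 0.0],
            [0.0, 1 - end_ft, end_ft, 0.0],
            [p_fr, p_ft, 1 - p_leave, p_rest],
            [0.0, 0.0, end_off, 1 - end_off],
        ]
    )
    return tuple(map(tuple, T))


def preset_cur3_vs_rmx(seed: int = 0) -> AgentParams:
    """Two-accession contrast preset (resistant reference vs susceptible test).

    Fitted, not measured: bout scales and the 0.62 entry bias toward the
    test leaf were tuned so that an 8-h run of ~68 agents lands near the
    observed contrast (on-leaf time split roughly 38/62, activity ratio
    roughly twice as high on the reference side, walking speed ~0.7 mm/s).
    """
    return AgentParams(
        transition=_chain_matrix(
            dt=1 / 3.5,
            p_leave_walk_per_s=1 / 45.0,
            feed_bout_mean_s=(280.0, 450.0),
            rest_bout_mean_s=330.0,
            preference_bias=0.53,
        ),
        walk_speed_mm_s=0.7,
        walk_speed_sd_mm_s=0.25,
        preference_bias=0.53,
        seed=seed,
    )


def preset_no_preference(seed: int = 0) -> AgentParams:
    """Null preset: symmetric leaves, no side bias."""
    p = preset_cur3_vs_rmx(seed)
    return replace(
        p,
        transition=_chain_matrix(
            dt=1 / 3.5,
            p_leave_walk_per_s=1 / 45.0,
            feed_bout_mean_s=(350.0, 350.0),
            rest_bout_mean_s=330.0,
            preference_bias=0.5,
        ),
        preference_bias=0.5,
    )


@dataclass
class _ArenaGeom:
    """Prepared per-arena geometry in local (well-center) coordinates."""

    center: tuple
    radius: float
    zones: list  # Zone objects in absolute mm
    ref_poly: object
    test_poly: object

    @classmethod
    def from_zones(cls, center, well_radius, zones):
        by_label = {z.label: z for z in zones}
        return cls(
            center=tuple(center),
            radius=well_radius,
            zones=list(zones),
            ref_poly=by_label["reference_leaf"].shape,
            test_poly=by_label["test_leaf"].shape,
        )


def _nearest_inside(poly, xy) -> np.ndarray:
    """Nearest point of the polygon to xy (itself if already covered)."""
    p = Point(xy)
    if poly.covers(p):
        return np.asarray(xy, float)
    q = nearest_points(poly, p)[0]
    # nudge from the boundary toward the centroid so jitter stays inside
    c = poly.centroid
    out = np.array([q.x, q.y]) + 1e-6 * (np.array([c.x, c.y]) - np.array([q.x, q.y]))
    return out


def simulate_agent(
    params: AgentParams,
    duration_s: float,
    frame_rate_hz: float,
    arena_geometry,
    seed: int | None = None,
    arena_id: int = 0,
    initial_state: int = OFF_LEAF,
) -> tuple[Track, GroundTruth]:
    """Simulate one agent in one arena; one sample per frame.

    ``arena_geometry`` is (well_center_mm, well_radius_mm, zones). The
    agent is confined to the well interior by a reflective boundary.
    Identical seed gives identical output.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    center, radius, zones = arena_geometry
    geom = _ArenaGeom.from_zones(center, radius, zones)
    tracks, truths = _simulate_many(
        params, duration_s, frame_rate_hz, [geom], [arena_id],
        seed=params.seed if seed is None else seed,
        initial_state=initial_state,
    )
    return tracks[0], truths[0]


def simulate_plate(
    params: AgentParams,
    layout: PlateLayout,
    cal: Calibration,
    duration_s: float,
    n_arenas: int | None = None,
    seed: int | None = None,
    disc_diameter_mm: float = 6.0,
    scheme: str = "three_zone",
    alternate_reference_side: bool = True,
) -> tuple[list[Track], list[GroundTruth], dict[int, list[Zone]]]:
    """Simulate one agent per well for the first ``n_arenas`` wells.

    The reference-leaf side alternates by plate row when
    ``alternate_reference_side`` (position-bias control). Returns the
    tracks, the ground truths, and the zone map used.
    """
    if n_arenas is None:
        n_arenas = layout.n_wells
    n_arenas = min(n_arenas, layout.n_wells)
    r = layout.well_diameter_mm / 2.0
    geoms, ids, zone_map = [], [], {}
    for a in range(n_arenas):
        row = a // layout.n_cols
        side = "left" if (not alternate_reference_side or row % 2 == 0) else "right"
        zones = half_disc_zones(
            a, layout.well_centers[a], layout.well_diameter_mm,
            disc_diameter_mm=disc_diameter_mm, scheme=scheme, reference_side=side,
        )
        zone_map[a] = zones
        geoms.append(_ArenaGeom.from_zones(layout.well_centers[a], r, zones))
        ids.append(a)
    tracks, truths = _simulate_many(
        params, duration_s, cal.frame_rate_hz, geoms, ids,
        seed=params.seed if seed is None else seed,
    )
    return tracks, truths, zone_map


def _simulate_many(params, duration_s, frame_rate_hz, geoms, arena_ids, seed,
                   initial_state=OFF_LEAF):
    """Vectorized multi-arena simulation (frame loop, agents in parallel)."""
    rng = np.random.default_rng(seed)
    n = len(geoms)
    dt = 1.0 / frame_rate_hz
    n_frames = int(round(duration_s * frame_rate_hz))
    if n_frames < 1:
        raise ValueError("duration shorter than one frame")
    T = params.transition_matrix
    cumT = np.cumsum(T, axis=1)

    centers = np.array([g.center for g in geoms])
    radii = np.array([g.radius for g in geoms])
    ref_polys = np.array([g.ref_poly for g in geoms], dtype=object)
    test_polys = np.array([g.test_poly for g in geoms], dtype=object)
    # confine slightly inside the wall so polygonal well zones still cover
    conf_r = radii - 0.05

    # local coordinates relative to each well center
    pos = np.zeros((n, 2))
    ang0 = rng.uniform(0, 2 * math.pi, n)
    rad0 = conf_r * np.sqrt(rng.uniform(0.5, 1.0, n))
    pos[:, 0] = rad0 * np.cos(ang0)
    pos[:, 1] = rad0 * np.sin(ang0)
    heading = rng.uniform(0, 2 * math.pi, n)
    state = np.full(n, initial_state, dtype=np.int64)
    # initial position must be consistent with the initial state
    for i in range(n):
        if state[i] in STATE_ZONE:
            poly = geoms[i].ref_poly if state[i] == FEED_REF else geoms[i].test_poly
            pos[i] = _nearest_inside(poly, pos[i] + centers[i]) - centers[i]
        elif state[i] == OFF_LEAF:
            p = Point(pos[i] + centers[i])
            if geoms[i].ref_poly.covers(p) or geoms[i].test_poly.covers(p):
                pos[i] = _off_leaf_point(geoms[i], rng) - centers[i]

    states_out = np.empty((n_frames, n), dtype=np.int64)
    pos_out = np.empty((n_frames, n, 2))
    states_out[0] = state
    pos_out[0] = pos + centers

    jitter_step = params.feed_jitter_mm_s * dt

    for f in range(1, n_frames):
        u = rng.random(n)
        new_state = (u[:, None] < cumT[state]).argmax(axis=1)

        # --- walking agents: persistent random walk ---
        walking = new_state == WALK
        if walking.any():
            nw = int(walking.sum())
            heading[walking] += rng.normal(0.0, params.turn_sd_rad, nw)
            speed = rng.normal(params.walk_speed_mm_s, params.walk_speed_sd_mm_s, nw)
            np.clip(speed, 0.0, None, out=speed)
            step = speed * dt
            pos[walking, 0] += step * np.cos(heading[walking])
            pos[walking, 1] += step * np.sin(heading[walking])
            # reflective boundary: fold radial excursions back inside
            d = np.hypot(pos[walking, 0], pos[walking, 1])
            over = d > conf_r[walking]
            if over.any():
                idx = np.flatnonzero(walking)[over]
                dd = d[over]
                scale = (2 * conf_r[idx] - dd) / dd
                np.clip(scale, 0.0, None, out=scale)
                pos[idx] *= scale[:, None]
                heading[idx] += math.pi  # turn back after bouncing off the wall

        # --- stationary agents: small jitter, confined to their zone ---
        stationary = ~walking
        if stationary.any():
            entered = stationary & (new_state != state)
            staying = stationary & ~entered
            jit = rng.normal(0.0, jitter_step, (n, 2))

            # entries are rare: handle with a small Python loop
            for i in np.flatnonzero(entered):
                st = new_state[i]
                if st in STATE_ZONE:
                    poly = geoms[i].ref_poly if st == FEED_REF else geoms[i].test_poly
                    pos[i] = _nearest_inside(poly, pos[i] + centers[i]) - centers[i]
                else:  # entering OFF_LEAF: leave any leaf polygon
                    p = Point(pos[i] + centers[i])
                    if geoms[i].ref_poly.covers(p) or geoms[i].test_poly.covers(p):
                        pos[i] = _off_leaf_point(geoms[i], rng) - centers[i]

            # staying agents: accept the jitter only if it respects the zone
            if staying.any():
                idx = np.flatnonzero(staying)
                cand = pos[idx] + jit[idx]
                pts = shapely.points(cand + centers[idx])
                st = new_state[idx]
                ok = np.zeros(len(idx), dtype=bool)
                feeding = st != OFF_LEAF
                if feeding.any():
                    polys = np.where(st[feeding] == FEED_REF,
                                     ref_polys[idx[feeding]], test_polys[idx[feeding]])
                    ok[feeding] = shapely.covers(polys, pts[feeding])
                resting = ~feeding
                if resting.any():
                    on_leaf = shapely.covers(ref_polys[idx[resting]], pts[resting]) | \
                        shapely.covers(test_polys[idx[resting]], pts[resting])
                    in_well = np.hypot(cand[resting, 0], cand[resting, 1]) <= conf_r[idx[resting]]
                    ok[resting] = ~on_leaf & in_well
                pos[idx[ok]] = cand[ok]

        state = new_state
        states_out[f] = state
        pos_out[f] = pos + centers

    tracks, truths = [], []
    times = np.arange(n_frames) * dt
    for i, aid in enumerate(arena_ids):
        xy = pos_out[:, i, :]
        tracks.append(
            Track(
                arena_id=aid,
                frame_index=np.arange(n_frames),
                time_s=times.copy(),
                x_mm=xy[:, 0].copy(),
                y_mm=xy[:, 1].copy(),
                detected=np.ones(n_frames, dtype=bool),
                imputed=np.zeros(n_frames, dtype=bool),
            )
        )
        truths.append(
            GroundTruth(
                arena_id=aid,
                states=states_out[:, i].copy(),
                positions_mm=xy.copy(),
                zone_labels=_zone_labels_from_truth(states_out[:, i], xy, geoms[i]),
            )
        )
    return tracks, truths


def _off_leaf_point(geom: _ArenaGeom, rng) -> np.ndarray:
    """Random point in the well but outside both leaf polygons (absolute mm)."""
    cx, cy = geom.center
    for _ in range(200):
        ang = rng.uniform(0, 2 * math.pi)
        rad = (geom.radius - 0.05) * math.sqrt(rng.uniform())
        p = np.array([cx + rad * math.cos(ang), cy + rad * math.sin(ang)])
        q = Point(p)
        if not (geom.ref_poly.covers(q) or geom.test_poly.covers(q)):
            return p
    raise RuntimeError("could not place an off-leaf point; leaves fill the well")


def _zone_labels_from_truth(states, positions, geom: _ArenaGeom) -> np.ndarray:
    """Occupied zone per frame, from positions (vectorized)."""
    pts = shapely.points(positions)
    labels = np.full(len(states), "off_leaf", dtype=object)
    on_test = shapely.covers(geom.test_poly, pts)
    labels[on_test] = "test_leaf"
    on_ref = shapely.covers(geom.ref_poly, pts)
    labels[on_ref] = "reference_leaf"
    return labels


@dataclass(frozen=True)
class Appearance:
    """Gray levels and subject geometry for rendering backlit wells."""

    background_level: int = 200
    leaf_level: int = 130
    subject_level: int = 40
    subject_axes_mm: tuple = (1.4, 0.3)  # full length, full width
    noise_sd: float = 0.0


def render_frames(
    tracks: list[Track],
    layout: PlateLayout,
    cal: Calibration,
    appearance: Appearance = Appearance(),
    seed: int = 0,
    zone_map: dict | None = None,
    frames: range | None = None,
):
    """Render tracks into a stack of grayscale uint8 frames (generator).

    Subjects are drawn as dark ellipses (long axis along the direction
    of motion); leaf zones as mid-gray polygons; optional additive
    Gaussian noise is reproducible by seed. Yields (frame_index, image).
    """
    from skimage.draw import polygon as draw_polygon

    app = appearance
    darkest_bg = min(app.background_level, app.leaf_level if zone_map else app.background_level)
    if app.subject_level >= darkest_bg - 8:
        log.warning(
            "subject gray level %d has little or no dark contrast against "
            "background %d; detection may fail", app.subject_level, darkest_bg,
        )
    H, W = cal.image_height_px, cal.image_width_px
    template = np.full((H, W), app.background_level, dtype=np.uint8)
    if zone_map:
        for zones in zone_map.values():
            for z in zones:
                if z.label == "off_leaf":
                    continue
                v = cal.mm_to_px(np.asarray(z.polygon))
                rr, cc = draw_polygon(v[:, 1], v[:, 0], shape=template.shape)
                template[rr, cc] = app.leaf_level

    n_frames = min(len(t) for t in tracks) if tracks else 0
    frame_iter = frames if frames is not None else range(n_frames)
    rng = np.random.default_rng(seed)
    a_px = (app.subject_axes_mm[0] / 2.0) * cal.px_per_mm
    b_px = (app.subject_axes_mm[1] / 2.0) * cal.px_per_mm
    pad = int(math.ceil(a_px)) + 2

    headings = {t.arena_id: _motion_headings(t) for t in tracks}

    for f in frame_iter:
        img = template.astype(np.int16, copy=True)
        if app.noise_sd > 0:
            img += rng.normal(0.0, app.noise_sd, img.shape).round().astype(np.int16)
        for t in tracks:
            x, y = t.x_mm[f], t.y_mm[f]
            if np.isnan(x):
                continue
            cx, cy = cal.mm_to_px([x, y])
            th = headings[t.arena_id][f]
            x0, x1 = int(cx) - pad, int(cx) + pad + 1
            y0, y1 = int(cy) - pad, int(cy) + pad + 1
            x0c, x1c = max(x0, 0), min(x1, W)
            y0c, y1c = max(y0, 0), min(y1, H)
            if x0c >= x1c or y0c >= y1c:
                continue
            yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
            dx, dy = xx - cx, yy - cy
            u = dx * math.cos(th) + dy * math.sin(th)
            v = -dx * math.sin(th) + dy * math.cos(th)
            inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
            patch = img[y0c:y1c, x0c:x1c]
            patch[inside] = np.minimum(patch[inside], app.subject_level)
        yield f, np.clip(img, 0, 255).astype(np.uint8)


def _motion_headings(t: Track) -> np.ndarray:
    """Per-frame body orientation: direction of last nonzero displacement."""
    dx = np.diff(t.x_mm, prepend=t.x_mm[:1])
    dy = np.diff(t.y_mm, prepend=t.y_mm[:1])
    th = np.zeros(len(t))
    cur = 0.0
    for i in range(len(t)):
        if abs(dx[i]) > 1e-9 or abs(dy[i]) > 1e-9:
            cur = math.atan2(dy[i], dx[i])
        th[i] = cur
    return th
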