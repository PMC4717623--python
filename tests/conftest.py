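import numpy as np
import pytest

import arenatrack as at


@pytest.fixture(scope="session")
def study_cal():
    """Full-scale imaging calibration: 1280x960 px over 100x75 mm, 3.5 fps."""
    return at.make_calibration(1280, 960, 100, 75, 3.5)


@pytest.fixture(scope="session")
def small_cal():
    """Reduced field at the same mm/px scale, for render-based tests."""
    return at.make_calibration(256, 256, 20, 20, 3.5)


@pytest.fixture(scope="session")
def small_layout():
    return at.make_plate_layout(2, 2, 7.0, 20, 20)


@pytest.fixture(scope="session")
def arena_zones():
    """Three-zone scheme for one 7-mm well centered at (5, 5) mm."""
    return at.half_disc_zones(0, (5.0, 5.0), 7.0)


@pytest.fixture(scope="session")
def small_roundtrip(small_cal, small_layout):
    """Simulate 4 arenas for 2 min, render noise-free, detect and link.

    Session-scoped because several tests reuse the same recovery run.
    Returns (ground-truth tracks, linked tracks, zone map, calibration).
    """
    from arenatrack.detect import DetectionParams, detect_stack
    from arenatrack.synthetic import render_frames
    from arenatrack.track import GapPolicy, link_track

    cal, layout = small_cal, small_layout
    tracks, truths, zm = at.simulate_plate(
        at.preset_cur3_vs_rmx(), layout, cal, 120.0, n_arenas=4, seed=2
    )
    app = at.Appearance(noise_sd=0.0)
    _, bg = next(render_frames([], layout, cal, app, zone_map=zm, frames=range(1)))
    frames = render_frames(tracks, layout, cal, app, seed=0, zone_map=zm)
    dets = detect_stack(frames, layout, cal, DetectionParams(), background=bg)
    linked = [
        link_track(
            dets[a], a, GapPolicy(), n_frames=len(tracks[0]),
            frame_rate_hz=cal.frame_rate_hz, arena_center_mm=layout.well_centers[a],
        )
        for a in range(4)
    ]
    return tracks, linked, zm, cal
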