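"""Shared fixtures: seeded synthetic movies, footprints and populations.

The expensive end-to-end bundles (rendered movie -> tracking -> rotation
reconstruction) are session-scoped and shared between the unit tests and
the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from rollmap import adhesionmap as am
from rollmap import rotrack as rt
from rollmap import synthlab as sl
from rollmap import trackcore as tc

PX = 0.53
DT = 1.0 / 30.0
TWO_PI = 2.0 * np.pi

# three scatterers, well separated along the rotation axis so their
# projections never blend
SPOTS = ((4.5, 0.0, 0.0), (-1.0, 3.2, 4.2), (2.5, -3.3, -3.0))


@pytest.fixture(scope="session")
def patchy_profile() -> sl.AdhesionProfile:
    return sl.make_adhesion_profile([(np.pi, np.pi / 2, 5.0)], baseline_dwell=0.3)


@pytest.fixture(scope="session")
def flat_profile() -> sl.AdhesionProfile:
    return sl.make_adhesion_profile([], baseline_dwell=0.3)


@pytest.fixture(scope="session")
def spot_geometry() -> sl.CellGeometry:
    return sl.CellGeometry(diameter=14.0, spot_positions=SPOTS)


def _run_pipeline(movie, truth):
    detections = tc.segment_movie(movie, PX)
    tracks = tc.link_cell_tracks(detections, max_jump_um=7.0, frame_interval=DT)
    assert len(tracks) == 1
    track = tracks[0]
    tc.cell_velocity(track)
    stack = tc.crop_cell_frame(movie, track, 10.0, PX)
    trace, trajs = rt.rotation_pipeline(stack, DT)
    rt.traction_classification(trace, track, radius_um=7.0)
    return {
        "movie": movie,
        "truth": truth,
        "track": track,
        "stack": stack,
        "trace": trace,
        "trajs": trajs,
    }


@pytest.fixture(scope="session")
def clean_bundle(patchy_profile, spot_geometry):
    """Noise-free rendered movie of 4.5 rolling cycles, fully analyzed."""
    movie, truth = sl.simulate_rolling_movie(
        patchy_profile, spot_geometry, n_cycles=4.5
    )
    return _run_pipeline(movie, truth)


@pytest.fixture(scope="session")
def detach_bundle(flat_profile, spot_geometry):
    """Noise-free movie with one transient detachment, fully analyzed."""
    ct = flat_profile.cycle_time()
    detachments = ((2.0 * ct, 3.0 * ct),)
    movie, truth = sl.simulate_rolling_movie(
        flat_profile,
        spot_geometry,
        n_cycles=5.0,
        detachment_intervals=detachments,
    )
    return _run_pipeline(movie, truth)


@pytest.fixture(scope="session")
def footprint_bundle():
    """Patchy footprint tiles with vignette, jitter and mild noise."""
    profile = sl.make_adhesion_profile([(0.9 * np.pi, 0.5 * np.pi, 8.0)], 0.3)
    geom = sl.CellGeometry(diameter=14.0)
    yy, xx = np.mgrid[0:80, 0:256]
    vig = 0.4 + 0.6 * np.exp(-((yy - 40) ** 2 + (xx - 128) ** 2) / (2 * 90.0**2))
    vig = vig / vig.max()
    params = sl.FootprintSimParams(illum_field=vig, noise_sd=0.1, tile_jitter_px=4)
    tiles, truth = sl.simulate_footprint_tiles(
        profile, geom, params, track_length_cycles=3, seed=7
    )
    return {
        "tiles": tiles,
        "truth": truth,
        "params": params,
        "vignette": vig,
        "profile": profile,
        "geometry": geom,
    }


@pytest.fixture(scope="session")
def flat_footprint_bundle():
    """Bead-analogue: flat adhesion profile, no periodicity expected."""
    profile = sl.make_adhesion_profile([], 0.3)
    geom = sl.CellGeometry(diameter=14.0)
    params = sl.FootprintSimParams(noise_sd=0.3)
    tiles, truth = sl.simulate_footprint_tiles(
        profile, geom, params, track_length_cycles=3, seed=11
    )
    return {"tiles": tiles, "truth": truth, "params": params}


@pytest.fixture(scope="session")
def population_analysis():
    """30-cell population: angle-based vs position-based dwell autocorrelation."""
    from rollmap.trackcore import moving_average

    cells = sl.simulate_rolling_population(n_cells=30, seed=42)
    angle_results = []
    pos_traces = []
    for cell in cells:
        truth = cell["truth"]
        n = len(truth.t)
        lab = np.where(truth.detached, rt.LABEL_DETACHED, rt.LABEL_ROLLING).astype(
            object
        )
        om = moving_average(np.gradient(cell["theta_meas"], truth.t), 9)
        trace = rt.AngleTrace(
            frames=np.arange(n),
            t=truth.t,
            theta_rel=np.mod(cell["theta_meas"], TWO_PI),
            theta_cum=cell["theta_meas"],
            omega=om,
            labels=lab,
        )
        samples = am.dwell_time(trace)
        grid, tau = am.resample_dwell(samples)
        angle_results.append(am.dwell_autocorrelation(grid, tau, max_lag=5 * TWO_PI))
        # translational-only control: dwell per unit distance 1/v over x
        v = moving_average(np.gradient(cell["x_meas"], truth.t), 9)
        ok = v > 0.01 * np.median(v)
        pos_traces.append((truth.x_um[ok], 1.0 / v[ok]))
    pop_angle = am.population_autocorrelation(angle_results)
    _, pop_pos = am.positional_dwell_autocorrelation(
        pos_traces, dx_um=0.5, max_lag_um=120.0
    )
    d_mean = float(np.mean([c["diameter"] for c in cells]))
    return {
        "cells": cells,
        "pop_angle": pop_angle,
        "pop_pos": pop_pos,
        "d_mean": d_mean,
    }
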