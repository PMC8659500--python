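"""Shared fixtures: small synthetic streams and calibrated thresholds."""

import numpy as np
import pytest

import calfwatch as cw

BLOCK_MS = 1000.0 / 0.27  # resample block length at the default rate


@pytest.fixture(scope="session")
def herd_params() -> cw.PostureParams:
    """Posture thresholds calibrated once from a labelled baseline day.

    Mirrors field practice: thresholds come from the herd's labelled
    distributions and are then applied to new streams.
    """
    scenario = cw.SimScenario(duration_h=24.0, seed=999)
    _, stream, events = cw.simulate_collar_data(scenario, seed=999)
    labelled = cw.trim_pre_transition(cw.synchronize(stream, events))
    return cw.calibrate_thresholds(labelled).params


def make_grid_schedule(seed: int = 7, n_blocks: int = 11664,
                       first_boundary: int = 486,
                       dwell_range: tuple[int, int] = (324, 973),
                       tail_margin: int = 500) -> cw.BoutSchedule:
    """Bout schedule whose boundaries sit exactly on the resample grid.

    Dwells of 20-60 min (longer than the 15-min count window) with no
    boundary near either stream edge: under zero sensor noise the classifier
    recovers every boundary exactly up to its deterministic decision latency.
    """
    rng = np.random.default_rng(seed)
    edges = []
    t = first_boundary
    while t < n_blocks - tail_margin:
        edges.append(t)
        t += int(rng.integers(*dwell_range))
    return cw.BoutSchedule(
        duration_s=n_blocks * BLOCK_MS / 1000.0,
        boundaries_s=np.asarray(edges, dtype=float) * BLOCK_MS / 1000.0,
        start_posture="standing")


@pytest.fixture(scope="session")
def noiseless_case():
    """Grid-snapped schedule + zero-noise stream + calibrated thresholds."""
    schedule = make_grid_schedule()
    scenario = cw.SimScenario.noiseless(duration_h=schedule.duration_s / 3600.0)
    stream = cw.emit_accelerometer(schedule, scenario)
    events = cw.emit_annotations(schedule, scenario)
    labelled = cw.trim_pre_transition(cw.synchronize(stream, events))
    params = cw.calibrate_thresholds(labelled).params
    return schedule, scenario, stream, params


def decision_lags(params: cw.PostureParams) -> tuple[int, int]:
    """Deterministic classification latency in samples for lie->stand and
    stand->lie transitions (threshold crossing of the trailing count)."""
    w = params.window_samples
    lag_up = int(np.floor(params.thr_standing))
    lag_down = int(np.ceil(w - 1 - params.thr_standing))
    return lag_up, lag_down


def random_ay_series(rng: np.random.Generator, n: int,
                     rate_hz: float = 0.27) -> cw.AySeries:
    """Regular resampled-series stand-in with random values, single segment."""
    times = (np.arange(n, dtype=float) + 1) * 1000.0 / rate_hz
    values = rng.normal(0.15, 0.3, size=n)
    return cw.AySeries(times, values, rate_hz, np.zeros(n, dtype=np.intp))
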