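"""Synthetic cattle-behaviour generator.

Produces collar accelerometer streams and observer annotations with the
statistical structure the calving detector assumes, so the whole pipeline is
testable without field data:

* a two-state (standing/lying) alternating-renewal bout process at a
  configurable lying-bout onset rate — literature baselines of 9.3 bouts/day
  four days before calving rising to 13.0 bouts/day on the day of calving;
* pre-calving escalation: the bout rate ramps linearly from baseline to a
  peak multiple inside the 8 h → 2 h pre-calving window, holds the peak until
  calving, then drops below baseline and relaxes back (restlessness subsides);
* posture-conditional accelerometer distributions on the Y axis (standing has
  the larger mean) and Z axis (standing has the larger spread), with an AR(1)
  slow drift shared across postures so block averaging does not trivially
  collapse the noise;
* observer annotations with a configurable reaction lag.

Dwell times are shifted exponentials: a hard minimum bout duration (default
10 min) plus an exponential tail, parameterized so the realized onset rate
matches the configured rate.  The process starts in its equilibrium state, so
the expected number of onsets over any horizon equals rate x duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.signal import lfilter

from .annotation import AnnotationEvent
from .codec import NOMINAL_IMU_HZ, PHYS_DTYPE, RecordStream

_MS = 1000.0


@dataclass(frozen=True)
class SensorModel:
    """Posture-conditional sensor distributions (units of g for accelerations,
    degrees/s for rotations).

    The ay/az defaults give moderate, not perfect, overlap between the
    standing and lying distributions at the raw 17.6 Hz rate; they are
    synthetic choices, not fitted to any herd.  ``drift_sd``/``drift_tau_s``
    parameterize a shared AR(1) (Ornstein-Uhlenbeck) drift emulating slow
    head/neck movement, which survives block averaging.
    """

    ay_standing_mean: float = 0.35
    ay_standing_sd: float = 0.18
    ay_lying_mean: float = -0.05
    ay_lying_sd: float = 0.12
    az_standing_mean: float = -0.92
    az_standing_sd: float = 0.22
    az_lying_mean: float = -0.98
    az_lying_sd: float = 0.08
    ax_sd: float = 0.12
    gyro_sd: float = 8.0
    drift_sd: float = 0.06
    drift_tau_s: float = 120.0
    skin_temp_c: float = 38.5
    imu_temp_c: float = 24.0
    lon_deg: float = -5.74
    lat_deg: float = 40.94
    alt_m: float = 800.0

    @classmethod
    def noiseless(cls) -> "SensorModel":
        """Zero-noise model: ay equals the posture-conditional mean exactly."""
        return cls(ay_standing_sd=0.0, ay_lying_sd=0.0, az_standing_sd=0.0,
                   az_lying_sd=0.0, ax_sd=0.0, gyro_sd=0.0, drift_sd=0.0)


@dataclass(frozen=True)
class SimScenario:
    """Full parameterization of one synthetic cow.

    Rates are lying-bout onsets per day.  The escalation window is expressed
    in hours *before* calving (start > end >= 0); inside it the instantaneous
    rate ramps linearly from baseline to ``peak_multiplier x baseline`` and
    holds that peak from the window's end until calving.  After calving the
    rate drops to ``post_calving_dip x baseline`` and relaxes back to baseline
    with half-life ``post_calving_halflife_h`` (bouts gradually decrease).
    """

    duration_h: float = 96.0
    baseline_bout_rate: float = 9.3
    calving_day_bout_rate: float = 13.0
    peak_multiplier: float = 6.0
    escalation_start_h: float = 8.0
    escalation_end_h: float = 2.0
    post_calving_dip: float = 0.6
    post_calving_halflife_h: float = 12.0
    calving_time_h: float | None = None
    standing_fraction: float = 0.55
    min_bout_min: float = 10.0
    observer_lag_s: float = 5.0
    observer_jitter_s: float = 2.0
    sensor: SensorModel = field(default_factory=SensorModel)
    cow_id: str = "cow-01"
    collar_id: int = 0x01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_bout_rate < 0 or self.calving_day_bout_rate < 0:
            raise ValueError("bout rates must be >= 0")
        if not self.escalation_start_h > self.escalation_end_h >= 0:
            raise ValueError("escalation window must satisfy start > end >= 0")
        if self.observer_lag_s < 0:
            raise ValueError("observer lag must be >= 0")

    @classmethod
    def default_calving(cls, **overrides) -> "SimScenario":
        """One-week scenario with a calving event at hour 132 (day 5.5)."""
        defaults = dict(duration_h=168.0, calving_time_h=132.0)
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def noiseless(cls, **overrides) -> "SimScenario":
        """Deterministic sensors and instantaneous observers."""
        defaults = dict(sensor=SensorModel.noiseless(),
                        observer_lag_s=0.0, observer_jitter_s=0.0)
        defaults.update(overrides)
        return cls(**defaults)

    def bout_rate_at(self, t_h: float) -> float:
        """Instantaneous lying-bout onset rate (bouts/day) at hour ``t_h``."""
        r0 = self.baseline_bout_rate
        if self.calving_time_h is None:
            return r0
        peak = r0 * self.peak_multiplier
        before = self.calving_time_h - t_h  # hours until calving
        if before > self.escalation_start_h:
            return r0
        if before > self.escalation_end_h:
            frac = ((self.escalation_start_h - before)
                    / (self.escalation_start_h - self.escalation_end_h))
            return r0 + frac * (peak - r0)
        if before > 0:
            return peak
        since = -before
        dip = self.post_calving_dip * r0
        return r0 - (r0 - dip) * 2.0 ** (-since / self.post_calving_halflife_h)

    # -- config file round trip ------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "SimScenario":
        d = dict(d)
        if isinstance(d.get("sensor"), dict):
            d["sensor"] = SensorModel(**d["sensor"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimScenario":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


STANDING, LYING = "standing", "lying"


@dataclass
class BoutSchedule:
    """Ground-truth posture intervals for one simulated cow.

    ``boundaries_s`` are the posture-change times in seconds from stream
    start; posture alternates starting from ``start_posture`` and intervals
    tile [0, duration] contiguously.
    """

    duration_s: float
    boundaries_s: np.ndarray
    start_posture: str
    calving_time_s: float | None = None

    @property
    def intervals(self) -> list[tuple[float, float, str]]:
        edges = np.concatenate([[0.0], self.boundaries_s, [self.duration_s]])
        postures = [self.start_posture, STANDING if self.start_posture == LYING else LYING]
        return [(edges[i], edges[i + 1], postures[i % 2]) for i in range(len(edges) - 1)]

    def standing_at(self, times_s: np.ndarray) -> np.ndarray:
        """Boolean standing indicator at each query time."""
        k = np.searchsorted(self.boundaries_s, times_s, side="right")
        start_standing = self.start_posture == STANDING
        return (k % 2 == 0) == start_standing

    @property
    def n_transitions(self) -> int:
        return len(self.boundaries_s)

    def lying_onsets_s(self) -> np.ndarray:
        """Times of stand->lie transitions (lying-bout onsets)."""
        first_is_onset = self.start_posture == STANDING
        return self.boundaries_s[0 if first_is_onset else 1::2]

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.intervals, columns=["start_s", "end_s", "posture"])


def _dwell_means_h(rate_per_day: float, standing_fraction: float,
                   min_h: float) -> tuple[float, float]:
    """Mean standing/lying dwell (hours) realizing the target onset rate."""
    cycle = 24.0 / rate_per_day
    mu_stand = max(standing_fraction * cycle, min_h)
    mu_lie = max((1.0 - standing_fraction) * cycle, min_h)
    return mu_stand, mu_lie


def _draw_dwell_h(rng: np.random.Generator, mean_h: float, min_h: float) -> float:
    if mean_h <= min_h:
        return min_h
    return min_h + rng.exponential(mean_h - min_h)


def _draw_equilibrium_residual_h(rng: np.random.Generator, mean_h: float,
                                 min_h: float) -> float:
    """Residual dwell under the stationary distribution of a shifted
    exponential: uniform over the deterministic head with probability
    min/mean, else a fresh exponential tail."""
    if mean_h <= min_h:
        return rng.uniform(0.0, min_h)
    if rng.uniform() < min_h / mean_h:
        return rng.uniform(0.0, min_h)
    return rng.exponential(mean_h - min_h)


def simulate_bout_schedule(scenario: SimScenario,
                           rng: np.random.Generator | None = None) -> BoutSchedule:
    """Sample the alternating standing/lying process of one cow.

    Each dwell's mean is set from the instantaneous bout rate at its onset
    (adequate resolution: even peak-rate cycles last tens of minutes).  A zero
    bout rate degenerates to a single interval with no transitions.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    dur_h = scenario.duration_h
    min_h = scenario.min_bout_min / 60.0
    calving_s = (None if scenario.calving_time_h is None
                 else scenario.calving_time_h * 3600.0)

    standing = bool(rng.uniform() < scenario.standing_fraction)
    if scenario.bout_rate_at(0.0) <= 0 and scenario.calving_time_h is None:
        return BoutSchedule(dur_h * 3600.0, np.empty(0), STANDING if standing else LYING,
                            calving_s)

    boundaries: list[float] = []
    t = 0.0
    first = True
    start_posture = STANDING if standing else LYING
    while t < dur_h:
        rate = scenario.bout_rate_at(t)
        if rate <= 0:
            break
        mu_s, mu_l = _dwell_means_h(rate, scenario.standing_fraction, min_h)
        mu = mu_s if standing else mu_l
        if first:
            dwell = _draw_equilibrium_residual_h(rng, mu, min_h)
            first = False
        else:
            dwell = _draw_dwell_h(rng, mu, min_h)
        t += dwell
        if t < dur_h:
            boundaries.append(t * 3600.0)
        standing = not standing
    return BoutSchedule(dur_h * 3600.0, np.asarray(boundaries), start_posture, calving_s)


def _ar1_drift(rng: np.random.Generator, n: int, sd: float, tau_s: float,
               dt_s: float) -> np.ndarray:
    """Stationary AR(1)/OU sample path, vectorized via an IIR filter."""
    if sd <= 0 or n == 0:
        return np.zeros(n)
    phi = float(np.exp(-dt_s / tau_s))
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - phi * phi), size=n)
    eps[0] = rng.normal(0.0, sd)  # start in stationarity
    return lfilter([1.0], [1.0, -phi], eps)


def _posture_conditional(rng, standing, mean_s, sd_s, mean_l, sd_l):
    out = np.where(standing, mean_s, mean_l).astype(np.float64)
    sd = np.where(standing, sd_s, sd_l)
    if sd_s > 0 or sd_l > 0:
        out += rng.normal(0.0, 1.0, size=len(standing)) * sd
    return out


def emit_accelerometer(schedule: BoutSchedule, scenario: SimScenario,
                       rng: np.random.Generator | None = None) -> RecordStream:
    """Render a schedule into a 17.6 Hz collar record stream.

    ay and az are drawn from the posture-conditional distributions of the
    sensor model plus the shared slow drift; GNSS and temperature channels are
    placeholders held constant within each second (their 1 Hz semantics on the
    real collar).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed + 1)
    sm = scenario.sensor
    dt_s = 1.0 / NOMINAL_IMU_HZ
    n = int(round(schedule.duration_s * NOMINAL_IMU_HZ))
    data = np.empty(n, dtype=PHYS_DTYPE)
    ts_ms = np.round(np.arange(n, dtype=np.float64) * (_MS / NOMINAL_IMU_HZ)).astype(np.int64)
    data["timestamp"] = ts_ms
    t_s = ts_ms / _MS
    standing = schedule.standing_at(t_s)

    drift = _ar1_drift(rng, n, sm.drift_sd, sm.drift_tau_s, dt_s)
    data["ay"] = _posture_conditional(rng, standing, sm.ay_standing_mean,
                                      sm.ay_standing_sd, sm.ay_lying_mean,
                                      sm.ay_lying_sd) + drift
    data["az"] = _posture_conditional(rng, standing, sm.az_standing_mean,
                                      sm.az_standing_sd, sm.az_lying_mean,
                                      sm.az_lying_sd)
    data["ax"] = rng.normal(0.0, 1.0, n) * sm.ax_sd if sm.ax_sd > 0 else 0.0
    for g in ("gx", "gy", "gz"):
        data[g] = rng.normal(0.0, 1.0, n) * sm.gyro_sd if sm.gyro_sd > 0 else 0.0

    # 1 Hz channels: one value per second, repeated across the IMU samples.
    sec = (ts_ms // 1000).astype(np.intp)
    n_sec = int(sec[-1]) + 1 if n else 0
    wob = 0.02 * rng.standard_normal(n_sec) if sm.drift_sd > 0 else np.zeros(n_sec)
    data["temp_skin"] = (sm.skin_temp_c + wob)[sec] if n else sm.skin_temp_c
    data["temp_imu"] = sm.imu_temp_c
    data["lon"] = sm.lon_deg
    data["lat"] = sm.lat_deg
    data["alt"] = sm.alt_m
    data["speed"] = 0.0
    return RecordStream(data, collar_id=scenario.collar_id)


def emit_annotations(schedule: BoutSchedule, scenario: SimScenario,
                     rng: np.random.Generator | None = None,
                     label_set: str = "posture") -> list[AnnotationEvent]:
    """Observer annotations for a schedule.

    ``label_set="posture"`` emits one B1/B2 event per posture change (plus the
    initial state at t=0), delayed by the observer's reaction lag.  With
    ``label_set="general"`` an A1-A4 stream is emitted instead, carrying the
    documented ambiguity: Neutral (A3) and Ruminating (A2) occur in both
    postures, Grazing-Eating (A1) and Walking (A4) only while standing.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed + 2)
    if label_set not in ("posture", "general"):
        raise ValueError("label_set must be 'posture' or 'general'")

    def lagged(t_s: float) -> int:
        lag = scenario.observer_lag_s
        if scenario.observer_jitter_s > 0:
            lag = max(0.0, rng.normal(scenario.observer_lag_s, scenario.observer_jitter_s))
        return int(round((t_s + lag) * _MS))

    events: list[AnnotationEvent] = []
    for start, _end, posture in schedule.intervals:
        if label_set == "posture":
            label = "B1" if posture == STANDING else "B2"
        else:
            if posture == STANDING:
                label = rng.choice(["A1", "A2", "A3", "A4"], p=[0.4, 0.2, 0.2, 0.2])
            else:
                label = rng.choice(["A2", "A3"], p=[0.5, 0.5])
        t_ms = lagged(start) if start > 0 else 0
        events.append(AnnotationEvent(timestamp_ms=t_ms, label_set=label_set,
                                      label=str(label), cow_id=scenario.cow_id))
    events.sort(key=lambda e: e.timestamp_ms)
    return events


def simulate_collar_data(scenario: SimScenario, seed: int | None = None
                         ) -> tuple[BoutSchedule, RecordStream, list[AnnotationEvent]]:
    """Convenience wrapper: schedule, accelerometer stream and posture
    annotations from one seed, with independent sub-streams of randomness."""
    root = np.random.SeedSequence(scenario.seed if seed is None else seed)
    r_sched, r_acc, r_ann = (np.random.default_rng(s) for s in root.spawn(3))
    if seed is not None:
        scenario = replace(scenario, seed=seed)
    schedule = simulate_bout_schedule(scenario, r_sched)
    stream = emit_accelerometer(schedule, scenario, r_acc)
    events = emit_annotations(schedule, scenario, r_ann)
    return schedule, stream, events
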