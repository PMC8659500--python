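"""Parturition detection from the classified posture signal.

Each posture change is a lying-bout transition:

    f_lb(t) = | f_standing(t) - f_standing(t-1) |

and the detector statistic is the number of transitions in the trailing five
hours:

    f_parturition(t) = sum of f_lb over (t - 5 h, t].

Restlessness in the hours before calving drives f_parturition above its
baseline range, so an alarm is raised the first time it exceeds a per-animal
trigger: the maximum of f_parturition over a calving-free calibration window
plus a safety margin (a value sitting just above everything the cow has shown
before).  Alarms can be gated to a plausibility window around the expected
calving date (one month either side of term when a service/insemination date
is known) and are followed by a refractory period so a single event does not
ring repeatedly while the statistic stays elevated.
"""

from __future__ import annotations

import csv
import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .posture import PostureSeries, _segment_slices

logger = logging.getLogger(__name__)

#: Default transition-count window, seconds (5 hours).
DEFAULT_BOUT_WINDOW_S = 18000.0
#: Default refractory period after an alarm, hours.
DEFAULT_REFRACTORY_H = 24.0


def transitions(f_standing: np.ndarray, valid: np.ndarray,
                segment: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Transition indicator f_lb with validity mask.

    f_lb(t) = |f_standing(t) - f_standing(t-1)| where both samples are valid
    and in the same segment; the first valid sample of each segment carries no
    value.
    """
    n = len(f_standing)
    f_lb = np.zeros(n, dtype=np.int8)
    lb_valid = np.zeros(n, dtype=bool)
    if n >= 2:
        prev_same = (segment[1:] == segment[:-1]) & valid[1:] & valid[:-1]
        f_lb[1:][prev_same] = np.abs(
            f_standing[1:][prev_same].astype(np.int8)
            - f_standing[:-1][prev_same].astype(np.int8))
        lb_valid[1:] = prev_same
    return f_lb, lb_valid


def rolling_bout_count(f_lb: np.ndarray, lb_valid: np.ndarray,
                       segment: np.ndarray, rate_hz: float,
                       window_s: float = DEFAULT_BOUT_WINDOW_S
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Trailing-window transition count f_parturition with warmup mask.

    The window is (t - window, t]: a transition exactly one window plus one
    step old has left the window.  f_parturition is valid once a full window
    of valid f_lb exists after the start of the segment (or after a gap).
    """
    w = int(np.floor(window_s * rate_hz + 1e-9))
    n = len(f_lb)
    f_part = np.zeros(n, dtype=np.int64)
    part_valid = np.zeros(n, dtype=bool)
    for sl in _segment_slices(segment):
        x = np.where(lb_valid[sl], f_lb[sl], 0).astype(np.int64)
        c = np.cumsum(x)
        seg = np.empty(len(c), dtype=np.int64)
        seg[:w] = c[:w]
        if len(c) > w:
            seg[w:] = c[w:] - c[:-w]
        f_part[sl] = seg
        # valid once the trailing window holds w valid f_lb values, i.e. one
        # full window after the segment's first valid transition sample
        lv = lb_valid[sl]
        idx = np.arange(sl.stop - sl.start)
        if lv.any():
            first_valid = int(np.argmax(lv))
            part_valid[sl] = idx >= first_valid + w - 1
    return f_part, part_valid


@dataclass
class BoutStatistic:
    """f_lb and f_parturition on the posture series' time grid."""

    times_ms: np.ndarray
    f_lb: np.ndarray
    lb_valid: np.ndarray
    f_parturition: np.ndarray
    part_valid: np.ndarray
    segment: np.ndarray
    rate_hz: float
    bout_window_s: float = DEFAULT_BOUT_WINDOW_S

    def __len__(self) -> int:
        return len(self.f_lb)

    @property
    def window_samples(self) -> int:
        return int(np.floor(self.bout_window_s * self.rate_hz + 1e-9))

    def n_transitions(self) -> int:
        return int(self.f_lb[self.lb_valid].sum())

    def lying_bout_onsets(self, f_standing: np.ndarray) -> np.ndarray:
        """Indices of stand->lie transitions (lying-bout onsets)."""
        idx = np.nonzero((self.f_lb == 1) & self.lb_valid)[0]
        return idx[f_standing[idx] == 0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "timestamp_ms": self.times_ms, "f_lb": self.f_lb,
            "lb_valid": self.lb_valid, "f_parturition": self.f_parturition,
            "part_valid": self.part_valid,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def bout_statistic(posture: PostureSeries,
                   bout_window_s: float = DEFAULT_BOUT_WINDOW_S) -> BoutStatistic:
    """Compute f_lb and f_parturition from a classified posture series."""
    f_lb, lb_valid = transitions(posture.f_standing, posture.valid, posture.segment)
    f_part, part_valid = rolling_bout_count(
        f_lb, lb_valid, posture.segment, posture.params.resample_hz, bout_window_s)
    return BoutStatistic(posture.times_ms, f_lb, lb_valid, f_part, part_valid,
                         posture.segment, posture.params.resample_hz, bout_window_s)


# ---------------------------------------------------------------------------
# Trigger fitting and alarms


@dataclass(frozen=True)
class TriggerModel:
    """Per-animal alarm threshold on f_parturition.

    ``trigger_value`` = max of f_parturition over a calving-free calibration
    window + ``margin``; restlessness differs between individuals, so the
    value is always derived from the animal's own previous readings.
    ``gate_ms`` optionally bounds the calendar interval in which alarms are
    viable (expected calving date +/- one month).
    """

    cow_id: str
    trigger_value: float
    calibration_hours: float
    margin: float = 1.0
    gate_ms: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.trigger_value > 0:
            raise ValueError("trigger_value must be > 0")

    def in_gate(self, t_ms: float) -> bool:
        if self.gate_ms is None:
            return True
        return self.gate_ms[0] <= t_ms <= self.gate_ms[1]


def gestation_gate(expected_calving_ms: float,
                   half_width_days: float = 30.0) -> tuple[float, float]:
    """Allowed alarm interval around an expected calving date."""
    half = half_width_days * 86400_000.0
    return (expected_calving_ms - half, expected_calving_ms + half)


def fit_trigger(stat: BoutStatistic, calibration_end_ms: float,
                margin: float = 1.0, min_hours: float = 24.0,
                cow_id: str = "",
                gate_ms: tuple[float, float] | None = None) -> TriggerModel:
    """Fit a per-animal trigger from a calving-free calibration window.

    The calibration window runs from the start of the statistic to
    ``calibration_end_ms`` and must span at least ``min_hours`` of valid
    samples; the trigger is the window's maximum f_parturition plus
    ``margin`` (so a constant-zero baseline yields trigger == margin).
    """
    sel = stat.part_valid & (stat.times_ms <= calibration_end_ms)
    if not sel.any():
        raise ValueError(f"no valid f_parturition samples before calibration end; "
                         f"need at least {min_hours} h")
    span_h = (stat.times_ms[sel].max() - stat.times_ms[sel].min()) / 3600_000.0
    if span_h < min_hours:
        raise ValueError(f"calibration window spans {span_h:.1f} h of valid data; "
                         f"at least {min_hours:.0f} h are required")
    peak = float(stat.f_parturition[sel].max())
    return TriggerModel(cow_id=cow_id, trigger_value=peak + margin,
                        calibration_hours=span_h, margin=margin, gate_ms=gate_ms)


@dataclass(frozen=True)
class Alarm:
    """One trigger exceedance event."""

    time_ms: float
    value: int
    trigger: float
    in_gate: bool
    cow_id: str = ""


@dataclass
class DetectionResult:
    """In-gate alarms plus gated-out (suppressed) exceedance events."""

    alarms: list[Alarm] = field(default_factory=list)
    suppressed: list[Alarm] = field(default_factory=list)

    @property
    def first_alarm(self) -> Alarm | None:
        return self.alarms[0] if self.alarms else None


def detect_parturition(stat: BoutStatistic, model: TriggerModel,
                       refractory_h: float = DEFAULT_REFRACTORY_H
                       ) -> DetectionResult:
    """Scan f_parturition for trigger exceedances.

    An alarm fires at the first valid time with f_parturition >
    trigger_value; exceedances outside the gestation gate are suppressed and
    logged.  After any event a refractory period (default 24 h) silences
    further events so one calving does not ring repeatedly.
    """
    result = DetectionResult()
    refractory_ms = refractory_h * 3600_000.0
    quiet_until = -np.inf
    idx = np.nonzero(stat.part_valid
                     & (stat.f_parturition > model.trigger_value))[0]
    for i in idx:
        t = float(stat.times_ms[i])
        if t < quiet_until:
            continue
        alarm = Alarm(time_ms=t, value=int(stat.f_parturition[i]),
                      trigger=model.trigger_value,
                      in_gate=model.in_gate(t), cow_id=model.cow_id)
        if alarm.in_gate:
            result.alarms.append(alarm)
        else:
            logger.warning("suppressed out-of-gate exceedance at t=%.0f ms "
                           "(f_parturition=%d > %.1f)", t, alarm.value,
                           model.trigger_value)
            result.suppressed.append(alarm)
        quiet_until = t + refractory_ms
    return result


def lead_time(result: DetectionResult, truth_ms: float) -> float | None:
    """Hours between the first in-gate alarm and the true calving time.

    Positive when the alarm precedes calving; ``None`` (not zero) when no
    alarm fired.
    """
    if not result.alarms:
        return None
    return (truth_ms - result.alarms[0].time_ms) / 3600_000.0


def write_alarm_log(result: DetectionResult, path: str | Path) -> None:
    """CSV log of all exceedance events (in-gate and suppressed)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cow_id", "time_ms", "f_parturition", "trigger", "gated_out"])
        for a in sorted(result.alarms + result.suppressed, key=lambda a: a.time_ms):
            w.writerow([a.cow_id, int(a.time_ms), a.value, a.trigger,
                        not a.in_gate])


# ---------------------------------------------------------------------------
# Streaming path


class BoutTracker:
    """Incremental f_lb / f_parturition over classified posture samples.

    State is the previous posture plus one bout window of transition
    indicators with a running sum — together with the posture streamer this
    is the collar's whole memory footprint.  ``push`` returns ``None`` for a
    value that is not yet defined; call :meth:`reset` at a data gap.
    """

    def __init__(self, rate_hz: float, window_s: float = DEFAULT_BOUT_WINDOW_S):
        self.window_samples = int(np.floor(window_s * rate_hz + 1e-9))
        self._prev: int | None = None
        self._window: deque[int] = deque()
        self._sum = 0

    def reset(self) -> None:
        self._prev = None
        self._window.clear()
        self._sum = 0

    def push(self, f_standing: int) -> tuple[int | None, int | None]:
        if self._prev is None:
            self._prev = f_standing
            return None, None
        f_lb = abs(f_standing - self._prev)
        self._prev = f_standing
        self._window.append(f_lb)
        self._sum += f_lb
        if len(self._window) > self.window_samples:
            self._sum -= self._window.popleft()
        if len(self._window) < self.window_samples:
            return f_lb, None
        return f_lb, self._sum

    @property
    def state_size(self) -> int:
        return len(self._window) + (self._prev is not None)


class OnlineDetector:
    """End-to-end streaming detector over resampled ay samples.

    Wires a :class:`~calfwatch.posture.PostureStreamer` into a
    :class:`BoutTracker` and, when a trigger model is supplied, raises alarms
    with the same gate/refractory semantics as :func:`detect_parturition`.
    """

    def __init__(self, params, model: TriggerModel | None = None,
                 bout_window_s: float = DEFAULT_BOUT_WINDOW_S,
                 refractory_h: float = DEFAULT_REFRACTORY_H):
        from .posture import PostureStreamer
        self.posture = PostureStreamer(params)
        self.bouts = BoutTracker(params.resample_hz, bout_window_s)
        self.model = model
        self.refractory_ms = refractory_h * 3600_000.0
        self._quiet_until = -np.inf
        self.result = DetectionResult()

    def reset(self) -> None:
        self.posture.reset()
        self.bouts.reset()

    def push(self, t_ms: float, ay: float) -> dict:
        f_count, f_standing = self.posture.push(ay)
        f_lb = f_part = None
        if f_standing is not None:
            f_lb, f_part = self.bouts.push(f_standing)
            if (self.model is not None and f_part is not None
                    and f_part > self.model.trigger_value
                    and t_ms >= self._quiet_until):
                alarm = Alarm(time_ms=t_ms, value=int(f_part),
                              trigger=self.model.trigger_value,
                              in_gate=self.model.in_gate(t_ms),
                              cow_id=self.model.cow_id)
                (self.result.alarms if alarm.in_gate
                 else self.result.suppressed).append(alarm)
                self._quiet_until = t_ms + self.refractory_ms
        return {"f_count": f_count, "f_standing": f_standing,
                "f_lb": f_lb, "f_parturition": f_part}
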