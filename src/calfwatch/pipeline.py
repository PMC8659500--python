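"""End-to-end helpers composing the posture and calving stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calving import (BoutStatistic, DetectionResult, TriggerModel,
                      bout_statistic, detect_parturition, fit_trigger,
                      gestation_gate, DEFAULT_BOUT_WINDOW_S,
                      DEFAULT_REFRACTORY_H)
from .codec import RecordStream
from .posture import PostureParams, PostureSeries, compute_posture


def detected_bout_rate(stream: RecordStream, params: PostureParams
                       ) -> tuple[float, int, float]:
    """Lying bouts per day recovered by the full pipeline.

    Returns ``(bouts_per_day, n_onsets, observed_days)``: stand->lie onsets
    counted over the span where transitions are observable (from each
    segment's first valid posture sample to its end).
    """
    posture = compute_posture(stream, params)
    stat = bout_statistic(posture)
    onsets = stat.lying_bout_onsets(posture.f_standing)
    days = 0.0
    for seg in np.unique(posture.segment):
        sel = (posture.segment == seg) & posture.valid
        if sel.sum() >= 2:
            t = posture.times_ms[sel]
            days += (t[-1] - t[0]) / 86400_000.0
    if days <= 0:
        return float("nan"), 0, 0.0
    return len(onsets) / days, int(len(onsets)), days


@dataclass
class DetectionRun:
    """Everything one detection pass produces."""

    posture: PostureSeries
    stat: BoutStatistic
    model: TriggerModel
    result: DetectionResult


def run_detection(stream: RecordStream, params: PostureParams,
                  calibration_end_ms: float, margin: float = 1.0,
                  expected_calving_ms: float | None = None,
                  gate_half_width_days: float = 30.0,
                  bout_window_s: float = DEFAULT_BOUT_WINDOW_S,
                  refractory_h: float = DEFAULT_REFRACTORY_H,
                  cow_id: str = "") -> DetectionRun:
    """Classify, accumulate the bout statistic, fit the per-animal trigger on
    the calibration window, and scan for alarms (gated when an expected
    calving date is supplied, ungated otherwise)."""
    posture = compute_posture(stream, params)
    stat = bout_statistic(posture, bout_window_s)
    gate = (gestation_gate(expected_calving_ms, gate_half_width_days)
            if expected_calving_ms is not None else None)
    model = fit_trigger(stat, calibration_end_ms, margin=margin,
                        cow_id=cow_id, gate_ms=gate)
    result = detect_parturition(stat, model, refractory_h)
    return DetectionRun(posture, stat, model, result)
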