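"""Standing/lying classification from collar accelerometry.

The classifier is deliberately simple enough to run on the collar's
microcontroller.  Y-axis acceleration is resampled from 17.6 Hz to 0.27 Hz by
block averaging; a trailing 15-minute window counts how many resampled
readings fall strictly between a lower and an upper threshold (a band placed
over the standing-conditional distribution):

    f_count(t) = #{ i in (t - 15 min, t] : thr_inf < f_ay(i) < thr_sup }

and posture is the thresholded count:

    f_standing(t) = 1 (standing) if f_count(t) > thr_standing, else 0 (lying).

Thresholds are calibrated from labelled data by maximizing the separation of
the posture-conditional mean counts.  Both a vectorized batch path and an
O(window)-memory streaming path are provided; they agree exactly.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import LabelledStream
from .codec import RecordStream

logger = logging.getLogger(__name__)

#: Default resample rate, Hz.
DEFAULT_RATE_HZ = 0.27
#: Default trailing count window, seconds (15 minutes).
DEFAULT_COUNT_WINDOW_S = 900.0


class CalibrationError(ValueError):
    """Raised when labelled data cannot support threshold calibration."""


@dataclass(frozen=True)
class PostureParams:
    """Thresholds and window geometry of the posture classifier.

    ``thr_inf``/``thr_sup`` bound the acceleration band (units of g);
    ``thr_standing`` is the count threshold; the count window and resample
    rate default to 15 min at 0.27 Hz, giving a window capacity of 243
    samples.
    """

    thr_inf: float
    thr_sup: float
    thr_standing: float
    count_window_s: float = DEFAULT_COUNT_WINDOW_S
    resample_hz: float = DEFAULT_RATE_HZ

    def __post_init__(self) -> None:
        if not self.thr_inf < self.thr_sup:
            raise ValueError("thr_inf must be < thr_sup")
        if not 0 <= self.thr_standing <= self.window_samples:
            raise ValueError("thr_standing must lie in [0, window capacity]")

    @property
    def window_samples(self) -> int:
        """Count-window capacity: floor(window duration x resample rate)."""
        return int(np.floor(self.count_window_s * self.resample_hz + 1e-9))

    def to_yaml(self, path: str | Path) -> None:
        d = {k: float(v) for k, v in asdict(self).items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PostureParams":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class AySeries:
    """Regularly resampled Y-axis acceleration.

    ``segment`` increments across data gaps: windowed statistics never span a
    gap.  Times are block-end timestamps (trailing alignment — every value is
    computable in real time from past samples only).
    """

    times_ms: np.ndarray
    values: np.ndarray
    rate_hz: float
    segment: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def resample(stream: RecordStream, rate_hz: float = DEFAULT_RATE_HZ,
             gap_factor: float = 3.0) -> AySeries:
    """Block-mean resample of ay onto a regular grid.

    Non-overlapping blocks of 1/rate seconds are averaged and stamped at
    block end; blocks overlapping a gap marker (or containing no samples)
    emit nothing and start a new segment.  An empty stream yields an empty
    series.
    """
    n = len(stream)
    if n == 0:
        e = np.empty(0)
        return AySeries(e, e, rate_hz, np.empty(0, dtype=np.intp))
    block_ms = 1000.0 / rate_hz
    ts = stream.timestamps
    t0 = ts[0]
    block = np.floor((ts - t0) / block_ms).astype(np.intp)
    n_blocks = int(block[-1]) + 1
    counts = np.bincount(block, minlength=n_blocks)
    sums = np.bincount(block, weights=stream.ay.astype(np.float64),
                       minlength=n_blocks)

    bad = counts == 0
    for i in stream.gap_indices(gap_factor):
        b_lo = int((ts[i] - t0) // block_ms)
        b_hi = int((ts[i + 1] - t0) // block_ms)
        bad[b_lo:b_hi + 1] = True
    keep = np.nonzero(~bad)[0]
    values = sums[keep] / counts[keep]
    times = t0 + (keep + 1) * block_ms
    # a jump in kept block ids marks a gap: start a new segment there
    segment = np.zeros(len(keep), dtype=np.intp)
    if len(keep) > 1:
        segment[1:] = np.cumsum(np.diff(keep) > 1)
    return AySeries(times.astype(np.float64), values, rate_hz, segment)


def _segment_slices(segment: np.ndarray):
    if len(segment) == 0:
        return
    bounds = np.nonzero(np.diff(segment))[0] + 1
    edges = np.concatenate([[0], bounds, [len(segment)]])
    for a, b in zip(edges[:-1], edges[1:]):
        yield slice(int(a), int(b))


def banded_count(series: AySeries, params: PostureParams
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Trailing-window in-band count f_count with warmup mask.

    Inequalities are strict on both sides.  The first ``window - 1`` samples
    of each segment have incomplete windows and are flagged as warmup (their
    counts are computed over what exists but must not be consumed).
    """
    w = params.window_samples
    in_band = ((series.values > params.thr_inf)
               & (series.values < params.thr_sup)).astype(np.int64)
    counts = np.empty(len(series), dtype=np.int64)
    warmup = np.zeros(len(series), dtype=bool)
    for sl in _segment_slices(series.segment):
        c = np.cumsum(in_band[sl])
        seg = np.empty(len(c), dtype=np.int64)
        seg[:w] = c[:w]
        if len(c) > w:
            seg[w:] = c[w:] - c[:-w]
        counts[sl] = seg
        warmup[sl.start:min(sl.start + w - 1, sl.stop)] = True
    return counts, warmup


def classify_standing(f_count: np.ndarray, params: PostureParams) -> np.ndarray:
    """Binary posture: 1 (standing) where f_count > thr_standing, else 0."""
    return (f_count > params.thr_standing).astype(np.int8)


@dataclass
class PostureSeries:
    """The classified posture signal with its provenance.

    ``warmup`` samples carry no usable f_standing value; ``segment`` tracks
    gap structure so downstream windows never span a gap.
    """

    times_ms: np.ndarray
    f_count: np.ndarray
    f_standing: np.ndarray
    warmup: np.ndarray
    segment: np.ndarray
    params: PostureParams

    def __len__(self) -> int:
        return len(self.f_count)

    @property
    def valid(self) -> np.ndarray:
        return ~self.warmup

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "timestamp_ms": self.times_ms, "f_count": self.f_count,
            "f_standing": self.f_standing, "warmup": self.warmup,
            "segment": self.segment,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def compute_posture(stream: RecordStream, params: PostureParams,
                    gap_factor: float = 3.0) -> PostureSeries:
    """Resample -> banded count -> threshold, as one batch pipeline."""
    series = resample(stream, params.resample_hz, gap_factor)
    f_count, warmup = banded_count(series, params)
    f_standing = classify_standing(f_count, params)
    return PostureSeries(series.times_ms, f_count, f_standing, warmup,
                         series.segment, params)


# ---------------------------------------------------------------------------
# Calibration


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrated thresholds plus how well they separate the classes."""

    params: PostureParams
    separation: float           # mean f_count standing - mean f_count lying
    balanced_accuracy: float    # on the calibration data itself
    n_standing: int
    n_lying: int


def _block_labels(labelled: LabelledStream, series: AySeries) -> np.ndarray:
    """Label per resampled sample: the block's label if it is unambiguous
    (same retained label at block start and end, no excluded record inside),
    else unlabelled."""
    from .annotation import UNLABELLED

    ts = labelled.stream.timestamps
    block_ms = 1000.0 / series.rate_hz
    end_idx = np.searchsorted(ts, series.times_ms, side="right") - 1
    start_idx = np.searchsorted(ts, series.times_ms - block_ms, side="right")
    start_idx = np.minimum(start_idx, end_idx)
    exc_cum = np.concatenate([[0], np.cumsum(labelled.excluded)])
    any_excluded = (exc_cum[end_idx + 1] - exc_cum[start_idx]) > 0
    lab = labelled.labels
    out = np.where((lab[start_idx] == lab[end_idx]) & ~any_excluded,
                   lab[end_idx], UNLABELLED)
    return out.astype(object)


def calibrate_thresholds(labelled: LabelledStream,
                         count_window_s: float = DEFAULT_COUNT_WINDOW_S,
                         resample_hz: float = DEFAULT_RATE_HZ,
                         n_grid: int = 16,
                         gap_factor: float = 3.0) -> CalibrationResult:
    """Fit (thr_inf, thr_sup, thr_standing) from a posture-labelled stream.

    A grid of candidate band edges is taken from the quantiles of the
    labelled resampled signal; the pair maximizing the difference between the
    standing- and lying-conditional mean counts wins, and thr_standing is set
    to the midpoint of those two means.  The band targets the
    standing-conditional mode (standing ay has the larger mean on a neck
    collar), so the separation is maximized in signed form.

    Raises
    ------
    CalibrationError
        If either posture class is absent from the retained labelled data.
    """
    series = resample(labelled.stream, resample_hz, gap_factor)
    blab = _block_labels(labelled, series)
    is_standing = blab == "B1"
    is_lying = blab == "B2"
    if not is_standing.any():
        raise CalibrationError("calibration data contains no standing (B1) samples")
    if not is_lying.any():
        raise CalibrationError("calibration data contains no lying (B2) samples")

    labelled_vals = series.values[is_standing | is_lying]
    qs = np.linspace(0.02, 0.98, n_grid)
    candidates = np.quantile(labelled_vals, qs)
    # pad beyond the observed range so a strict band can still contain an
    # extreme mode (matters in the noiseless limit, where the labelled values
    # collapse onto two point masses)
    span = max(float(labelled_vals.max() - labelled_vals.min()), 1e-6)
    pad = 0.01 * span
    candidates = np.unique(np.concatenate(
        [candidates, [labelled_vals.min() - pad, labelled_vals.max() + pad]]))
    if len(candidates) < 2:
        raise CalibrationError("degenerate signal: cannot form a band")

    probe = PostureParams(candidates[0], candidates[-1] + 1.0, 0.0,
                          count_window_s, resample_hz)
    w = probe.window_samples
    best = None
    for i in range(len(candidates) - 1):
        for j in range(i + 1, len(candidates)):
            p = PostureParams(candidates[i], candidates[j], 0.0,
                              count_window_s, resample_hz)
            f_count, warmup = banded_count(series, p)
            ok = ~warmup
            m_s = f_count[is_standing & ok].mean() if (is_standing & ok).any() else np.nan
            m_l = f_count[is_lying & ok].mean() if (is_lying & ok).any() else np.nan
            if np.isnan(m_s) or np.isnan(m_l):
                continue
            sep = m_s - m_l
            if best is None or sep > best[0]:
                best = (sep, p, m_s, m_l, f_count, warmup)
    if best is None:
        raise CalibrationError("no candidate band had both classes outside warmup")
    sep, p, m_s, m_l, f_count, warmup = best
    thr_standing = float(np.clip((m_s + m_l) / 2.0, 0.0, w))
    params = PostureParams(p.thr_inf, p.thr_sup, thr_standing,
                           count_window_s, resample_hz)
    pred = classify_standing(f_count, params)
    ok = ~warmup
    tpr = (pred[is_standing & ok] == 1).mean()
    tnr = (pred[is_lying & ok] == 0).mean()
    return CalibrationResult(params=params, separation=float(sep),
                             balanced_accuracy=float((tpr + tnr) / 2.0),
                             n_standing=int(is_standing.sum()),
                             n_lying=int(is_lying.sum()))


# ---------------------------------------------------------------------------
# Streaming path


class PostureStreamer:
    """Incremental f_count / f_standing over resampled ay samples.

    State is one count window of in-band indicators plus a running sum —
    the on-collar memory contract.  ``push`` returns ``(None, None)`` during
    warmup; call :meth:`reset` at a data gap.
    """

    def __init__(self, params: PostureParams):
        self.params = params
        self._window: deque[int] = deque()
        self._sum = 0

    def reset(self) -> None:
        self._window.clear()
        self._sum = 0

    def push(self, ay: float) -> tuple[int | None, int | None]:
        w = self.params.window_samples
        b = int(self.params.thr_inf < ay < self.params.thr_sup)
        self._window.append(b)
        self._sum += b
        if len(self._window) > w:
            self._sum -= self._window.popleft()
        if len(self._window) < w:
            return None, None
        f_count = self._sum
        return f_count, int(f_count > self.params.thr_standing)

    @property
    def state_size(self) -> int:
        return len(self._window)
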