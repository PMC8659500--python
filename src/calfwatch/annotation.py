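"""Observer-annotation handling: label sets, timestamp joins and hygiene.

Two label sets are used in the field: a general-behaviour set (A1
Grazing-Eating, A2 Ruminating, A3 Neutral, A4 Walking) and a standing/lying
set (B1 Standing, B2 Lying).  Annotations record state *changes*; labels are
extended forward in time (last observation carried forward) until the next
event.  Because a human observer reacts with a delay, records shortly before
each label change are excluded from calibration via a trailing exclusion
horizon (default two minutes).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .codec import RecordStream

logger = logging.getLogger(__name__)

GENERAL_LABELS = {"A1": "Grazing-Eating", "A2": "Ruminating",
                  "A3": "Neutral", "A4": "Walking"}
POSTURE_LABELS = {"B1": "Standing", "B2": "Lying"}
LABEL_SETS = {"general": GENERAL_LABELS, "posture": POSTURE_LABELS}

#: Sentinel for records carrying no label (before the first event, or inside
#: a span the observer deliberately left blank).
UNLABELLED = ""


@dataclass(frozen=True)
class AnnotationEvent:
    """One observer action label.  A blank ``label`` opens an unlabelled span
    (observers blank their annotations when they lose track of the animal)."""

    timestamp_ms: int
    label_set: str
    label: str
    cow_id: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if self.label_set not in LABEL_SETS:
            raise ValueError(f"unknown label set {self.label_set!r}")
        if self.label != UNLABELLED and self.label not in LABEL_SETS[self.label_set]:
            raise ValueError(f"label {self.label!r} not in set {self.label_set!r}")


@dataclass
class LabelledStream:
    """A record stream with per-record labels and an exclusion mask.

    ``labels`` holds one label (or :data:`UNLABELLED`) per record; ``excluded``
    marks records that must not enter calibration (pre-transition horizon).
    Labels are preserved under exclusion — the mask, not the label, gates use.
    """

    stream: RecordStream
    labels: np.ndarray
    excluded: np.ndarray
    label_set: str = "posture"

    def __post_init__(self) -> None:
        n = len(self.stream)
        if len(self.labels) != n or len(self.excluded) != n:
            raise ValueError("labels/excluded must have one entry per record")

    @property
    def retained(self) -> np.ndarray:
        """Records usable for calibration: labelled and not excluded."""
        return (~self.excluded) & (self.labels != UNLABELLED)


def synchronize(stream: RecordStream, events: Sequence[AnnotationEvent]
                ) -> LabelledStream:
    """Join events onto a stream by timestamp (piecewise-constant extension).

    Each record takes the most recent preceding (or simultaneous) event's
    label; records before the first event are unlabelled.  Events outside the
    stream's time range are warned about and contribute nothing.
    """
    n = len(stream)
    labels = np.full(n, UNLABELLED, dtype=object)
    label_set = events[0].label_set if events else "posture"
    if n == 0:
        return LabelledStream(stream, labels, np.zeros(0, dtype=bool), label_set)
    ts = stream.timestamps
    ev_times = np.array([e.timestamp_ms for e in events], dtype=np.int64)
    if np.any(np.diff(ev_times) < 0):
        raise ValueError("events must be time-ordered")
    n_after = int(np.sum(ev_times > ts[-1]))
    if n_after:
        logger.warning("%d event(s) after the stream's end are ignored", n_after)
    # index of last event at or before each record
    idx = np.searchsorted(ev_times, ts, side="right") - 1
    valid = idx >= 0
    ev_labels = np.array([e.label for e in events], dtype=object)
    labels[valid] = ev_labels[idx[valid]]
    return LabelledStream(stream, labels, np.zeros(n, dtype=bool), label_set)


def trim_pre_transition(labelled: LabelledStream,
                        horizon_s: float = 120.0) -> LabelledStream:
    """Exclude records within ``horizon_s`` before each label change.

    The observer annotates a change slightly after it happens, so records in
    the window [change - horizon, change) may carry the stale label.  Labels
    are kept; only the exclusion mask is set.  Idempotent: the change points
    are a function of the (unchanged) labels.
    """
    labels = labelled.labels
    excluded = labelled.excluded.copy()
    n = len(labels)
    if n >= 2:
        ts = labelled.stream.timestamps
        change = np.nonzero(labels[1:] != labels[:-1])[0] + 1
        horizon_ms = int(round(horizon_s * 1000))
        for i in change:
            t_c = ts[i]
            lo = np.searchsorted(ts, t_c - horizon_ms, side="left")
            excluded[lo:i] = True
    return replace(labelled, excluded=excluded)


_GENERAL_TO_POSTURE = {"A4": "B1", "A1": "B1", "A2": UNLABELLED, "A3": UNLABELLED}


def map_general_to_posture(labelled: LabelledStream,
                           grazing_standing: bool = True) -> LabelledStream:
    """Project general-behaviour labels onto the posture set.

    Walking can only happen standing; grazing/eating is done upright too (a
    documented assumption, toggleable via ``grazing_standing``); ruminating
    and the neutral state occur in both postures and become unlabelled.
    Posture-set input is returned unchanged with a warning.
    """
    if labelled.label_set == "posture":
        logger.warning("map_general_to_posture called on a posture-labelled "
                       "stream; no-op")
        return labelled
    mapping = dict(_GENERAL_TO_POSTURE)
    if not grazing_standing:
        mapping["A1"] = UNLABELLED
    labels = np.array([mapping.get(l, UNLABELLED) for l in labelled.labels],
                      dtype=object)
    return replace(labelled, labels=labels, label_set="posture")


# ---------------------------------------------------------------------------
# Annotation CSV: timestamp_ms, cow_id, label_set, label, note — mirroring the
# export of the field annotation software.

_CSV_FIELDS = ["timestamp_ms", "cow_id", "label_set", "label", "note"]


def write_annotations(events: Iterable[AnnotationEvent], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_FIELDS)
        for e in events:
            w.writerow([e.timestamp_ms, e.cow_id, e.label_set, e.label, e.note])


def read_annotations(path: str | Path) -> list[AnnotationEvent]:
    events = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            events.append(AnnotationEvent(
                timestamp_ms=int(row["timestamp_ms"]), cow_id=row.get("cow_id", ""),
                label_set=row["label_set"], label=row["label"],
                note=row.get("note", "")))
    events.sort(key=lambda e: e.timestamp_ms)
    return events
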