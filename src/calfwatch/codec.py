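"""Bit-exact codec for the neck-collar binary sensor log.

The collar writes fixed-width 52-byte records to a microSD card, one file per
hour.  Each record holds a 32-bit millisecond timestamp, two temperatures,
GNSS longitude/latitude/altitude/speed (stored as scaled 32-bit integers) and
3-axis acceleration and rotation (32-bit floats).  This module decodes those
records into physical units, re-encodes them byte-identically, and assembles
hourly files into a single gap-aware stream.

The on-device timestamp is interpreted as milliseconds since collar
initialization (the 32-bit field overflows "ms since Unix epoch" after ~25
days); an absolute epoch may be attached per stream to recover wall-clock
times.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Nominal IMU sampling rate of the collar, Hz.
NOMINAL_IMU_HZ = 17.6

#: Field names in on-disk order.
FIELD_NAMES = (
    "timestamp", "temp_imu", "temp_skin",
    "lon", "lat", "alt", "speed",
    "ax", "ay", "az", "gx", "gy", "gz",
)

#: Integer-stored fields and the divisor converting stored units to physical
#: (lon/lat stored as degrees x 10^7, alt/speed as m x 10^3).
_INT_DIVISOR = {"lon": 1e7, "lat": 1e7, "alt": 1e3, "speed": 1e3}

_FLOAT_FIELDS = ("temp_imu", "temp_skin", "ax", "ay", "az", "gx", "gy", "gz")
_ACCEL_FIELDS = ("ax", "ay", "az")


class TruncatedRecordError(ValueError):
    """A binary block shorter than one full record."""


@dataclass(frozen=True)
class CodecDialect:
    """Byte-level conventions of the collar firmware.

    The firmware's byte order is not externally documented; little-endian is
    the natural choice for the Cortex-M4 class microcontroller in the collar
    and is the default, but big-endian logs can be read by passing ``">"``.
    """

    byte_order: str = "<"

    def __post_init__(self) -> None:
        if self.byte_order not in ("<", ">"):
            raise ValueError("byte_order must be '<' or '>'")

    @property
    def raw_dtype(self) -> np.dtype:
        bo = self.byte_order
        fields = []
        for name in FIELD_NAMES:
            if name == "timestamp" or name in _INT_DIVISOR:
                fields.append((name, f"{bo}i4"))
            else:
                fields.append((name, f"{bo}f4"))
        return np.dtype(fields)


DEFAULT_DIALECT = CodecDialect()

#: Width of one record on disk (13 fields x 4 bytes).
RECORD_SIZE = DEFAULT_DIALECT.raw_dtype.itemsize  # == 52

#: In-memory physical-unit layout.  Timestamps widen to int64 so that streams
#: longer than the 32-bit field can be represented after epoch stitching.
PHYS_DTYPE = np.dtype([
    ("timestamp", "i8"),
    ("temp_imu", "f4"), ("temp_skin", "f4"),
    ("lon", "f8"), ("lat", "f8"), ("alt", "f8"), ("speed", "f8"),
    ("ax", "f4"), ("ay", "f4"), ("az", "f4"),
    ("gx", "f4"), ("gy", "f4"), ("gz", "f4"),
])


@dataclass(frozen=True)
class CollarRecord:
    """One decoded sensor sample in physical units.

    timestamp is milliseconds since the stream epoch; temperatures in degrees
    Celsius; lon/lat in degrees; alt in metres; speed in m/s; ax..az in
    multiples of g; gx..gz in degrees/second.
    """

    timestamp: int
    temp_imu: float
    temp_skin: float
    lon: float
    lat: float
    alt: float
    speed: float
    ax: float
    ay: float
    az: float
    gx: float
    gy: float
    gz: float


def decode_block(buf: bytes, dialect: CodecDialect = DEFAULT_DIALECT,
                 offset: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Decode a whole number of records from ``buf``.

    Returns ``(records, flagged)`` where ``records`` is a structured array in
    physical units (``PHYS_DTYPE``) and ``flagged`` marks records containing a
    non-finite float (kept, never raised on).

    Raises
    ------
    TruncatedRecordError
        If ``buf`` is not a whole number of records; the message names the
        offending file offset.
    """
    if len(buf) % RECORD_SIZE:
        raise TruncatedRecordError(
            f"truncated record at offset {offset + len(buf) - len(buf) % RECORD_SIZE}"
            f" ({len(buf) % RECORD_SIZE} stray bytes)")
    raw = np.frombuffer(buf, dtype=dialect.raw_dtype)
    phys = np.empty(len(raw), dtype=PHYS_DTYPE)
    phys["timestamp"] = raw["timestamp"].astype(np.int64)
    for name, divisor in _INT_DIVISOR.items():
        phys[name] = raw[name].astype(np.float64) / divisor
    for name in _FLOAT_FIELDS:
        phys[name] = raw[name]
    flagged = np.zeros(len(raw), dtype=bool)
    for name in _FLOAT_FIELDS:
        flagged |= ~np.isfinite(phys[name].astype(np.float64))
    return phys, flagged


def encode_block(records: np.ndarray,
                 dialect: CodecDialect = DEFAULT_DIALECT) -> bytes:
    """Encode physical-unit records back to on-disk bytes.

    Inverse of :func:`decode_block`: scaled integer fields are rounded back to
    their stored representation, floats are stored as float32.
    """
    raw = np.empty(len(records), dtype=dialect.raw_dtype)
    ts = np.asarray(records["timestamp"], dtype=np.int64)
    if ts.size and (ts.min() < np.iinfo(np.int32).min or ts.max() > np.iinfo(np.int32).max):
        raise ValueError("timestamp exceeds the 32-bit millisecond field; "
                         "re-base the stream epoch before encoding")
    raw["timestamp"] = ts.astype(np.int32)
    for name, divisor in _INT_DIVISOR.items():
        raw[name] = np.round(np.asarray(records[name], dtype=np.float64) * divisor).astype(np.int32)
    for name in _FLOAT_FIELDS:
        raw[name] = np.asarray(records[name], dtype=np.float32)
    return raw.tobytes()


def decode_record(block: bytes, dialect: CodecDialect = DEFAULT_DIALECT,
                  offset: int = 0) -> CollarRecord:
    """Decode a single 52-byte block into a :class:`CollarRecord`."""
    if len(block) != RECORD_SIZE:
        raise TruncatedRecordError(
            f"expected {RECORD_SIZE}-byte record, got {len(block)} bytes at offset {offset}")
    phys, _ = decode_block(block, dialect, offset=offset)
    row = phys[0]
    return CollarRecord(**{n: row[n].item() for n in FIELD_NAMES})


def encode_record(record: CollarRecord,
                  dialect: CodecDialect = DEFAULT_DIALECT) -> bytes:
    """Encode a single :class:`CollarRecord` to its 52 on-disk bytes."""
    phys = np.zeros(1, dtype=PHYS_DTYPE)
    for n in FIELD_NAMES:
        phys[0][n] = getattr(record, n)
    return encode_block(phys, dialect)


def validate_acceleration(records: np.ndarray, max_g: float = 8.0) -> np.ndarray:
    """Mask of records whose acceleration magnitude exceeds ``max_g``."""
    mag = np.sqrt(sum(records[n].astype(np.float64) ** 2 for n in _ACCEL_FIELDS))
    return mag > max_g


@dataclass
class RecordStream:
    """An ordered, gap-aware sequence of decoded collar records.

    ``data`` is a structured array (``PHYS_DTYPE``); ``flagged`` marks records
    decoded with non-finite floats.  ``epoch`` optionally anchors the relative
    millisecond timestamps to wall-clock time (the timestamp the annotation
    laptop exchanges with the collar at initialization).
    """

    data: np.ndarray
    collar_id: int = 0
    source_files: list[str] = field(default_factory=list)
    epoch: pd.Timestamp | None = None
    flagged: np.ndarray | None = None
    nominal_hz: float = NOMINAL_IMU_HZ

    def __post_init__(self) -> None:
        if self.flagged is None:
            self.flagged = np.zeros(len(self.data), dtype=bool)

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RecordStream):
            return NotImplemented
        return (len(self) == len(other)
                and all(np.array_equal(self.data[n], other.data[n]) for n in FIELD_NAMES)
                and self.collar_id == other.collar_id)

    @property
    def timestamps(self) -> np.ndarray:
        """Timestamps in milliseconds since the stream epoch (int64)."""
        return self.data["timestamp"]

    @property
    def times_s(self) -> np.ndarray:
        return self.timestamps.astype(np.float64) / 1000.0

    @property
    def ay(self) -> np.ndarray:
        return self.data["ay"]

    def gap_indices(self, gap_factor: float = 3.0) -> np.ndarray:
        """Indices ``i`` such that the jump from record ``i`` to ``i+1``
        exceeds ``gap_factor`` nominal sample periods.

        Gaps are reported, never interpolated over; downstream resampling
        emits no sample for windows that straddle one.
        """
        if len(self.data) < 2:
            return np.empty(0, dtype=np.intp)
        dt = np.diff(self.timestamps)
        thresh = gap_factor * 1000.0 / self.nominal_hz
        return np.nonzero(dt > thresh)[0]

    def record(self, i: int) -> CollarRecord:
        row = self.data[i]
        return CollarRecord(**{n: row[n].item() for n in FIELD_NAMES})

    def to_dataframe(self) -> pd.DataFrame:
        """Physical-unit DataFrame; adds an ISO-8601 ``time`` column when the
        stream epoch is known."""
        df = pd.DataFrame({n: self.data[n] for n in FIELD_NAMES})
        if self.epoch is not None:
            df.insert(0, "time", self.epoch + pd.to_timedelta(df["timestamp"], unit="ms"))
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


_FILE_RE = re.compile(r"^([0-9a-fA-F]{1,16})_(\d+)\.bin$")


def read_stream(paths: Sequence[str | Path],
                dialect: CodecDialect = DEFAULT_DIALECT,
                collar_id: int | None = None,
                epoch: pd.Timestamp | str | None = None,
                gap_factor: float = 3.0) -> RecordStream:
    """Read an ordered list of hourly binary files into one stream.

    Files are ordered by their first timestamp; a trailing partial record in
    any file is dropped with a warning (the collar may lose power mid-write).
    Non-monotonic timestamps within a file are stable-sorted with a warning
    rather than rejected — field devices glitch.  An empty file list yields an
    empty stream.
    """
    chunks: list[np.ndarray] = []
    flags: list[np.ndarray] = []
    sources: list[str] = []
    for p in paths:
        p = Path(p)
        buf = p.read_bytes()
        stray = len(buf) % RECORD_SIZE
        if stray:
            logger.warning("%s: dropping %d stray trailing bytes (partial record)", p, stray)
            buf = buf[: len(buf) - stray]
        phys, flagged = decode_block(buf, dialect)
        if len(phys) and np.any(np.diff(phys["timestamp"]) < 0):
            logger.warning("%s: non-monotonic timestamps; applying stable sort", p)
            order = np.argsort(phys["timestamp"], kind="stable")
            phys, flagged = phys[order], flagged[order]
        if collar_id is None:
            m = _FILE_RE.match(p.name)
            if m:
                collar_id = int(m.group(1), 16)
        chunks.append(phys)
        flags.append(flagged)
        sources.append(str(p))
    if not chunks:
        return RecordStream(np.empty(0, dtype=PHYS_DTYPE), collar_id=collar_id or 0)
    order = np.argsort([c["timestamp"][0] if len(c) else np.iinfo(np.int64).max
                        for c in chunks], kind="stable")
    data = np.concatenate([chunks[i] for i in order])
    flagged = np.concatenate([flags[i] for i in order])
    if epoch is not None:
        epoch = pd.Timestamp(epoch)
    stream = RecordStream(data, collar_id=collar_id or 0,
                          source_files=[sources[i] for i in order],
                          epoch=epoch, flagged=flagged)
    n_gaps = len(stream.gap_indices(gap_factor))
    if n_gaps:
        logger.info("stream contains %d gap(s) above %.1fx nominal period", n_gaps, gap_factor)
    return stream


def write_stream(stream: RecordStream, out_dir: str | Path,
                 rollover_s: float = 3600.0,
                 dialect: CodecDialect = DEFAULT_DIALECT) -> list[Path]:
    """Write a stream to hourly (by default) binary files.

    Records are grouped by ``floor(timestamp / rollover)`` so that splitting is
    a pure function of the timestamps: ``read_stream(write_stream(s)) == s``.
    An empty stream writes zero files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(stream) == 0:
        return []
    ts = stream.timestamps
    if np.any(np.diff(ts) < 0):
        raise ValueError("records must be time-ordered before writing")
    block = (ts // int(rollover_s * 1000)).astype(np.int64)
    paths: list[Path] = []
    for k, b in enumerate(np.unique(block)):
        sel = block == b
        path = out_dir / f"{stream.collar_id:016x}_{k:05d}.bin"
        path.write_bytes(encode_block(stream.data[sel], dialect))
        paths.append(path)
    return paths
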