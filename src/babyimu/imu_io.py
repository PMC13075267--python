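"""Reading, writing and windowing of tri-axial IMU recordings.

Canonical on-disk format: a CSV with columns ``time_s, acc_x, acc_y, acc_z,
gyr_x, gyr_y, gyr_z, mag_x, mag_y, mag_z`` (accelerometer in m/s^2, gyroscope
in deg/s, magnetometer in arbitrary normalized units) plus a sidecar JSON
(``<stem>.meta.json``) holding the recording metadata.  Other column names or
units (e.g. vendor exports with rad/s gyroscopes) are handled through a
:class:`Dialect` describing the column map and declared input units.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GRAVITY",
    "CANONICAL_COLUMNS",
    "Dialect",
    "ImuRecording",
    "FormatError",
    "SamplingError",
    "read_recording",
    "write_recording",
    "segment_window",
]

#: standard gravitational acceleration, m/s^2
GRAVITY = 9.81

CANONICAL_COLUMNS = (
    "time_s",
    "acc_x", "acc_y", "acc_z",
    "gyr_x", "gyr_y", "gyr_z",
    "mag_x", "mag_y", "mag_z",
)

#: relative tolerance on the sample interval (fraction of 1/fs)
TIME_STEP_RTOL = 0.01


class FormatError(ValueError):
    """Malformed recording file (missing columns, NaN rows, bad metadata)."""


class SamplingError(ValueError):
    """Timestamps inconsistent with a uniform sampling grid."""


@dataclass(frozen=True)
class Dialect:
    """Column map and declared input units for a CSV recording file.

    Parameters
    ----------
    columns
        Mapping from canonical column names (see :data:`CANONICAL_COLUMNS`)
        to the names used in the file.
    gyro_unit
        ``"deg/s"`` or ``"rad/s"``; rad/s inputs are converted on read.
    accel_unit
        ``"m/s2"`` or ``"g"``; g inputs are scaled by 9.81 on read.
    time_unit
        ``"s"`` or ``"ms"``.
    """

    columns: dict[str, str] = field(default_factory=dict)
    gyro_unit: str = "deg/s"
    accel_unit: str = "m/s2"
    time_unit: str = "s"

    def resolve(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


@dataclass
class ImuRecording:
    """A synchronized tri-axial accel/gyro/mag recording on a uniform grid.

    Attributes
    ----------
    time : (n,) array, seconds, uniform step 1/fs
    accel : (n, 3) array, m/s^2
    gyro : (n, 3) array, deg/s
    mag : (n, 3) array, normalized units
    fs : sampling rate, Hz
    meta : recording metadata (child_id, side, age_months, cohort, walking)
    """

    time: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        self.mag = np.atleast_2d(np.asarray(self.mag, dtype=float))
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        """Recording span in seconds (n/fs, counting the trailing interval)."""
        return self.n_samples / self.fs

    def validate(self) -> None:
        n = len(self.time)
        if n < 2:
            raise FormatError("recording must contain at least 2 samples")
        for name, arr in (("accel", self.accel), ("gyro", self.gyro),
                          ("mag", self.mag)):
            if arr.shape != (n, 3):
                raise FormatError(
                    f"{name} has shape {arr.shape}, expected ({n}, 3)")
            if not np.all(np.isfinite(arr)):
                bad = int(np.flatnonzero(~np.isfinite(arr).all(axis=1))[0])
                raise FormatError(f"non-finite {name} values at row {bad}")
        if not (self.fs > 0 and math.isfinite(self.fs)):
            raise FormatError(f"invalid sampling rate fs={self.fs}")
        dt = 1.0 / self.fs
        steps = np.diff(self.time)
        if np.any(np.abs(steps - dt) > TIME_STEP_RTOL * dt + 1e-9):
            bad = int(np.argmax(np.abs(steps - dt)))
            raise SamplingError(
                f"non-uniform time step at sample {bad}: "
                f"{steps[bad]:.6g} s vs expected {dt:.6g} s")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def read_recording(path: str | Path, dialect: Dialect | None = None) -> ImuRecording:
    """Read a CSV recording (plus sidecar JSON metadata) into canonical units.

    Raises :class:`FormatError` for missing columns or NaN rows and
    :class:`SamplingError` for a non-uniform time grid.
    """
    path = Path(path)
    dialect = dialect or Dialect()
    df = pd.read_csv(path, comment="#")
    cols = {}
    for canonical in CANONICAL_COLUMNS:
        name = dialect.resolve(canonical)
        if name not in df.columns:
            raise FormatError(f"missing column {canonical!r} "
                              f"(looked for {name!r}) in {path.name}")
        cols[canonical] = df[name].to_numpy(dtype=float)
    data = np.column_stack([cols[c] for c in CANONICAL_COLUMNS])
    nan_rows = np.flatnonzero(~np.isfinite(data).all(axis=1))
    if nan_rows.size:
        raise FormatError(f"NaN/non-finite values at row {int(nan_rows[0])}")

    time = cols["time_s"]
    if dialect.time_unit == "ms":
        time = time / 1000.0
    accel = np.column_stack([cols["acc_x"], cols["acc_y"], cols["acc_z"]])
    if dialect.accel_unit == "g":
        accel = accel * GRAVITY
    gyro = np.column_stack([cols["gyr_x"], cols["gyr_y"], cols["gyr_z"]])
    if dialect.gyro_unit == "rad/s":
        gyro = np.degrees(gyro)
    mag = np.column_stack([cols["mag_x"], cols["mag_y"], cols["mag_z"]])

    meta: dict = {}
    fs = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        meta = payload.get("meta", {})
        fs = payload.get("fs")
    if fs is None:
        # infer from the median step; validation then enforces uniformity
        fs = 1.0 / float(np.median(np.diff(time)))
    return ImuRecording(time=time, accel=accel, gyro=gyro, mag=mag,
                        fs=float(fs), meta=meta)


def write_recording(rec: ImuRecording, path: str | Path) -> None:
    """Write a recording as canonical CSV plus sidecar JSON metadata.

    ``read_recording(write_recording(rec))`` reproduces every numeric field
    exactly (full-precision float formatting).
    """
    path = Path(path)
    df = pd.DataFrame({
        "time_s": rec.time,
        "acc_x": rec.accel[:, 0], "acc_y": rec.accel[:, 1], "acc_z": rec.accel[:, 2],
        "gyr_x": rec.gyro[:, 0], "gyr_y": rec.gyro[:, 1], "gyr_z": rec.gyro[:, 2],
        "mag_x": rec.mag[:, 0], "mag_y": rec.mag[:, 1], "mag_z": rec.mag[:, 2],
    })
    df.to_csv(path, index=False, float_format="%.17g")
    payload = {"fs": rec.fs, "meta": rec.meta}
    _sidecar_path(path).write_text(json.dumps(payload, indent=1, default=str))


def segment_window(rec: ImuRecording, start: float, duration: float) -> ImuRecording:
    """Extract a ``[start, start + duration)`` window as a new recording.

    The window must lie within the recording span; a standard 5-minute
    segment at 20 Hz yields 6000 samples.  Metadata is preserved.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if start < -1e-9 or start + duration > rec.duration + 1e-9:
        raise IndexError(
            f"window [{start}, {start + duration}] s outside recording "
            f"span [0, {rec.duration:.6g}] s")
    i0 = int(round(start * rec.fs))
    n = int(round(duration * rec.fs))
    sl = slice(i0, i0 + n)
    return ImuRecording(
        time=rec.time[sl], accel=rec.accel[sl], gyro=rec.gyro[sl],
        mag=rec.mag[sl], fs=rec.fs, meta=dict(rec.meta))
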