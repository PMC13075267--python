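"""Gravity isolation and gyroscope bias correction.

The accelerometer of a slowly reorienting limb measures the rotated gravity
reaction plus transient movement acceleration and noise.  A zero-phase
low-pass Butterworth filter (default cutoff 8 Hz — most infant-generated
accelerometer fluctuations sit below 8 Hz) suppresses high-frequency noise
while leaving the gravitational component intact; residual transients are
further attenuated downstream by the fusion filter.

Rate gyroscopes carry a slowly varying additive bias that integrates into
orientation drift (a bias of 0.02 deg/s alone accumulates 6 degrees over a
5-minute window).  The bias is estimated as an exponential moving average of
the gyroscope signal over detected quiescent periods and subtracted as a
constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .imu_io import ImuRecording

__all__ = [
    "GravitySeries",
    "GyroBias",
    "lowpass_gravity",
    "estimate_gyro_bias",
    "correct_gyro",
    "DEFAULT_CUTOFF_HZ",
]

DEFAULT_CUTOFF_HZ = 8.0
DEFAULT_FILTER_ORDER = 4
DEFAULT_QUIESCENCE_THRESHOLD = 3.0   # deg/s
DEFAULT_MIN_QUIESCENCE_S = 2.0
DEFAULT_EMA_ALPHA = 0.02


@dataclass
class GravitySeries:
    """Low-passed sensor-frame gravity (surface-normal) vector series.

    ``g`` points opposite gravitational acceleration: a sensor lying flat
    reads (0, 0, +9.81) m/s^2.
    """

    time: np.ndarray
    g: np.ndarray  # (n, 3), m/s^2
    fs: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.g.shape != (len(self.time), 3):
            raise ValueError("g must have shape (n, 3) matching time")


@dataclass(frozen=True)
class GyroBias:
    """Constant gyroscope bias estimate in deg/s."""

    bias: np.ndarray  # (3,), deg/s
    n_quiescent_samples: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "bias", np.asarray(self.bias, dtype=float))
        if self.bias.shape != (3,) or not np.all(np.isfinite(self.bias)):
            raise ValueError("bias must be a finite 3-vector")
        if self.n_quiescent_samples < 0:
            raise ValueError("n_quiescent_samples must be >= 0")


def lowpass_gravity(rec: ImuRecording,
                    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
                    order: int = DEFAULT_FILTER_ORDER) -> GravitySeries:
    """Isolate the gravitational accelerometer component by zero-phase
    Butterworth low-pass filtering.

    The filter is applied forward-backward (``filtfilt``), so the effective
    magnitude response is the squared Butterworth response and the phase is
    zero; DC gain is exactly 1.  With the 20 Hz study rate the default 8 Hz
    cutoff sits close to the 10 Hz Nyquist frequency, so the transition band
    is narrow.
    """
    nyq = rec.fs / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(
            f"cutoff_hz={cutoff_hz} must lie in (0, Nyquist={nyq}) Hz")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rec.fs, output="sos")
    # reflect-pad to suppress start-up transients at the window edges
    padlen = min(3 * (2 * order + 1), rec.n_samples - 1)
    g = signal.sosfiltfilt(sos, rec.accel, axis=0, padtype="even",
                           padlen=padlen)
    return GravitySeries(time=rec.time, g=g, fs=rec.fs)


def _quiescent_mask(gyro: np.ndarray, fs: float, threshold: float,
                    min_duration_s: float) -> np.ndarray:
    """Samples belonging to runs of |gyro| < threshold lasting at least
    ``min_duration_s``."""
    quiet = np.linalg.norm(gyro, axis=1) < threshold
    min_run = max(1, int(round(min_duration_s * fs)))
    mask = np.zeros_like(quiet)
    # run-length encode the boolean series
    edges = np.flatnonzero(np.diff(np.concatenate(([False], quiet, [False]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start >= min_run:
            mask[start:stop] = True
    return mask


def estimate_gyro_bias(rec: ImuRecording,
                       quiescence_threshold: float = DEFAULT_QUIESCENCE_THRESHOLD,
                       min_quiescence_s: float = DEFAULT_MIN_QUIESCENCE_S,
                       ema_alpha: float = DEFAULT_EMA_ALPHA) -> GyroBias:
    """Estimate a constant gyroscope bias from quiescent periods.

    Quiescence = gyroscope magnitude below ``quiescence_threshold`` (deg/s)
    sustained for at least ``min_quiescence_s`` seconds.  The bias is an
    exponential moving average (coefficient ``ema_alpha`` per sample, seeded
    at the first quiescent sample) over the quiescent samples in order — so a
    noise-free constant-bias static recording is recovered exactly.  If no
    quiescent run is found, returns zero bias with a warning.
    """
    if quiescence_threshold <= 0:
        raise ValueError("quiescence_threshold must be positive")
    if rec.n_samples < min_quiescence_s * rec.fs:
        raise ValueError("recording shorter than min_quiescence_s")
    mask = _quiescent_mask(rec.gyro, rec.fs, quiescence_threshold,
                           min_quiescence_s)
    n_quiet = int(mask.sum())
    if n_quiet == 0:
        warnings.warn("no quiescent period detected; gyro bias set to zero",
                      stacklevel=2)
        return GyroBias(bias=np.zeros(3), n_quiescent_samples=0)
    samples = rec.gyro[mask]
    bias = samples[0].copy()
    for s in samples[1:]:
        bias += ema_alpha * (s - bias)
    return GyroBias(bias=bias, n_quiescent_samples=n_quiet)


def correct_gyro(rec: ImuRecording, bias: GyroBias) -> ImuRecording:
    """Subtract a constant bias from the gyroscope channels."""
    return ImuRecording(time=rec.time, accel=rec.accel,
                        gyro=rec.gyro - bias.bias[None, :], mag=rec.mag,
                        fs=rec.fs, meta=dict(rec.meta))
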