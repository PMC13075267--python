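"""Composite angular velocity and cross-validation of the two estimators.

A single non-negative scalar rate summarizes how fast the limb reorients,
combining all rotational axes.  Two constructions are available:

* full-3D (default ``geodesic``): the rotation angle between consecutive
  quaternions divided by the sample interval,
  ``omega_i = 2 * arccos(|<q_i, q_{i+1}>|) * fs`` (deg/s).  An alternative
  ``euler_rss`` construction — the root-sum-square of the three unwrapped
  Euler-rate finite differences — is available behind a switch; the two
  coincide for single-axis motion.
* accelerometer-only: ``omega_i = sqrt((d pitch * fs)^2 + (d roll * fs)^2)``
  over unwrapped pitch/roll differences.  Yaw motion is invisible to this
  mode, so it lower-bounds the full-3D rate; on pure pitch/roll motion the
  two agree.

Comparing the two series (Pearson correlation and pairwise mean absolute
difference) quantifies how much a gravity-only pipeline underestimates true
angular velocity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .orientation import FLAG_YAW_UNOBSERVABLE, OrientationSeries

__all__ = [
    "AngularVelocitySeries",
    "angular_velocity_full",
    "angular_velocity_accel_only",
    "compare_series",
]


@dataclass
class AngularVelocitySeries:
    """Scalar composite angular-velocity series (deg/s) at sample-pair
    midpoints."""

    time: np.ndarray   # midpoints of consecutive sample pairs, seconds
    omega: np.ndarray  # deg/s, >= 0
    fs: float
    mode: str          # "full3d" or "accel_only"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.shape != self.time.shape:
            raise ValueError("omega and time must have equal length")
        if np.any(self.omega < -1e-12):
            raise ValueError("omega must be non-negative")


def _wrap_deg(delta: np.ndarray) -> np.ndarray:
    """Wrap angle differences into (-180, 180] degrees."""
    return -((-delta + 180.0) % 360.0 - 180.0)


def angular_velocity_full(orient: OrientationSeries,
                          method: str = "geodesic") -> AngularVelocitySeries:
    """Composite angular velocity from a fused orientation series.

    Requires full (fused) orientation; an accelerometer-only series is
    rejected because its constant placeholder yaw would silently drop the
    heading contribution.
    """
    if orient.mode != "fused" or np.any(orient.flags & FLAG_YAW_UNOBSERVABLE):
        raise ValueError(
            "full-3D angular velocity requires fused orientation "
            "(yaw unobservable in accelerometer-only mode)")
    if method == "geodesic":
        dots = np.abs(np.sum(orient.quat[:-1] * orient.quat[1:], axis=1))
        angles = 2.0 * np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))
        omega = angles * orient.fs
    elif method == "euler_rss":
        dp = _wrap_deg(np.diff(orient.pitch)) * orient.fs
        dr = _wrap_deg(np.diff(orient.roll)) * orient.fs
        dy = _wrap_deg(np.diff(orient.yaw)) * orient.fs
        omega = np.sqrt(dp ** 2 + dr ** 2 + dy ** 2)
    else:
        raise ValueError(f"unknown method {method!r}")
    mid = 0.5 * (orient.time[:-1] + orient.time[1:])
    return AngularVelocitySeries(time=mid, omega=omega, fs=orient.fs,
                                 mode="full3d")


def angular_velocity_accel_only(orient: OrientationSeries) -> AngularVelocitySeries:
    """Composite angular velocity from pitch and roll rates only."""
    dp = _wrap_deg(np.diff(orient.pitch)) * orient.fs
    dr = _wrap_deg(np.diff(orient.roll)) * orient.fs
    omega = np.hypot(dp, dr)
    mid = 0.5 * (orient.time[:-1] + orient.time[1:])
    return AngularVelocitySeries(time=mid, omega=omega, fs=orient.fs,
                                 mode="accel_only")


def compare_series(a: AngularVelocitySeries,
                   b: AngularVelocitySeries) -> tuple[float, float]:
    """Pearson correlation and pairwise mean absolute difference (deg/s)
    between two aligned angular-velocity series.

    Returns ``(r, mad)``; ``r`` is NaN (flagged via warning-free NaN) when
    either series has zero variance.
    """
    if a.omega.shape != b.omega.shape:
        raise ValueError("series length mismatch")
    if not np.allclose(a.time, b.time, atol=1e-9):
        raise ValueError("series timestamps not aligned")
    mad = float(np.mean(np.abs(a.omega - b.omega)))
    if np.std(a.omega) < 1e-15 or np.std(b.omega) < 1e-15:
        return float("nan"), mad
    r = float(stats.pearsonr(a.omega, b.omega).statistic)
    return r, mad
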