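"""Circular-statistics variability measures for orientation angles.

Pitch, roll and yaw are circular variables, so dispersion is measured on the
circle.  For a window of angles theta_1..theta_n (internally in radians) the
mean resultant length is ``Rbar = |mean(exp(i*theta))|``; the axis-specific
circular standard deviation is ``sqrt(-2 ln Rbar)`` (reported in degrees),
which converges to the ordinary standard deviation for tightly concentrated
data.

Multi-axis variability is summarized by the determinant of the circular
covariance matrix ("generalized variance").  The covariance between two
angle series is defined through sine deviations about their circular means,

    C_jk = (1/n) * sum_i sin(theta_ij - mu_j) * sin(theta_ik - mu_k),

a symmetric positive-semidefinite matrix that reduces to the ordinary
covariance (in rad^2) in the small-dispersion limit.  A ``linearized``
variant (ordinary covariance of angles unwrapped about the circular mean)
is available behind a switch for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .orientation import OrientationSeries

__all__ = [
    "VariabilityMetrics",
    "circular_mean",
    "circular_sd",
    "circular_covariance_matrix",
    "generalized_variance",
    "window_metrics",
    "UndefinedCircularMeanError",
]

_RBAR_EPS = 1e-12


class UndefinedCircularMeanError(ValueError):
    """Raised when the mean resultant length vanishes (no preferred
    direction, e.g. antipodal angle pairs)."""


@dataclass(frozen=True)
class VariabilityMetrics:
    """Window-level orientation-variability summary.

    Circular SDs in degrees; generalized variance dimensionless
    (radian-based sine deviations).
    """

    pitch_csd: float
    roll_csd: float
    yaw_csd: float
    gen_var: float
    n: int
    window: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "pitch_csd_deg": self.pitch_csd,
            "roll_csd_deg": self.roll_csd,
            "yaw_csd_deg": self.yaw_csd,
            "gen_var": self.gen_var,
            "n": self.n,
            "window_s": list(self.window),
        }


def _resultant(theta_rad: np.ndarray) -> tuple[float, float]:
    """(circular mean in radians, mean resultant length)."""
    s = np.mean(np.sin(theta_rad))
    c = np.mean(np.cos(theta_rad))
    return float(np.arctan2(s, c)), float(np.hypot(s, c))


def circular_mean(theta_deg) -> tuple[float, float]:
    """Circular mean (degrees) and mean resultant length Rbar of an angle
    series in degrees.

    Raises :class:`UndefinedCircularMeanError` when Rbar vanishes.
    """
    theta = np.radians(np.asarray(theta_deg, dtype=float))
    if theta.size < 1:
        raise ValueError("need at least one angle")
    mu, rbar = _resultant(theta)
    if rbar < _RBAR_EPS:
        raise UndefinedCircularMeanError(
            "mean resultant length ~ 0: circular mean undefined")
    return float(np.degrees(mu)), rbar


def circular_sd(theta_deg) -> float:
    """Circular standard deviation sqrt(-2 ln Rbar), in degrees."""
    theta = np.radians(np.asarray(theta_deg, dtype=float))
    if theta.size < 2:
        raise ValueError("need at least two angles")
    _, rbar = _resultant(theta)
    if rbar < _RBAR_EPS:
        raise UndefinedCircularMeanError(
            "mean resultant length ~ 0: circular SD undefined")
    # Rbar can exceed 1 by round-off for constant series
    return float(np.degrees(np.sqrt(max(0.0, -2.0 * np.log(min(rbar, 1.0))))))


def circular_covariance_matrix(pitch_deg, roll_deg, yaw_deg,
                               definition: str = "sine") -> np.ndarray:
    """Circular covariance matrix of three angle series (degrees in,
    rad^2-scale out).

    ``definition="sine"`` (default) uses sine deviations about the circular
    means; ``definition="linearized"`` uses the ordinary covariance of the
    angle deviations wrapped into (-pi, pi] about the circular means.  Both
    agree in the small-dispersion limit.
    """
    series = [np.radians(np.asarray(s, dtype=float))
              for s in (pitch_deg, roll_deg, yaw_deg)]
    n = series[0].size
    if any(s.size != n for s in series) or n < 2:
        raise ValueError("series must have equal length n >= 2")
    devs = []
    for s in series:
        mu, rbar = _resultant(s)
        if rbar < _RBAR_EPS:
            raise UndefinedCircularMeanError(
                "circular mean undefined on one axis; covariance undefined")
        d = s - mu
        if definition == "sine":
            devs.append(np.sin(d))
        elif definition == "linearized":
            devs.append(np.arctan2(np.sin(d), np.cos(d)))
        else:
            raise ValueError(f"unknown definition {definition!r}")
    D = np.column_stack(devs)
    return (D.T @ D) / n


def generalized_variance(cov: np.ndarray) -> float:
    """Determinant of a symmetric PSD covariance matrix, clamped at 0 for
    tiny negative round-off."""
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (3, 3):
        raise ValueError("covariance matrix must be 3x3")
    if np.max(np.abs(cov - cov.T)) > 1e-9:
        raise ValueError("covariance matrix must be symmetric (to 1e-9)")
    det = float(np.linalg.det(cov))
    if det < -1e-12:
        raise ValueError(f"matrix is not positive semidefinite (det={det:g})")
    return max(det, 0.0)


def window_metrics(orient: OrientationSeries,
                   window: tuple[float, float]) -> VariabilityMetrics:
    """Variability metrics over a time window of an orientation series.

    Flagged samples (warm-up, gimbal lock, invalid) are excluded.  Raises
    when fewer than 2 valid samples remain.
    """
    start, end = window
    in_window = (orient.time >= start - 1e-9) & (orient.time < end - 1e-9)
    mask = in_window & orient.valid_mask
    n = int(mask.sum())
    if n < 2:
        raise ValueError(
            f"insufficient data: {n} valid samples in window {window}")
    pitch = orient.pitch[mask]
    roll = orient.roll[mask]
    yaw = orient.yaw[mask]
    cov = circular_covariance_matrix(pitch, roll, yaw)
    return VariabilityMetrics(
        pitch_csd=circular_sd(pitch),
        roll_csd=circular_sd(roll),
        yaw_csd=circular_sd(yaw),
        gen_var=generalized_variance(cov),
        n=n,
        window=(float(start), float(end)),
    )
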