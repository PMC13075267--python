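"""Sensor orientation estimation: gravity-referenced tilt and MARG fusion.

Two estimators are provided, mirroring the two information streams an
ankle-worn IMU offers:

* :func:`pitch_roll_from_gravity` — tilt from the isolated gravity vector
  alone, using ``pitch = arctan(-X / sqrt(Y^2 + Z^2))`` and
  ``roll = arctan2(Y, Z)`` on the sensor-frame gravity components (X, Y, Z).
  Yaw — rotation about the world vertical — is unobservable from gravity:
  rotating the sensor about the vertical leaves the gravity vector in the
  sensor frame unchanged, so all headings are consistent with the same
  accelerometer reading.
* :func:`fuse` — full pitch/roll/yaw via a Madgwick-type gradient-descent
  fusion of accelerometer, gyroscope and magnetometer, producing a unit
  quaternion per sample.

Conventions: quaternions are scalar-first and rotate sensor-frame vectors
into the world frame; Euler angles follow the intrinsic z-y-x
(yaw-pitch-roll) aerospace sequence, which reduces exactly to the gravity
formulas on static data.  Roll uses the quadrant-aware two-argument
arctangent so inverted limb postures (|roll| > 90 deg) are representable; it
agrees with arctan(Y/Z) everywhere in (-90, 90) deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .imu_io import GRAVITY, ImuRecording
from .preprocess import GravitySeries

__all__ = [
    "FLAG_WARMUP",
    "FLAG_GIMBAL_LOCK",
    "FLAG_INVALID",
    "FLAG_YAW_UNOBSERVABLE",
    "OrientationSeries",
    "FusionParams",
    "pitch_roll_from_gravity",
    "fuse",
    "accel_only_orientation",
    "axis_vector",
    "euler_to_quat",
    "quat_to_euler",
]

FLAG_WARMUP = 1          #: sample inside the fusion warm-up interval
FLAG_GIMBAL_LOCK = 2     #: |pitch| > 89.9 deg; yaw/roll ill-conditioned
FLAG_INVALID = 4         #: undefined orientation (e.g. zero gravity vector)
FLAG_YAW_UNOBSERVABLE = 8  #: accelerometer-only estimate; yaw is a placeholder

GIMBAL_LOCK_PITCH_DEG = 89.9


def euler_to_quat(yaw: np.ndarray, pitch: np.ndarray,
                  roll: np.ndarray) -> np.ndarray:
    """Intrinsic z-y-x Euler angles (degrees) to scalar-first unit
    quaternions (sensor-to-world)."""
    r = Rotation.from_euler("ZYX", np.column_stack(
        np.broadcast_arrays(yaw, pitch, roll)), degrees=True)
    q = r.as_quat()  # scalar-last
    q = np.column_stack([q[:, 3], q[:, 0], q[:, 1], q[:, 2]])
    # fix the sign ambiguity for reproducibility
    flip = q[:, 0] < 0
    q[flip] *= -1
    return q


def quat_to_euler(quat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scalar-first quaternions to (yaw, pitch, roll) in degrees,
    intrinsic z-y-x."""
    quat = np.atleast_2d(quat)
    r = Rotation.from_quat(
        np.column_stack([quat[:, 1], quat[:, 2], quat[:, 3], quat[:, 0]]))
    ypr = r.as_euler("ZYX", degrees=True)
    return ypr[:, 0], ypr[:, 1], ypr[:, 2]


def _quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array([
        aw * bw - ax * bx - ay * by - az * bz,
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
    ])


def _quat_exp_half(omega_dt: np.ndarray) -> np.ndarray:
    """exp([0, omega*dt]/2): the unit quaternion rotating by |omega*dt| rad
    about omega (body frame)."""
    angle = np.linalg.norm(omega_dt)
    if angle < 1e-12:
        return np.array([1.0, *(0.5 * omega_dt)])
    axis = omega_dt / angle
    half = 0.5 * angle
    return np.array([np.cos(half), *(np.sin(half) * axis)])


def _rotate_by_quat(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate sensor-frame v into the world frame by scalar-first q."""
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return R @ v


@dataclass
class OrientationSeries:
    """Per-sample orientation: unit quaternion plus derived Euler angles.

    ``pitch`` lies in (-90, 90) deg, ``roll`` and ``yaw`` in (-180, 180] deg.
    ``flags`` is a per-sample bitmask (warm-up, gimbal lock, invalid,
    yaw-unobservable); ``valid_mask`` selects samples usable downstream.
    """

    time: np.ndarray
    quat: np.ndarray   # (n, 4), scalar-first, unit
    pitch: np.ndarray  # degrees
    roll: np.ndarray   # degrees
    yaw: np.ndarray    # degrees
    fs: float
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    mode: str = "fused"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.quat = np.asarray(self.quat, dtype=float)
        if self.flags is None:
            self.flags = np.zeros(len(self.time), dtype=np.int64)
        self.flags = np.asarray(self.flags, dtype=np.int64)
        norms = np.linalg.norm(self.quat, axis=1)
        ok = self.flags & FLAG_INVALID
        if np.any(np.abs(norms[ok == 0] - 1.0) > 1e-9):
            raise ValueError("quaternions must be unit norm to 1e-9")

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def valid_mask(self) -> np.ndarray:
        """Samples free of warm-up/invalid/gimbal-lock flags."""
        return (self.flags & (FLAG_WARMUP | FLAG_INVALID | FLAG_GIMBAL_LOCK)) == 0


@dataclass(frozen=True)
class FusionParams:
    """Madgwick fusion parameters.

    beta
        Gradient-descent gain balancing gyroscope propagation against
        accelerometer/magnetometer correction (unitless, default 0.1).
    warmup_s
        Initial interval flagged and excluded from downstream metrics while
        the filter converges (default 5 s).
    mag_reference
        World-frame magnetic field direction used by the synthetic renderer
        and the heading initialization; the filter itself re-references the
        measured field each step, so only the field's dip matters.
    """

    beta: float = 0.1
    warmup_s: float = 5.0
    mag_reference: np.ndarray = field(
        default_factory=lambda: np.array([0.5, 0.0, -np.sqrt(3) / 2]))

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.warmup_s < 0:
            raise ValueError("warmup_s must be >= 0")


def pitch_roll_from_gravity(g) -> tuple:
    """Tilt from sensor-frame gravity components (X, Y, Z).

    ``pitch = arctan(-X / sqrt(Y^2 + Z^2))`` in (-90, 90) deg and
    ``roll = arctan2(Y, Z)`` in (-180, 180] deg.  A sensor lying flat
    (g = (0, 0, +9.81) m/s^2) gives pitch = roll = 0; rotated 45 deg about
    its local y-axis (g = 9.81*(sin 45, 0, cos 45)) the formula yields
    pitch = -45 deg.

    Accepts a single 3-vector or an (n, 3) array; returns degrees.
    """
    g = np.asarray(g, dtype=float)
    single = g.ndim == 1
    g = np.atleast_2d(g)
    norm = np.linalg.norm(g, axis=1)
    if np.any(norm < 1e-12):
        raise ValueError("zero gravity vector: orientation undefined")
    x, y, z = g[:, 0], g[:, 1], g[:, 2]
    pitch = np.degrees(np.arctan2(-x, np.hypot(y, z)))
    roll = np.degrees(np.arctan2(y, z))
    if single:
        return float(pitch[0]), float(roll[0])
    return pitch, roll


def _heading_from_mag(mag: np.ndarray, pitch_deg: float,
                      roll_deg: float) -> float:
    """Tilt-compensated heading (yaw, degrees) from a sensor-frame
    magnetometer sample."""
    detilt = Rotation.from_euler("YX", [pitch_deg, roll_deg], degrees=True)
    m = detilt.apply(mag)
    return float(np.degrees(np.arctan2(-m[1], m[0])))


def _madgwick_gradient(q: np.ndarray, a_hat: np.ndarray,
                       m_hat: np.ndarray | None) -> np.ndarray:
    """Gradient of the fusion objective 0.5*|f|^2 at q.

    f stacks the mismatch between the measured (normalized) accelerometer /
    magnetometer vectors and the world gravity / magnetic references rotated
    into the sensor frame by q.  Closed forms verified against a symbolic
    derivation.
    """
    w, x, y, z = q
    ax, ay, az = a_hat
    f = [2 * (x * z - w * y) - ax,
         2 * (w * x + y * z) - ay,
         1 - 2 * x * x - 2 * y * y - az]
    J = [[-2 * y, 2 * z, -2 * w, 2 * x],
         [2 * x, 2 * w, 2 * z, 2 * y],
         [0.0, -4 * x, -4 * y, 0.0]]
    if m_hat is not None:
        mx, my, mz = m_hat
        # world-frame field reference from the current estimate: horizontal
        # intensity bx, vertical bz (declination-free)
        h = _rotate_by_quat(q, m_hat)
        bx = np.hypot(h[0], h[1])
        bz = h[2]
        f += [bx * (1 - 2 * y * y - 2 * z * z) + 2 * bz * (x * z - w * y) - mx,
              2 * bx * (x * y - w * z) + 2 * bz * (w * x + y * z) - my,
              2 * bx * (x * z + w * y) + bz * (1 - 2 * x * x - 2 * y * y) - mz]
        J += [[-2 * bz * y, 2 * bz * z, -4 * bx * y - 2 * bz * w,
               -4 * bx * z + 2 * bz * x],
              [-2 * bx * z + 2 * bz * x, 2 * bx * y + 2 * bz * w,
               2 * bx * x + 2 * bz * z, -2 * bx * w + 2 * bz * y],
              [2 * bx * y, 2 * bx * z - 4 * bz * x, 2 * bx * w - 4 * bz * y,
               2 * bx * x]]
    return np.asarray(J).T @ np.asarray(f)


def _finalize_series(time: np.ndarray, quat: np.ndarray, fs: float,
                     flags: np.ndarray, mode: str) -> OrientationSeries:
    yaw, pitch, roll = quat_to_euler(quat)
    lock = np.abs(pitch) > GIMBAL_LOCK_PITCH_DEG
    flags = flags | np.where(lock, FLAG_GIMBAL_LOCK, 0)
    return OrientationSeries(time=time, quat=quat, pitch=pitch, roll=roll,
                             yaw=yaw, fs=fs, flags=flags, mode=mode)


def fuse(rec: ImuRecording,
         params: FusionParams | None = None) -> OrientationSeries:
    """Estimate full orientation by Madgwick-type MARG fusion.

    Each step propagates the quaternion with the (bias-corrected) gyroscope
    through the exact exponential map and applies a gradient-descent
    correction of gain ``beta`` toward the orientations consistent with the
    measured gravity and magnetic field directions.  The filter is
    initialized from the first sample's gravity tilt and tilt-compensated
    magnetometer heading; the first ``warmup_s`` seconds are flagged.

    Yaw is relative heading (magnetic declination is ignored).
    """
    params = params or FusionParams()
    n = rec.n_samples
    n_warm = int(round(params.warmup_s * rec.fs))
    if n <= n_warm:
        raise ValueError(
            f"recording ({n} samples) shorter than warm-up ({n_warm} samples)")
    dt = 1.0 / rec.fs

    pitch0, roll0 = pitch_roll_from_gravity(rec.accel[0])
    yaw0 = _heading_from_mag(rec.mag[0] / np.linalg.norm(rec.mag[0]),
                             pitch0, roll0)
    q = euler_to_quat(yaw0, pitch0, roll0)[0]

    quat = np.empty((n, 4))
    quat[0] = q
    gyro_rad = np.radians(rec.gyro)
    for i in range(1, n):
        q = _quat_multiply(q, _quat_exp_half(gyro_rad[i - 1] * dt))
        a = rec.accel[i]
        a_norm = np.linalg.norm(a)
        m = rec.mag[i]
        m_norm = np.linalg.norm(m)
        a_hat = a / a_norm if a_norm > 1e-9 else None
        m_hat = m / m_norm if m_norm > 1e-9 else None
        if a_hat is not None:
            grad = _madgwick_gradient(q, a_hat, m_hat)
            gnorm = np.linalg.norm(grad)
            if gnorm > 1e-12:
                q = q - params.beta * dt * grad / gnorm
        q = q / np.linalg.norm(q)
        quat[i] = q

    flags = np.zeros(n, dtype=np.int64)
    flags[:n_warm] |= FLAG_WARMUP
    return _finalize_series(rec.time, quat, rec.fs, flags, "fused")


def accel_only_orientation(grav: GravitySeries) -> OrientationSeries:
    """Orientation from the gravity vector alone.

    Pitch and roll are populated per sample; yaw is identically 0 and every
    sample carries the yaw-unobservable flag (heading cannot be recovered
    from gravity).  Zero-magnitude gravity samples are flagged invalid and
    excluded downstream.
    """
    n = len(grav.time)
    norms = np.linalg.norm(grav.g, axis=1)
    invalid = norms < 1e-9
    g_safe = np.where(invalid[:, None], [[0.0, 0.0, GRAVITY]], grav.g)
    pitch, roll = pitch_roll_from_gravity(g_safe)
    yaw = np.zeros(n)
    quat = euler_to_quat(yaw, pitch, roll)
    flags = np.full(n, FLAG_YAW_UNOBSERVABLE, dtype=np.int64)
    flags[invalid] |= FLAG_INVALID
    series = _finalize_series(grav.time, quat, grav.fs, flags, "accel_only")
    # the placeholder heading must stay exactly 0 for flagged samples
    series.yaw = np.zeros(n)
    return series


def axis_vector(orient: OrientationSeries, axis: str, t: float) -> np.ndarray:
    """World-frame direction of a sensor basis axis at the sample nearest t.

    Used to visualize limb pointing (e.g. the sensor's y-axis along the
    shank) against video frames.
    """
    if axis not in ("x", "y", "z"):
        raise ValueError("axis must be one of 'x', 'y', 'z'")
    if not (orient.time[0] - 1e-9 <= t <= orient.time[-1] + 1e-9):
        raise IndexError(f"t={t} outside series span")
    i = int(np.argmin(np.abs(orient.time - t)))
    basis = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]),
             "z": np.array([0, 0, 1.0])}[axis]
    v = _rotate_by_quat(orient.quat[i], basis)
    return v / np.linalg.norm(v)
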