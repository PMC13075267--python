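"""Synthetic infant-limb IMU data with known ground truth.

Real recordings from the study population are not redistributable, so every
downstream module is exercised against simulated data whose generating
parameters are known exactly.  Two generators are provided:

* a trajectory/recording simulator: a piecewise-smooth limb orientation made
  of quiescent periods and movement bouts (Poisson onsets), rendered into
  accelerometer (rotated gravity + transient movement acceleration + white
  noise), gyroscope (true body rates + constant bias + white noise) and
  magnetometer (rotated world field + white noise) channels at 20 Hz;
* a longitudinal cohort simulator: per-child random intercepts and linear
  age slopes for each variability metric, with MSEL gross-motor scores
  linked to generalized variance at configurable strength.

Orientation bouts are built by integrating the gated derivative of a
band-limited Gaussian process per Euler axis and rescaling each axis to its
target stationary dispersion, so trajectories are smooth across bout
boundaries and the per-axis angular dispersions are controlled.  All
generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.spatial.transform import Rotation

from .imu_io import GRAVITY, ImuRecording
from .orientation import euler_to_quat

__all__ = [
    "NoiseParams",
    "MovementParams",
    "TrajectoryConfig",
    "SynthTruth",
    "SynthCohortConfig",
    "simulate_trajectory",
    "render_imu",
    "simulate_cohort",
    "DEFAULT_MAG_WORLD",
]

#: world magnetic field direction: unit vector dipping 60 deg below the
#: horizontal (mid-latitude), in the x-z plane
DEFAULT_MAG_WORLD = np.array([0.5, 0.0, -np.sqrt(3.0) / 2.0])


@dataclass(frozen=True)
class NoiseParams:
    """Additive white sensor noise (1 SD per axis)."""

    accel_sd: float = 0.05  # m/s^2
    gyro_sd: float = 0.2    # deg/s
    mag_sd: float = 0.01    # normalized units

    def __post_init__(self) -> None:
        if min(self.accel_sd, self.gyro_sd, self.mag_sd) < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class MovementParams:
    """Movement-bout structure and orientation dispersion targets.

    per_axis_dispersion is the target stationary SD of the (pitch, roll,
    yaw) Euler series in degrees; angle_bandwidth_hz bounds how fast the
    orientation wanders within a bout; movement acceleration is band-limited
    below movement_accel_band_hz so the gravity low-pass assumption holds by
    construction (the band edge is configurable to stress-test the filter).
    """

    bout_rate: float = 6.0            # bouts per minute
    bout_duration_s: float = 4.0
    per_axis_dispersion: tuple = (15.0, 35.0, 35.0)  # deg (pitch, roll, yaw)
    angle_bandwidth_hz: float = 0.5
    movement_accel_sd: float = 0.5    # m/s^2 during bouts
    movement_accel_band_hz: float = 6.0
    ramp_s: float = 0.5               # raised-cosine bout on/offsets


@dataclass(frozen=True)
class TrajectoryConfig:
    """Full configuration for one synthetic recording."""

    movement: MovementParams = field(default_factory=MovementParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    gyro_bias: tuple = (0.02, -0.015, 0.01)  # deg/s
    mag_world: tuple = tuple(DEFAULT_MAG_WORLD)
    seed: int = 0


@dataclass
class SynthTruth:
    """Ground truth for a rendered recording."""

    time: np.ndarray
    quat_true: np.ndarray      # (n, 4) scalar-first, sensor-to-world
    omega_true: np.ndarray     # (n-1,) deg/s, geodesic rate
    euler_true: np.ndarray     # (n, 3) yaw, pitch, roll in degrees
    bout_envelope: np.ndarray  # (n,) in [0, 1]
    fs: float
    config: TrajectoryConfig

    @property
    def gyro_bias(self) -> np.ndarray:
        return np.asarray(self.config.gyro_bias, dtype=float)


def _bout_envelope(n: int, fs: float, mov: MovementParams,
                   rng: np.random.Generator) -> np.ndarray:
    """Smooth [0, 1] envelope: Poisson bout onsets, raised-cosine ramps."""
    env = np.zeros(n)
    if mov.bout_rate <= 0 or n == 0:
        return env
    duration = n / fs
    rate_per_s = mov.bout_rate / 60.0
    n_bouts = rng.poisson(rate_per_s * duration)
    onsets = np.sort(rng.uniform(0.0, duration, size=n_bouts))
    ramp = max(1, int(round(mov.ramp_s * fs)))
    core = max(1, int(round(mov.bout_duration_s * fs)))
    up = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    shape = np.concatenate([up, np.ones(core), up[::-1]])
    for t0 in onsets:
        i0 = int(round(t0 * fs))
        seg = shape[: max(0, min(len(shape), n - i0))]
        env[i0:i0 + len(seg)] = np.maximum(env[i0:i0 + len(seg)], seg)
    return env


def _smooth_noise(n: int, fs: float, cutoff_hz: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Unit-scale band-limited Gaussian process (low-passed white noise)."""
    white = rng.standard_normal(n)
    if n < 16 or cutoff_hz >= fs / 2:
        return white
    sos = signal.butter(2, cutoff_hz, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, white)


def simulate_trajectory(cfg: TrajectoryConfig, duration: float,
                        fs: float = 20.0) -> SynthTruth:
    """Simulate a piecewise-smooth limb-orientation trajectory.

    Within bouts each Euler angle follows a band-limited Gaussian path;
    between bouts the orientation is held.  Each axis is rescaled so its
    overall (linear) dispersion equals the configured target; the composite
    angular velocity ``omega_true`` is the quaternion geodesic rate.
    """
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("duration * fs must be >= 2")
    rng = np.random.default_rng(cfg.seed)
    env = _bout_envelope(n, fs, cfg.movement, rng)

    angles = np.zeros((n, 3))  # columns: pitch, roll, yaw
    for j, target_sd in enumerate(cfg.movement.per_axis_dispersion):
        x = _smooth_noise(n, fs, cfg.movement.angle_bandwidth_hz, rng)
        gated = np.concatenate([[0.0], np.cumsum(np.diff(x) * env[1:])])
        sd = gated.std()
        if target_sd > 0 and sd > 1e-12:
            angles[:, j] = (gated - gated.mean()) / sd * target_sd
    pitch, roll, yaw = angles[:, 0], angles[:, 1], angles[:, 2]

    quat = euler_to_quat(yaw, pitch, roll)
    dots = np.abs(np.sum(quat[:-1] * quat[1:], axis=1))
    omega = 2.0 * np.degrees(np.arccos(np.clip(dots, -1.0, 1.0))) * fs
    return SynthTruth(
        time=np.arange(n) / fs,
        quat_true=quat,
        omega_true=omega,
        euler_true=np.column_stack([yaw, pitch, roll]),
        bout_envelope=env,
        fs=fs,
        config=cfg,
    )


def _as_rotations(quat: np.ndarray) -> Rotation:
    return Rotation.from_quat(
        np.column_stack([quat[:, 1], quat[:, 2], quat[:, 3], quat[:, 0]]))


def _body_rates_deg(quat: np.ndarray, fs: float) -> np.ndarray:
    """Body-frame angular velocity (deg/s) whose exact exponential-map
    integration reproduces the quaternion sequence."""
    r = _as_rotations(quat)
    rel = r[:-1].inv() * r[1:]
    omega = np.degrees(rel.as_rotvec()) * fs
    return np.vstack([omega, omega[-1:]])  # hold last rate


def render_imu(truth: SynthTruth, fs: float | None = None) -> ImuRecording:
    """Render a ground-truth trajectory into a synthetic IMU recording.

    accel = gravity rotated into the sensor frame (+9.81 on z at identity)
    + band-limited movement acceleration during bouts + white noise;
    gyro = body rates + constant bias + white noise (deg/s);
    mag = world field rotated into the sensor frame + white noise.
    """
    fs = truth.fs if fs is None else fs
    if fs != truth.fs:
        raise ValueError("rendering at a rate different from the trajectory "
                         "rate is not supported")
    cfg = truth.config
    n = len(truth.time)
    rng = np.random.default_rng([cfg.seed, 1])
    rot = _as_rotations(truth.quat_true)
    inv = rot.inv()

    grav_sensor = inv.apply(np.array([0.0, 0.0, GRAVITY]))
    move = np.column_stack([
        _smooth_noise(n, fs, cfg.movement.movement_accel_band_hz, rng)
        for _ in range(3)])
    for j in range(3):
        sd = move[:, j].std()
        if sd > 1e-12:
            move[:, j] *= cfg.movement.movement_accel_sd / sd
    move *= truth.bout_envelope[:, None]
    accel = grav_sensor + inv.apply(move)
    accel = accel + rng.standard_normal((n, 3)) * cfg.noise.accel_sd

    gyro = _body_rates_deg(truth.quat_true, fs)
    gyro = gyro + np.asarray(cfg.gyro_bias, dtype=float)
    gyro = gyro + rng.standard_normal((n, 3)) * cfg.noise.gyro_sd

    mag_world = np.asarray(cfg.mag_world, dtype=float)
    mag = inv.apply(mag_world)
    mag = mag + rng.standard_normal((n, 3)) * cfg.noise.mag_sd

    meta = {"synthetic": True, "seed": cfg.seed, "side": "left",
            "walking": False}
    return ImuRecording(time=truth.time, accel=accel, gyro=gyro, mag=mag,
                        fs=fs, meta=meta)


# -- longitudinal cohort ----------------------------------------------------

#: per-metric (value at 3 months, slope per month) anchored to the observed
#: cohort ranges: circular SDs in degrees, generalized variance dimensionless
DEFAULT_BASELINE_3MO = {"pitch_csd": 14.8, "roll_csd": 21.4,
                        "yaw_csd": 24.3, "gen_var": 0.025}
DEFAULT_SLOPES = {"pitch_csd": 0.71, "roll_csd": 3.63,
                  "yaw_csd": 4.17, "gen_var": 0.06}
DEFAULT_BETWEEN_SD = {"pitch_csd": 5.0, "roll_csd": 5.0,
                      "yaw_csd": 5.0, "gen_var": 0.10}
DEFAULT_RESIDUAL_SD = {"pitch_csd": 8.0, "roll_csd": 8.0,
                       "yaw_csd": 8.0, "gen_var": 0.15}


@dataclass(frozen=True)
class SynthCohortConfig:
    """Generating model for a longitudinal cohort table.

    Each metric follows ``baseline_3mo + slope * (age - 3) + b_child + eps``
    with ``b_child ~ N(0, between_sd^2)`` per child and metric and
    ``eps ~ N(0, residual_sd^2)`` per visit.  MSEL GM is
    ``msel_intercept + msel_age_slope * age + msel_link_slope * gen_var +
    noise``; the link slope controls the metric-outcome association (0 =
    independent).  The walking flag is always False (the analysis cohort is
    restricted to non-walking visits).
    """

    n_children: tuple = (25, 25)  # (ILA, LLA)
    ages: tuple = (3, 6, 9, 12)
    baseline_3mo: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_3MO))
    slopes: dict = field(default_factory=lambda: dict(DEFAULT_SLOPES))
    between_sd: dict = field(default_factory=lambda: dict(DEFAULT_BETWEEN_SD))
    residual_sd: dict = field(default_factory=lambda: dict(DEFAULT_RESIDUAL_SD))
    cohort_level_shift: dict = field(default_factory=dict)  # LLA minus ILA
    cohort_slope_shift: dict = field(default_factory=dict)
    msel_intercept: float = 20.0
    msel_age_slope: float = 2.5   # raw-score points per month
    msel_link_slope: float = 10.0  # points per unit generalized variance
    msel_sd: float = 4.0
    seed: int = 0


def simulate_cohort(cfg: SynthCohortConfig) -> pd.DataFrame:
    """Draw a longitudinal cohort table (one row per child-visit).

    Metrics are linear-Gaussian draws and are not truncated at zero: near
    the floor (generalized variance at 3 months) truncation would bias the
    very slopes the table is used to recover.
    """
    rng = np.random.default_rng(cfg.seed)
    metrics = tuple(cfg.slopes.keys())
    rows = []
    for cohort, n_kids in zip(("ILA", "LLA"), cfg.n_children):
        if n_kids < 2:
            raise ValueError("need >= 2 children per cohort")
        for k in range(n_kids):
            child = f"{cohort}{k:03d}"
            intercepts = {m: rng.normal(0.0, cfg.between_sd[m])
                          for m in metrics}
            for age in cfg.ages:
                row = {"child_id": child, "cohort": cohort,
                       "age_months": age, "walking": False}
                for m in metrics:
                    level = cfg.baseline_3mo[m]
                    slope = cfg.slopes[m]
                    if cohort == "LLA":
                        level = level + cfg.cohort_level_shift.get(m, 0.0)
                        slope = slope + cfg.cohort_slope_shift.get(m, 0.0)
                    row[m] = (level + slope * (age - 3) + intercepts[m]
                              + rng.normal(0.0, cfg.residual_sd[m]))
                row["msel_gm"] = (cfg.msel_intercept
                                  + cfg.msel_age_slope * age
                                  + cfg.msel_link_slope * row["gen_var"]
                                  + rng.normal(0.0, cfg.msel_sd))
                rows.append(row)
    return pd.DataFrame(rows)
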