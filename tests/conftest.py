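import numpy as np
import pytest

import babyimu as bi
from babyimu.orientation import euler_to_quat


def make_static_truth(yaw=0.0, pitch=0.0, roll=0.0, duration=20.0, fs=20.0,
                      noise=None, gyro_bias=(0.0, 0.0, 0.0), seed=0):
    """Ground truth for a static recording at a fixed pose."""
    n = int(round(duration * fs))
    cfg = bi.TrajectoryConfig(
        movement=bi.MovementParams(bout_rate=0.0),
        noise=noise or bi.NoiseParams(0.0, 0.0, 0.0),
        gyro_bias=tuple(gyro_bias), seed=seed)
    q = euler_to_quat(np.full(n, float(yaw)), np.full(n, float(pitch)),
                      np.full(n, float(roll)))
    return bi.SynthTruth(
        time=np.arange(n) / fs, quat_true=q, omega_true=np.zeros(n - 1),
        euler_true=np.column_stack([np.full(n, float(yaw)),
                                    np.full(n, float(pitch)),
                                    np.full(n, float(roll))]),
        bout_envelope=np.zeros(n), fs=fs, config=cfg)


def make_static_recording(**kwargs):
    return bi.render_imu(make_static_truth(**kwargs))


@pytest.fixture(scope="session")
def default_truth():
    """One 5-minute default-noise synthetic recording's ground truth."""
    return bi.simulate_trajectory(bi.TrajectoryConfig(seed=11), duration=300.0)


@pytest.fixture(scope="session")
def default_recording(default_truth):
    return bi.render_imu(default_truth)


@pytest.fixture(scope="session")
def fused_default(default_recording):
    bias = bi.estimate_gyro_bias(default_recording)
    return bi.fuse(bi.correct_gyro(default_recording, bias))


@pytest.fixture(scope="session")
def cohort_table():
    return bi.simulate_cohort(bi.SynthCohortConfig(seed=5))


def orientation_error_deg(quat_est, quat_true):
    dots = np.abs(np.sum(quat_est * quat_true, axis=1))
    return 2.0 * np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))
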