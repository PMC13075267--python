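# babyimu

Gravity-referenced limb-orientation analysis for ankle-worn infant IMUs.

Wearable inertial sensors are widely used to monitor infant movement in
naturalistic settings, but most processing pipelines focus on
movement-generated *linear* acceleration and discard the information about
limb **orientation** carried by the gravitational component of the
accelerometer signal. `babyimu` implements a complementary,
gravity-referenced pipeline for 20 Hz tri-axial accelerometer / gyroscope /
magnetometer recordings from an ankle-worn sensor:

1. **Gravity isolation** — a zero-phase low-pass Butterworth filter
   (default cutoff 8 Hz) separates the rotated gravity vector from
   transient movement acceleration and noise.
2. **Gyroscope bias correction** — quiescent periods (gyro magnitude below
   a threshold, sustained) feed an exponential-moving-average estimator of
   the constant rate bias, which otherwise integrates into orientation
   drift (0.02 deg/s alone accumulates 6° over a 5-minute window).
3. **Orientation estimation** — tilt from gravity alone,

       pitch = arctan( −X / √(Y² + Z²) ),   roll = arctan2( Y, Z ),

   with (X, Y, Z) the sensor-frame gravity components; and full
   pitch/roll/yaw via a Madgwick-type gradient-descent fusion of
   accelerometer, gyroscope and magnetometer producing a unit quaternion
   per sample. Yaw (rotation about the world vertical) is unobservable from
   gravity alone, so the accelerometer-only mode flags it explicitly.
4. **Composite angular velocity** — a scalar reorientation rate, either the
   quaternion geodesic rate (full 3-D) or √(Δpitch² + Δroll²)·fs
   (accelerometer-only), plus their comparison (Pearson r, mean absolute
   difference).
5. **Variability metrics** — per-window circular standard deviations
   √(−2 ln R̄) of pitch, roll and yaw (degrees), and the **generalized
   variance**: the determinant of the circular covariance matrix built from
   sine deviations about the circular means.
6. **Longitudinal cohort analysis** — linear mixed-effects models (REML,
   random intercept per child) for age trends and angle contrasts across
   visits at 3/6/9/12 months, and Spearman correlations between generalized
   variance and concurrent/future Mullen gross-motor (MSEL GM) scores in
   non-walking infants.

A first-class synthetic-data module simulates piecewise-smooth orientation
trajectories (movement bouts + quiescence), renders them into realistic IMU
channels with known ground truth, and draws longitudinal cohort tables from
a linear mixed model — so the whole pipeline is testable without any
sensor data.

## Worked example

```python
import numpy as np
import babyimu as bi

# simulate one 5-minute ankle recording and analyze it
truth = bi.simulate_trajectory(bi.TrajectoryConfig(seed=42), duration=300.0)
rec = bi.render_imu(truth)

bias = bi.estimate_gyro_bias(rec)
rec = bi.correct_gyro(rec, bias)
orient = bi.fuse(rec)

metrics = bi.window_metrics(orient, (5.0, 300.0))
print(f"gyro bias estimate [deg/s]: {np.round(bias.bias, 3)}")
print(f"pitch circular SD: {metrics.pitch_csd:.1f} deg")
print(f"roll  circular SD: {metrics.roll_csd:.1f} deg")
print(f"yaw   circular SD: {metrics.yaw_csd:.1f} deg")
print(f"generalized variance: {metrics.gen_var:.4f}")

full = bi.angular_velocity_full(orient)
accel_only = bi.angular_velocity_accel_only(
    bi.accel_only_orientation(bi.lowpass_gravity(rec)))
r, mad = bi.compare_series(full, accel_only)
print(f"angular-velocity cross-check: r = {r:.2f}, MAD = {mad:.2f} deg/s")

table = bi.simulate_cohort(bi.SynthCohortConfig(seed=42))
res = bi.fit_age_lmm(table, "roll_csd")
print(f"roll circular SD age slope: "
      f"{res.estimate('age_months'):.2f} +/- {res.se('age_months'):.2f} "
      f"deg/month (p = {res.p('age_months'):.2g})")
```

Output:

```
gyro bias estimate [deg/s]: [ 0.01  -0.006  0.003]
pitch circular SD: 15.0 deg
roll  circular SD: 33.4 deg
yaw   circular SD: 35.3 deg
generalized variance: 0.0022
angular-velocity cross-check: r = 0.67, MAD = 19.69 deg/s
roll circular SD age slope: 3.95 +/- 0.22 deg/month (p = 9.9e-71)
```

The circular SDs recover the simulated per-axis dispersions (15°, 35°,
35°); the angular-velocity comparison shows the characteristic pattern of
the accelerometer-only estimator — it tracks the temporal structure of
movement (moderate-to-high r) but is a coarse estimate of magnitude
(non-trivial MAD); and the mixed model recovers the injected developmental
slope of 3.63 deg/month within two standard errors.

## Command line

Every step is also exposed as a `babyimu` subcommand:

```bash
babyimu simulate --preset infant-5min --seed 7 rec.csv truth.csv
babyimu preprocess --cutoff-hz 8 rec.csv prep.csv
babyimu orient --mode fused prep.csv orient.csv
babyimu angvel --mode both orient.csv angvel.csv
babyimu metrics orient.csv --window 5 300 metrics.json
babyimu simulate-cohort --seed 7 cohort.csv
babyimu cohort --model age --metric roll_csd cohort.csv result.json
```

Recordings are plain CSV (`time_s, acc_{x,y,z} [m/s²], gyr_{x,y,z} [deg/s],
mag_{x,y,z}`) with a JSON metadata sidecar; other column names/units are
handled through a dialect map.

## Layout

- `babyimu.imu_io` — recording I/O, dialects, windowing
- `babyimu.preprocess` — gravity low-pass, gyro bias estimation/correction
- `babyimu.orientation` — gravity tilt formulas, Madgwick fusion,
  accelerometer-only mode, axis vectors
- `babyimu.kinematics` — composite angular velocity, estimator comparison
- `babyimu.circular_stats` — circular mean/SD, circular covariance,
  generalized variance, window metrics
- `babyimu.cohort_stats` — mixed-effects age/angle models, MSEL
  correlations
- `babyimu.synth` — trajectory/recording/cohort simulators
- `docs/methods.md` — modelling assumptions, parameter choices, numerical
  details and limitations
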