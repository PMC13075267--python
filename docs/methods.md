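# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `babyimu`. It is written for users who need to judge
whether the defaults fit their data, and for maintainers who need to know
which choices were genuinely open.

## Coordinate and angle conventions

Quaternions are scalar-first and rotate sensor-frame vectors into the world
frame. Euler angles follow the intrinsic z-y-x (yaw → pitch → roll)
aerospace sequence: yaw is rotation about the world vertical, pitch about
the intermediate y-axis (range −90°..90°), roll about the sensor x-axis
(range −180°..180°]. Under this convention a static sensor measures

    accel = g · (−sin θ, sin φ cos θ, cos φ cos θ),   g = 9.81 m/s²,

with θ = pitch, φ = roll, so the gravity-referenced formulas

    pitch = arctan(−X / √(Y² + Z²)),   roll = arctan2(Y, Z)

invert it exactly. Note the sign: a sensor whose gravity reading is
(+g sin 45°, 0, +g cos 45°) — "rotated 45° about its local y-axis" — has
pitch −45° under the formula. Roll uses the two-argument arctangent rather
than the scalar arctan(Y/Z) so that inverted postures (|roll| > 90°, which
infant limbs do reach) are representable; the two agree everywhere in
(−90°, 90°).

Yaw is *relative* heading: magnetic declination is ignored, because every
analysis in the pipeline compares orientations within a recording, never to
geographic north.

## Gravity isolation

The accelerometer measures the rotated gravity reaction plus movement
acceleration and noise. A Butterworth low-pass of order 4, cutoff 8 Hz,
applied forward-backward (`sosfiltfilt`, reflect padding) isolates the
slowly rotating gravity component with exactly zero phase and DC gain 1.
At the 20 Hz sampling rate the 8 Hz cutoff sits close to the 10 Hz Nyquist
frequency, so the transition band is narrow; the effective amplitude
response is the squared bilinear-warped Butterworth magnitude

    |H(f)|⁴ factorization:  gain(f) = [1 + (tan(πf/fs)/tan(πfc/fs))^(2n)]⁻¹

squared once more by the forward-backward pass (verified against the
empirical attenuation in the test suite). The filter order and the
zero-phase application are package choices: only the cutoff is externally
prescribed, and zero phase avoids the group delay that would misalign
orientation estimates with the gyroscope stream.

Movement acceleration below the cutoff passes through; it is attenuated
downstream by the fusion filter, which weighs the accelerometer only
through a bounded gradient-descent correction.

## Gyroscope bias

Rate gyroscopes carry a quasi-constant additive bias. The estimator
detects quiescent runs — gyro magnitude below 3 deg/s sustained for at
least 2 s (both configurable; the strategy, not the thresholds, is
externally prescribed) — and applies a per-sample exponential moving
average with coefficient 0.02 over the quiescent samples, seeded at the
first quiescent sample. Seeding at the first sample makes the estimator
*exact* on noise-free constant-bias static input, and gives it a noise
floor of `gyro_sd·√(α/(2−α)) ≈ 0.1·α^½` on noisy input. If no quiescent
run exists the bias is reported as zero with a warning, and the fusion
filter's accelerometer/magnetometer correction remains the only bias
defence. Correction subtracts the estimate as a constant; a 0.02 deg/s
residual corresponds to 6° of integrated drift over a 5-minute window,
which is why the correction matters at the study's segment length.

## Orientation fusion

The fusion filter is a Madgwick-type MARG gradient-descent filter written
for this package. Each step:

1. propagates the quaternion with the bias-corrected gyro through the
   exact exponential map `q ← q ⊗ exp(½ ω dt)` (rather than the customary
   first-order Euler step — at 20 Hz and infant-kick rates of ~100 deg/s
   the per-step rotation reaches several degrees, where the Euler step's
   truncation error is no longer negligible);
2. applies a normalized gradient-descent correction of gain β toward the
   orientations consistent with the measured gravity direction and
   magnetic field. The objective stacks the world gravity reference
   (0, 0, 1) and the declination-free field reference (bₓ, 0, b_z)
   (recomputed from the current estimate each step) rotated into the
   sensor frame, minus the normalized measurements. The closed-form
   Jacobians were verified against a symbolic derivation.

Defaults: β = 0.1; initialization from the first sample's gravity tilt and
tilt-compensated magnetometer heading; the first 5 s are flagged as
warm-up and excluded from all downstream metrics. Samples with
|pitch| > 89.9° are flagged as gimbal-locked. None of these values are
externally prescribed; β = 0.1 balances gyro drift suppression against
movement-acceleration contamination at the simulator's default noise
(orientation RMS error ≈ 1° on 5-minute renderings), and the suite would
flag a regression beyond 2° RMS.

The accelerometer-only mode populates pitch/roll from the gravity formulas
per sample, sets yaw identically to 0, and flags every sample
yaw-unobservable: rotating the sensor about the world vertical leaves the
sensor-frame gravity vector unchanged, so no accelerometer-only estimator
can recover heading.

## Composite angular velocity

The full-3D rate is the quaternion geodesic rate
`ω_i = 2 arccos(|⟨q_i, q_{i+1}⟩|)·fs` (deg/s). The exact construction of a
composite rate is genuinely open; the geodesic rate is the standard
rotation-metric choice, reduces to the nominal rate on single-axis motion,
and — because for yaw-constant z-y-x motion the body rate satisfies
|ω|² = θ̇² + φ̇² identically — agrees with the accelerometer-only
construction `√((Δpitch·fs)² + (Δroll·fs)²)` on pure pitch/roll motion (to
discretization error, < 0.01 deg/s at 20 Hz). A root-sum-square of the
three unwrapped Euler rates is provided behind a `method="euler_rss"`
switch; it coincides with the geodesic rate for single-axis motion but is
convention-dependent near gimbal lock. Angle differences are unwrapped to
(−180°, 180°] before differencing; no additional smoothing is applied to
ω (smoothing already happened at the 8 Hz gravity filter).

The comparison operation reports the Pearson correlation and the pairwise
mean absolute difference between two aligned ω series. On rendered
synthetic recordings the accelerometer-only estimate correlates moderately
to strongly with the full-3D estimate while differing in magnitude by tens
of deg/s — the expected signature of an estimator blind to yaw and exposed
to movement-acceleration leakage.

## Circular variability metrics

Dispersion per axis is the circular SD √(−2 ln R̄) in degrees, with R̄ the
mean resultant length; it converges to the ordinary SD for concentrated
data (within 2% at σ ≤ 15°). Multi-axis variability is the determinant
("generalized variance") of the 3×3 circular covariance matrix

    C_jk = (1/n) Σᵢ sin(θᵢⱼ − μⱼ) sin(θᵢₖ − μₖ),

with μ the circular means and angles in radians, a symmetric PSD matrix
that reduces to the ordinary covariance (rad²) in the small-dispersion
limit. The normalization of a circular covariance is not uniquely fixed in
the literature; the sine-deviation form is the default here and a
`linearized` variant (ordinary covariance of deviations wrapped into
(−π, π]) is available behind a switch — the two agree for tight data and
the choice is recorded in the function signature rather than hidden.
Windows whose circular mean is undefined (R̄ ≈ 0) yield missing metrics
rather than zeros, to avoid biasing cohort models. Determinants are
clamped at 0 against negative round-off; warm-up, invalid and
gimbal-locked samples are excluded before computing window metrics.

Note the scale implication: because sine deviations are bounded, the
generalized variance of a sine-deviation covariance cannot exceed ~1/8 for
three axes; empirical values reported on other normalizations can run
larger. Comparisons across studies should therefore fix the definition
first.

## Longitudinal models

Per-metric age trends use a linear mixed-effects model
`metric ~ age·cohort` (months, treatment coding) with a random intercept
per child, fitted by REML (statsmodels `MixedLM`); p-values are Wald tests
on the fixed effects, α = 0.05, no multiple-testing correction. "Random
child effects" admits several readings; the random intercept is the
minimal one, and the age slope is a within-child effect for which the
Wald z-test is close to nominal at the simulated cohort sizes (type-I
error ≈ 5% at 25 children × 4 visits in the calibration runs). When the
optimizer fails to converge the model is refitted with a derivative-free
method; only a genuinely singular fit (non-finite fixed-effect standard
errors) triggers the documented fallback of dropping the interaction, and
the fallback is recorded in the result's notes. On balanced data the
fixed-effect estimates coincide with OLS (a GLS identity under compound
symmetry), which the suite exploits as an independent check.

The angle-contrast model stacks the three circular SDs in long format and
fits `csd ~ angle·age` (pitch as reference) with a random intercept per
child, giving roll−pitch and yaw−pitch level and slope contrasts.

Metric–outcome correlations are Spearman by default (Pearson available),
across children pairing a metric at one visit age with the MSEL GM score
at the same or a later visit (concurrent-and-future pairs only), restricted
to non-walking visits so the global body posture is comparable across
ages; ties receive average ranks.

## Synthetic data

The trajectory generator emulates free infant leg movement in a supine or
seated context: movement bouts (Poisson onsets, default 6/min, ~4 s long
with 0.5 s raised-cosine ramps) alternating with quiescence. Within bouts
each Euler angle follows a band-limited Gaussian path (cutoff 0.5 Hz);
between bouts the orientation is held. Each axis is rescaled so its
overall dispersion equals the target — default (15°, 35°, 35°) for
(pitch, roll, yaw), chosen so the rendered circular SDs land in the range
observed for infants in the second half of the first year, with pitch
systematically tighter than roll and yaw as observed empirically. The
rendering model is

- accel = gravity rotated into the sensor frame + band-limited (≤ 6 Hz)
  movement acceleration during bouts (SD 0.5 m/s²) + white noise
  (SD 0.05 m/s²),
- gyro = exact body rates (whose exponential-map integration reproduces
  the quaternion path bit-for-bit) + constant bias (default
  (0.02, −0.015, 0.01) deg/s, the magnitude implied by a 6°-per-5-min
  drift) + white noise (SD 0.2 deg/s),
- mag = world field (unit vector dipping 60° below horizontal,
  mid-latitude) rotated into the sensor frame + white noise (SD 0.01).

The movement-acceleration band sits below the 8 Hz gravity cutoff by
construction, mirroring the empirical observation that infant-generated
accelerometer fluctuations concentrate below 8 Hz; the band edge is
configurable to stress-test the filter. All generators are pure functions
of (config, seed).

What the simulator does **not** model: biomechanical limb constraints and
jointed kinematic chains, contact/impact spikes, sensor saturation,
magnetic disturbances from the environment, soft-tissue artefact, and
temperature-dependent bias drift. Passing tests on synthetic data
therefore demonstrate correctness of the estimators under the stated
signal model, not hardware-level validity.

The cohort generator draws each metric from
`baseline₃ₘₒ + slope·(age − 3) + b_child + ε` with defaults anchored to the
observed cohort scales: 3-month baselines (14.8°, 21.4°, 24.3°, 0.025),
slopes (0.71, 3.63, 4.17 °/month; 0.06/month), between-child SD 5° /
residual SD 8° for the angle SDs and 0.10 / 0.15 for the generalized
variance. Draws are *not* truncated at zero: near the floor (generalized
variance at 3 months) truncation would bias exactly the slopes the tables
are used to recover, so the linear-Gaussian model is kept honest and small
negative values are tolerated in simulated tables. MSEL GM is generated as
`20 + 2.5·age + link·gen_var + N(0, 4²)` with a default link of 10 points
per unit generalized variance (set to 0 for null calibrations). The
walking flag is always False, matching the restriction of the analysis to
non-walking visits.

## Problem sizes in tests and the acceptance script

Simulation-based checks use 5-minute recordings at 20 Hz (6000 samples),
cohorts of 50 children × 4 visits for recovery, 25 children for the
1000-replicate type-I calibration, and 48 children for the null-correlation
calibration at the single-visit sample size; the acceptance script averages
orientation recovery over 5 recordings and slope recovery over 25 cohorts.
These sizes make every quantity stable to well within its stated tolerance.

## Known limitations

- The Madgwick gain β is fixed per run; no motion-adaptive gain.
- Heading is relative; recordings in magnetically distorted environments
  will show yaw drifting toward the distorted reference.
- The EMA bias estimator assumes the limb is genuinely still during
  detected quiescence; slow creeping movement below the threshold biases
  the estimate (bounded by the threshold itself).
- Circular covariance definitions differ across the literature; the
  generalized variance is only comparable across analyses using the same
  definition.
- Mixed-model p-values are Wald-based; at very small cohort sizes a
  likelihood-ratio or Satterthwaite approach would be preferable.
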