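# Methods

This note records the models implemented in `imugait`, their assumptions,
the defaults and why, and the design choices made where the design was
genuinely open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scope and conventions

Everything is sagittal-plane only: each body segment (trunk, thighs, shanks,
feet) is described by one inclination angle θ(t) in degrees, and joints by
the three trigonometric identities

    θ_ankle = −90 − θ_shank + θ_foot
    θ_knee  = θ_thigh − θ_shank
    θ_hip   = −(θ_trunk − θ_thigh − 180)

In the stand-up neutral pose the segment inclinations are trunk = +90°,
thigh = shank = −90°, foot = 0°; these are the unique values (up to common
360° shifts) that make all three joints read 0° at quiet standing, which is
how the convention was fixed.  Leg segments are wrapped into [−270, 180]°,
other segments and joints into [−180, 180]°.  Wrapping is applied *after*
the joint equations: they are affine and commute with consistent 360°
shifts, whereas wrapping mid-computation would cut continuous filter
outputs.  The equations are rank-3 in the four segment angles, so the
inverse map (used by the simulator) takes the trunk series as the free
closure; the round trip is the identity to machine precision and is tested
to 1e-9°.

Joint angular velocity uses central differences (one-sided at the ends)
times f_s; the differentiator is a free choice and central differences give
O(f_s⁻²) interior error.

## Static calibration

The first `window` seconds (default 10 s, the length of the device's
stand-up routine) of every trial are assumed motion-free.  Per axis the
gyro offset is the mean of the *scaled* window samples (counts × 0.06
deg/s); computing the offset after scaling keeps the calibration equation
dimensionally consistent (an offset in raw counts cannot be subtracted from
a value in deg/s).  The accelerometer reference is ‖(mean ax, mean ay,
mean az)‖ in counts, and calibration divides raw counts by that norm;
because numerator and denominator share the count unit, the nominal
0.00024 g/count factor cancels and is kept only for reporting raw axes
in g.  State always starts at zero and is re-estimated from each trial's
own window — no parameters carry over.

Because an incorrect posture during the stand-up corrupts everything
downstream, `StaticCalibrator` validates the window by default: scaled gyro
SD above 3 deg/s, or accelerometer norm varying more than 5 % of its mean,
rejects the fit.  Both thresholds are conservative for quiet standing
(tremor and sway are an order of magnitude smaller) and are parameters.

Note one degeneracy relevant to testing: the calibrated gyro mean over the
calibration window itself is identically zero (the offset *is* that mean),
so residual-bias checks are performed on held-out static samples.

## Segment orientation estimation

Three estimators share the same inputs (calibrated sagittal rate ω and the
accelerometer inclination atan2(a_anterior, a_vertical), unwrapped to be
continuous and anchored at the initial pose):

* **Rectangular integration** — the drifting baseline; a constant rate
  bias b produces an exactly linear error trend of slope b, which anchors
  the drift metrics.
* **Complementary filter** — θ_k = 0.98 (θ_{k−1} + ω_k/f_s) + 0.02 z_k,
  gains fixed (gyro trusted short-term, accelerometer long-term).  Sample 0
  is the initial angle; the recurrence runs from sample 1, so with zero
  inputs the output decays exactly geometrically (this identity is tested
  at machine precision; the implementation is a first-order IIR evaluated
  by `scipy.signal.lfilter` with the same floating-point operation order as
  the explicit loop).  A constant rate bias does not make this filter
  drift: it converges to a constant offset of (0.98/0.02)·b/f_s.
* **Kalman filter** — state [θ, gyro bias], per-step covariances
  Q = diag(0.005, 0.0003) and R = diag(0.0669, 0.039).  The raw rate drives
  the prediction θ ← θ + (ω − bias)/f_s.  The published 2×2 covariances
  imply a 2-vector measurement [accelerometer angle, raw rate], but the
  raw rate is already the control input, so a naive rate innovation is
  identically zero.  The implementation therefore uses the only
  non-circular pairing: the angle channel observes θ directly, and the
  rate channel observes the *bias*, z₂ = ω − d(z_acc)/dt, the
  accelerometer-derived rate supplying an independent reference for the
  true rate.  Under a static pose z₂ equals the bias exactly, which is what
  makes the bias state observable fast (tested: recovered within 5 % in
  10 s); during motion the differentiated accelerometer angle is noisy,
  which the relatively large R₂₂ down-weights.  Initial covariance
  P₀ = diag(1, 0.1).

Initialization uses the accelerometer inclination of the mean calibrated
gravity vector over the static prelude; vectors with norm ≤ 0.5 g are
rejected as unreliable (near free-fall).

## The synthetic gait/IMU simulator

The simulator is the package's test bed and defines the conditions every
property is checked under.

**Kinematics.**  Joint trajectories are stride-periodic harmonic sums,
θ_joint(t) = offset + Σ_k A_k sin(2πkt/T + φ_k) with stride period
T = 2·60/cadence.  The default flat-walk profile uses 2–3 harmonics per
joint shaped on normative adult curves (hip one main oscillation ≈ −10…30°,
knee a double bump ≈ 0…60° with its minimum near 0° in stance, ankle
≈ −15…10°), cadences 85/105/125 steps/min for slow/normal/fast with ±15 %
amplitude scaling, and offset adjustments per terrain (more hip/knee
flexion on stairs, trunk lean on ramps).  The left side runs half a stride
out of phase.  These shapes are plausibility-level, not subject-specific;
passing tests demonstrate correctness of the processing chain, not
anthropometric realism.

**Sensor model.**  Gravity is exactly 1 g; the accelerometer measures the
gravity unit vector rotated by θ plus optional white noise; segment linear
acceleration is omitted by default so the accelerometer-inclination
relationship stays exact (a toggleable idealization — real gait violates it
at heel strike, which is one reason real accelerometer channels are far
noisier than this model).  The in-plane (mediolateral) gyro axis carries
the angular rate plus bias, noise, and drift; out-of-plane axes carry bias
and noise only.  Counts are produced by dividing by the fixed scale factors
(0.06, 0.00024) and rounding halves away from zero — an unbiased 16-bit ADC
model.

The gyro rate is synthesized as the backward difference
ω_k = (θ_k − θ_{k−1})·f_s rather than the analytic derivative: a rate gyro
is exactly what a rectangular integrator consumes, so this choice makes the
noiseless loop closed (integration reconstructs θ up to quantization,
≈ 0.01° over 30 s at 100 Hz), whereas an analytic-derivative source would
leave O(1/f_s) truncation error (~0.3° for the default amplitudes) that
belongs to neither the sensor model nor the estimator under test.

**Drift.**  `drift_slope` (deg/s, scalar or per-segment) is injected as a
constant angular-rate offset active only after the static prelude, so
static calibration cannot cancel it and the orientation error grows
linearly at exactly the configured rate.  `inject_turn(trial, at, k)` marks
a 180° turn and multiplies the post-turn drift rate by k.  Note that a
drift rate common to all sensors cancels in the joint equations (e.g.
θ_knee = θ_thigh − θ_shank), so joint-level drift requires per-segment
rates; turn-increment recovery is therefore validated on segment
orientations, and gait-waveform oscillation biases short-window OLS slopes
as O(A/(m²T)) for m strides — drift slopes are measured on quiescent
postures or on drift-error series (estimate minus truth), or over windows
long relative to the stride.

**Regression benchmark.**  `make_regression_benchmark` emulates the error
chain of a fused-but-uncorrected joint angle across subjects: per subject a
random cadence (90–120 steps/min) and amplitude scale (±15 %), and a
measured angle = slightly attenuated (0.95–0.99) and lagged (10–30 ms)
true angle + constant offset (−4.5°) + linear drift (0.05 deg/s) +
band-limited noise (Gaussian white noise smoothed with a 0.2-s kernel,
SD 0.5°).  The lag/attenuation term models fixed-gain filter dynamics and
is the physical reason the angular-velocity input carries information (the
induced error ≈ −lag·velocity is invisible to an angle-only regressor); the
band-limited noise models the slowly varying fusion residual — white
sample-to-sample noise would be an unrealistic error model for a filtered
estimate and would differentiate into a velocity channel dominated by
noise.

## Drift-correction regressors

All inputs and targets are min–max normalized into [−1, 1] (state stored,
inverse applied after prediction).  Three families:

* **Shallow network** — one hidden layer of 5–20 tanh units (the standard
  sigmoid transfer of this model family) and a linear output, trained by
  damped least squares (Levenberg–Marquardt style: solve
  (JᵀJ + μI)δ = Jᵀr, μ ×0.1 on accepted steps, ×10 on rejected).  Training
  stops when any of four conditions fires: validation error rising for 10
  consecutive iterations (15 % of the training data held out per fit,
  seeded), MSE reaching 0, gradient infinity-norm below 1e-7, or μ
  exceeding 1e10; plus a 200-iteration cap.  The stopping semantics, not
  the optimizer brand, define reproducibility; fits are deterministic given
  the seed.
* **Regression tree** — binary splits maximizing MSE reduction
  (scikit-learn `DecisionTreeRegressor`), minimum leaf size from the menu
  {4, 12, 36, 50, 100} (fine → coarse) and a 200-observation branch
  minimum.
* **ε-SVR** — linear/quadratic/cubic/Gaussian kernels (Gaussian kernel
  scale σ via gamma = 1/(2σ²), σ ∈ {0.35, 1.35, 2.35} in the tuning menu).

Hyperparameters outside these menus are rejected at fit time.
Cross-validation reports per-fold NRMSE and R²; with subject labels, folds
are grouped so evaluation is always on unseen subjects (user independence),
otherwise folds are seeded-random.  Tree split ties follow scikit-learn's
first-best ordering.

## Agreement metrics

* **NRMSE** = RMSE / (max(ref) − min(ref)).  Range normalization was chosen
  because joint angles with tens-of-degrees range then yield the
  dimensionless few-percent magnitudes conventional in gait benchmarking;
  mean normalization is ill-behaved for signals crossing zero.  Constant
  references are rejected.
* **Pearson ρ** — sample correlation; constant inputs rejected.
* **XApEn(m, r)** = Φ_m − Φ_{m+1}, Φ_m the mean log fraction of m-length
  reference templates within Chebyshev distance r of each test template.
  Both series are standardized first, so r is in reference-SD units.
  Defaults m = 2, r = 0.2 — the conventional choices of the
  approximate-entropy lineage; both exposed.  A template with zero matches
  makes the statistic undefined and raises (rather than silently flooring
  the log).  Lower = more synchronous.  The implementation is vectorized
  with a bounded distance buffer and is tested for exact agreement against
  a double-loop reference.
* **Drift slope** — OLS slope against time; **drift ratio** =
  |slope_test|/|slope_ref| (reference slopes below 1e-12 deg/s are treated
  as zero and rejected); **turn drift increment** =
  100·(|slope_after| − |slope_before|)/|slope_before| around the turn
  index.  `trim_transients` drops a configurable lead/tail (default 2 s
  each) to exclude gait initiation/termination before slope analyses when
  no stride annotations exist.
* **Bland–Altman** — mean difference and mean ± 1.96·SD (SD with ddof = 1).
* **One-sample t-test** — two-sided, scipy implementation, α = 0.05.
* **SUS** — odd items contribute (response − 1), even items (5 − response),
  sum × 2.5, averaged over users.

One numerical caveat, found when testing the slope: a zero-mean sinusoid
sampled over whole periods has an OLS slope of order 1/n (≈ 2e-4 at n = 1e4
for unit amplitude), not zero — the continuum symmetry argument does not
survive discrete sampling; the tests bound it at 1e-3 accordingly.

## Pipeline, formats, determinism

`run_pipeline` mirrors the on-device order (calibration window → fusion →
joint trigonometry → optional correction → metrics), writes every
intermediate as CSV/YAML text, and is deterministic: one seed drives
simulation noise, network initialization and fold shuffling, and two runs
of the same configuration are byte-identical (tested).  Timestamps are
float seconds, indices 0-based, sampling capped at 200 Hz.  Stage progress
and failure analogs are logged at info/error level, mirroring the device's
LED feedback semantics.

## Problem sizes in the shipped checks

The test suite and acceptance script use trials of roughly 10–30 strides at
100 Hz (1–4·10³ samples per sensor), 5 synthetic subjects for the
regression benchmark (~6·10³ observations), and 100-pair oracle sweeps —
sizes chosen so the whole battery completes in well under a minute while
leaving every asserted margin (e.g. RMSE ≤ 1°, slope within 5 %) an order
of magnitude away from the measured values in the noiseless cases.

## Known limitations

* Sagittal-plane only; no quaternions, no magnetometer, no 3-D angles.
* The accelerometer model omits linear acceleration and soft-tissue
  artifact, so real-data fusion error will exceed the synthetic figures;
  passing tests validate the algorithms, not field accuracy.
* Drift is modeled as piecewise-constant-rate (linear angle trend), the
  same assumption the drift metrics make; real gyro drift has random-walk
  components these metrics summarize only as a trend.
* The published 2×2 Kalman covariances do not uniquely determine the
  state/measurement model; the bias-observing rate channel used here is one
  defensible completion.
* SUS scoring and questionnaire IO are provided, but usability data are
  user-supplied; there is nothing to simulate.
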