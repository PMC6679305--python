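# Methods

This note documents the models, numerical choices and limitations behind
`turnwork`. Notation: lab frame `x` along the lane, `z` vertical; sensor
frame `x` backward, `y` up, `z` to the athlete's left; `g = 9.81 m/s²`.

## 1. External mechanical work of a turn

The mass-specific external mechanical energy of the centre of mass is
`E_ext = ½‖v‖² + g h`. Over the 2 s window centred on a turn event `t*`,

```
W⁺ = Σ max(ΔE_ext, 0)        W⁻ = |Σ min(ΔE_ext, 0)|
```

summed over consecutive samples. Both are stored as magnitudes in J/kg
(`W⁻` is plotted negative in some conventions; the tables here keep it
positive). Two exact identities anchor the implementation and are asserted
by the tests:

* **telescoping** — `W⁺ − W⁻` equals `E_ext` at the window end minus at
  the window start, for every window;
* **level braking** — decelerating from 3 m/s to rest on the level costs
  exactly `½·3² = 4.5 J/kg` of negative work.

Velocity is obtained by central differences of the *filtered* trajectory
(zero-lag 2nd-order Butterworth, 15 Hz cut-off), in that order: filtering
after differentiation would amplify noise before it can be removed.
`v_before`/`v_after` are window *means* of the speed norm over
`[t*−1, t*]` / `[t*, t*+1]` rather than instantaneous samples; the mean is
robust to sample-level noise and is the quantity the generator can supply
in closed form.

## 2. The synthetic shuttle-run generator

The generator is built from piecewise-analytic profiles so that every
derived quantity has an independent closed form:

* **Lane motion.** Constant-speed legs joined by raised-cosine velocity
  reversals of duration `turn_duration` (0.5 s). The leg speed is derived
  from the configured average pace so that consecutive position apexes are
  exactly one lane length apart; velocity and acceleration are continuous
  everywhere.
* **Vertical motion.** A raised-cosine CoM dip of depth
  `vertical_dip_depth` (0.4 m) and duration 1.4 s centred on each turn,
  plus a step-frequency (3 Hz) sinusoidal bounce that is smoothly gated
  out inside the dip window.
* **Orientation.** Pelvis yaw rotates ±180° per turn with a raised-cosine
  rate profile (peak ≈ 720 deg/s, well inside the ±2000 deg/s range); the
  sign of the rotation is the pivot side. Step-frequency roll/pitch
  oscillations (25/18 deg/s) add benign gyroscope content.
* **IMU synthesis.** The accelerometer reads the rotation of
  (CoM acceleration + gravity) into the sensor frame, plus
  Gaussian-windowed foot-strike transients (20 m/s², σ = 8 ms) on the
  vertical channel — impact content that the CoM trajectory does not
  contain, which is exactly why the player-load feature is informative.
  Static biases, white noise (0.05 m/s², 1 deg/s), linear gyroscope drift
  (0.1 deg/s per minute) and range clipping complete the model.
* **Barometer.** CoM altitude is encoded through the international
  barometric formula `h = 44330·(1 − (p/p₀)^0.1903)` with white noise of
  0.10 m altitude-equivalent; the processing side inverts the same formula
  (round-trip exact to < 1 mm) and smooths with a zero-lag 10th-order
  1 Hz Butterworth.
* **Clocks.** IMU and barometer timestamps are shifted by a clock offset
  drawn uniformly in ±2 s unless fixed, so the synchronization stage is
  always exercised.

**Ground truth** is evaluated from the analytic profiles on a 2048 Hz grid
(speeds as window means, work as summed energy increments), independent of
the 100 Hz measurement path. On noiseless trials the pipeline recovers
events within one mocap sample, speeds within 1% and work within 2%.

**Calibration.** The defaults are fixed once so that the closed-form
per-turn means of a cohort match the target statistics of an elite-level
5 m shuttle-run protocol: mean approach speed 2.61 m/s (target 2.60),
mean positive work 8.49 J/kg (target 8.49), filtered barometric deltas
∓0.40 m (targets −0.39/+0.41). The operative knobs are the average pace
(2.55 m/s — the 1 s pre-turn window mean sits slightly above the pace
because the leg speed exceeds it), the turn duration (0.5 s, which sets
the kinetic share `½v_leg²`), the dip depth/duration (potential share and
barometric signature) and the step bounce amplitude (0.016 m, the extra
oscillatory work inside the window).

**Cohorts.** Subject-level parameters (pace ±0.2 m/s, mass ±7.3 kg,
height ±0.05 m, dip depth ±0.05 m, step frequency ±0.2 Hz, impact/bounce
scale) are jittered around the cohort means with sub-seeds derived
deterministically from the master seed; 13 subjects × 72 turns ≈ 936
turns, the scale of the emulated protocol. Anthropometrics are stored in
the metadata but never encoded in the signals — all responses are
mass-specific and the models use no anthropometric predictor.

**What the generator does *not* model** — and hence what passing tests do
not show about real data: soft-tissue artefact beyond the stereotyped
impact bursts, between-turn technique variability, fatigue-induced speed
decay (the exhaustion protocol), marker noise and gaps, orientation error
of the sensor mount, and temperature-driven barometer drift. The
feature→response relationship of the synthetic cohort is consequently far
cleaner and more *linear* than in real athletes: held-out R² values are
0.96–1.00 instead of the 0.4–0.7 regime typical of field data, and the
nonlinear families offer no systematic advantage over multiple linear
regression here (they tie within noise for the speeds and lead slightly
for the work responses). Relative statements about model families on this
cohort therefore do not transfer to real recordings.

## 3. IMU processing

* **Static biases** come from a still-unit recording (channel means;
  gravity subtracted on the vertical accelerometer axis). A minimum
  duration guard (60 s) rejects too-short calibrations; bias recovery on a
  noisy recording is within `3·SD/√n` of truth and idempotent.
* **Turn detection** low-passes the bias-corrected vertical-axis angular
  velocity at 0.5 Hz (zero-lag, 2nd order) and takes peaks of its absolute
  value above 30 deg/s with ≥1.5 s spacing. The zero-lag filter keeps
  interior peaks on the true event times to within one 512 Hz sample on
  noiseless data; the first and last peaks shift by up to ~8 ms because
  they see an opposite-sign neighbour pulse on one side only.
* **Zero-lag filtering** everywhere uses `sosfiltfilt` with reflective
  padding extended to ~3 time constants of the cut-off, so slow filters
  (0.5 Hz on 512 Hz data, 1 Hz on the barometer) settle before the data
  begin.
* **Synchronization** builds Gaussian-smoothed (σ = 50 ms) unit-impulse
  trains at each system's candidate event times on a common 100 Hz grid,
  takes the lag of maximum normalized cross-correlation within ±3 s, then
  refines the grid-quantized lag by the mean matched-event residual. The
  refined estimate averages per-event detection jitter away
  (error ≈ jitter SD / √n_events); a peak correlation below 0.2 raises a
  synchronization error rather than returning a spurious lag. On the
  calibrated noisy cohort the residual per-event error SD is ~0.003 s.
* **Features.** The 18 predictors are listed in `turnwork.features`.
  Integrals are SI trapezoids (with `dt`; gyroscope converted deg→rad
  beforehand so the integrals are in radians), skewness/kurtosis are
  population moments of the norm signals with no excess-kurtosis
  correction (a constant window raises an undefined-moments error), and
  the barometric deltas are signed so that a dip gives a negative
  before-delta and positive after-delta. Events whose 2 s window or 1 s
  barometric margins fall outside a recording are dropped and logged, as
  are events whose net yaw rotation is below 45° (side undetermined).
* **Outlier screen.** A turn is removed when *any* response or feature
  lies outside its column mean ± 3 SD, with the statistics computed once
  on the pooled dataset (no iteration — iterating the rule would keep
  shrinking heavy-tailed columns). On the near-Gaussian synthetic cohort
  this removes ~5% of turns. The coefficient of variation is reported as
  SD/|mean| and flagged not-applicable for zero-mean or strongly bimodal
  columns (CV > 50), e.g. the vertical-axis gyroscope integral whose sign
  encodes the side.

## 4. Models and evaluation

The four regression families and four classifiers are standard
scikit-learn estimators behind the package's `TurnRegressor` /
`TurnSideClassifier` surface. Hyperparameters that the protocol fixes:
40 boosting stages, 40 tanh hidden neurons, 70/15/15 split for the
neural-network protocol. Hyperparameters the protocol leaves open are
fixed by convention and recorded in the report: SVR epsilon-tube
`0.1·SD(y)`, Gaussian kernel width by the median pairwise-distance
heuristic on standardized inputs (γ = 1/(2·median²)), `C = 10`, boosting
learning rate 0.1, network learning rate 0.01 with tolerance 1e-5.

Evaluation is a seeded shuffled 10-fold cross-validation with metrics
pooled over held-out predictions (`R² = 1 − SSE/SST`, RMSE, MAE;
accuracy/sensitivity/specificity in percent with *left* as the positive
class, AUC from held-out scores). The neural network defaults to the
70/15/15 protocol — fit on 85% with validation-based early stopping,
report on the held-out 15% — and can be forced into k-fold mode, where it
trains to tolerance instead: early stopping is a property of the split
protocol, not of the fold loop, and a premature validation stop otherwise
leaves borderline points unresolved. Folds are *not* stratified by
subject by default (the protocol prescribes a plain random partition);
pooled-turn CV therefore leaks subject identity across folds, which is
one reason synthetic R² values are optimistic — `process_cohort` keeps
the subject column so a grouped partition can be run when that bias
matters.

Boosted-trees feature importances are split-gain based, normalized to sum
to one. On the synthetic cohort they concentrate on the forward-axis
acceleration integrals (F2/F5) for the speeds and add the barometric
deltas (F17/F18) for the work responses; the side is carried almost
entirely by the sign of the vertical-axis gyroscope integral (F12), which
is why even LDA classifies it perfectly.

## 5. Degenerate inputs and tie-breaks

Monotone trajectories yield an empty event list (not an error); extrema
closer than 1.5 s are suppressed (step-level wiggles); a window truncated
by the recording bounds drops the event with a logged warning; zero
pressure or out-of-troposphere altitudes are rejected; a constant window
has undefined moments; single-class label sets and fewer rows than folds
raise immediately; stochastic model families require an explicit seed.
Identical configurations (same seed) produce bit-identical trials,
datasets and reports.

## 6. Problem sizes

The default study size — 13 subjects × 72 turns ≈ 936 turns, ~155 s per
trial at 100/512/64 Hz — processes in a few seconds per cohort and is the
size used by the acceptance script and the heavier tests; unit tests run
on 3–12-turn trials. These sizes were chosen to match the emulated
protocol's scale while keeping a full end-to-end run interactive.
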