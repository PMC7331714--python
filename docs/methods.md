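# Methods

This note documents the models, estimators and design choices behind
`serialdep`, in the spirit of a package methods appendix: what is
computed, under which assumptions, and what the shipped validation does
and does not establish.

## Generative model

A trial's memory trace is a random walk on the circle over the delay,

    theta_t = theta_{t-1} + sigma * xi_t - DoG(theta_{t-1} - theta_prev),
    t = 1..T,  theta_0 = stimulus angle,  xi_t ~ N(0, 1) i.i.d.

The derivative-of-Gaussian drift

    DoG(delta) = a * w * c * delta * exp(-(delta * w)^2),  c = sqrt(2e)

is odd in the signed circular distance `delta`, so subtracting it moves
the trace *toward* the previous trial's reference regardless of which
side it lies on; with `c = sqrt(2e)` its maximum over distance is exactly
`a`, attained at `delta = 1/(w*sqrt(2))`. The reference is the previous
trial's stimulus by default (`reference_mode="previous-stimulus"`); the
endpoint of the previous trial's simulated trace is available as
`"previous-trace-end"`. The first trial of each session has no reference
and diffuses freely.

The report is the trace endpoint theta_T distorted by

* an inhomogeneity bias `-A * cos(f * theta_0)` (defaults A = 0.2,
  f = 4 cycles): a target-dependent distortion emulating the strong
  perceptual anisotropies of color space;
* a constant rotational bias (default +1.4 degrees): a uniform clockwise
  or counterclockwise report offset;
* with probability `guess_prob` (default 0), replacement by a uniform
  random angle — a memory-less guess. Guessing is an extension used to
  exercise the guess-rate controls; the default keeps the core model
  exact.

### Units

All internal angles are radians. The canonical parameter values
(`sigma = 0.006` per step, `a = 0.09`, `w = 0.007`, inhomogeneity
amplitude 0.2) are taken verbatim as radian-based quantities under the
default `angle_convention="radians"`; an explicit `"degrees"` switch
reinterprets them (the rotational bias is always specified in degrees).
The radian reading is the self-consistent one at analysis scale: with
`T = 50` steps it yields a response dispersion of
`sigma*sqrt(T) ~ 0.042 rad ~ 2.4 deg` and a simulated serial bias of a
few degrees, both in the empirically plausible range, while the
analysis windows (pi/2, pi/30) are defined on the same circle. The delay
length `T` is a free parameter (default 50, `n_steps`); the
parameter-recovery checks are invariant to it because they compare
estimates against the *configured* biases, not against absolute drift
magnitudes.

### Simulation strategy

With the previous-stimulus reference, every trial's attractor is known
up front, so the walk is vectorised across all subjects and trials and
loops only over the T timesteps; the trace-end mode chains trials
sequentially (vectorised across subjects). Identical seeds give
bit-identical trial tables.

## Estimators

* **Error**: `theta_e = wrap(report - target)` in (-pi, pi].
* **Previous-trial distance**: `theta_d = wrap(prev_reference - target)`,
  with the previous *target* (default) or previous *report* as reference.
  With this sign convention attraction makes `theta_e` co-vary with
  `theta_d`, so the folded error is positive under attraction.
* **Folded error**: `theta_e * sign(theta_d)`. For any trial set whose
  `theta_d` distribution is sign-symmetric, an additive error constant
  cancels *exactly* in the mean folded error — this is an algebraic
  identity, not an asymptotic property, and the test suite asserts it to
  machine precision.
* **Serial-bias curve**: means in sliding windows of size pi/2 stepped by
  pi/30. Folded curves run over |theta_d| in [0, pi] with windows
  truncated at the domain ends (the folded distance is not periodic);
  unfolded curves run over the full circle with wrapped windows. Empty
  windows are reported as missing, never as zero.
* **Mean folded error**: average over trials with |theta_d| <= 90 deg
  (configurable), the scalar strength of serial dependence.
* **Guess handling**: trials with |error| > 90 deg (strict) are
  classified as guesses and excluded from all bias analyses; by default a
  guess still serves as the *reference* for the following trial (only its
  own error is discarded) — `drop_guess_references=True` flips this.
* **Build-up slope**: per session, the OLS slope of folded error on trial
  number; sessions averaged into one slope per subject. Session thirds
  (near-equal contiguous parts, remainder to the earlier thirds) support
  the first-vs-last-third curve comparison; the comparison pair is
  configurable, defaulting to the session extremes because the build-up
  hypothesis concerns them.
* **Controls**: guess fraction and mean squared error in independent
  (non-overlapping) 20-trial windows, one OLS slope per session averaged
  per subject, regressed against the build-up slopes
  (`slope_association`) pooled and per experiment.

## Inference

Percentile bootstrap everywhere (the simplest scheme consistent with
resampling-based error bars; no BCa correction). The resampling unit for
group curves and scalars is the subject when subject labels exist,
otherwise the trial; both are exposed. Two-level aggregation supports
*experiment-weighted* (average subjects within experiment, then resample
experiment means — each study counts equally) and *subject-weighted*
(pool subjects) modes; with a single experiment the modes coincide. The
bootstrap test of a zero mean uses the tail mass of the resampled mean,
two-tailed, floored at 1/n_boot so Monte-Carlo p-values are never exactly
zero. Curve differences between two trial sets use pointwise permutation
tests (group labels shuffled within subject when possible), explicitly
*without* multiple-comparison correction, flagged in the result metadata.
The classical one-sample t-test is provided for scalar group tests.

Default draw counts are 10,000 for reported inference; tests and the
example pipeline use smaller, seeded plans.

## What the synthetic data does and does not establish

The simulator reproduces the structural features the analyses rely on:
uniform circular targets, diffusion-limited precision, previous-trial
attraction with a DoG distance profile, additive systematic biases, and
stationary or ramped attraction amplitude. Passing the validation suite
therefore shows the estimators are *unbiased and calibrated under this
generative model* — folding removes exactly additive biases, the null
rejects at the nominal rate, injected attraction and build-up are
recovered with the right sign and ordering. It does not establish
anything about features the model lacks: multi-item interference, swap
errors, lapses correlated with the stimulus, non-stationary motor
biases, multiplicative (non-additive) distortions, or learning effects
beyond a linear drift-amplitude ramp. In particular, folding is exact
only for biases that are additive in the error and independent of
theta_d's sign.

## Numerical choices and edge cases

* Angles canonicalised to [0, 2*pi); signed quantities to (-pi, pi], with
  explicit guards for the floating-point edge where `mod` rounds to the
  period itself.
* `sign(theta_d) = 0` when theta_d is exactly 0 (the folded error of such
  a trial is 0; measure-zero under continuous targets).
* Degenerate inputs fail loudly: sessions with fewer than 2 usable trials
  (slopes) or 3 trials (thirds), zero-variance predictors, empty trial
  sets, duplicate trial keys, non-finite angles. "No usable trials" is a
  distinct error, never silently reported as a zero effect.
* Validation problem sizes: bias-recovery and attraction checks use 100
  subjects x 1,000 trials (the scale at which the folding correction was
  characterised); null calibration uses 600 replicate subjects x 800
  trials; stationarity uses 80 replicate experiments of 50 subjects x 200
  trials. The all-windows null check on the folded curve uses 99%
  pointwise intervals as a family-wise-aware level for ~31 heavily
  overlapping windows (roughly 3-4 effectively independent).

## Known limitations

* The build-up regression is ordinary least squares on wrapped errors; at
  very large dispersion (near-guessing regimes) wrapping compresses the
  error scale and slopes are biased toward zero.
* Percentile bootstrap intervals slightly under-cover at small subject
  counts (n < ~30); the stationarity validation accounts for this.
* The simulator draws one session per subject; multi-session subjects are
  supported by the analysis code but must be assembled by the caller.
* `set_size` is bookkeeping only: the simulator is single-item, and the
  analyses treat the cued target as the sole reference.
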