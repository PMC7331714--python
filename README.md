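# serialdep

Serial dependence in delayed-estimation working memory: **folded-error**
bias estimation, within-session **build-up** regression, resampling
inference, and a random-walk + DoG-drift **trial simulator**.

## The problem

In delayed estimation of color, a subject briefly sees a colored stimulus,
holds it in memory over a blank delay, and reports the color on a wheel.
Reports are not only noisy: they are *attracted toward the previous
trial's stimulus* (serial dependence). Estimating this attraction from
behavior is complicated by two systematic distortions that have nothing to
do with the previous trial — target-dependent inhomogeneity biases of the
color space and constant rotational offsets — which shift the classic
serial-bias curve and can masquerade as attraction or repulsion.

`serialdep` implements a model-free correction. With the signed circular
error θ<sub>e</sub> = wrap(report − target) and the previous-to-current
target distance θ<sub>d</sub> = wrap(previous reference − target), the
**folded error** is

> θ′<sub>e</sub> = θ<sub>e</sub> · sign(θ<sub>d</sub>)

Any additive systematic bias cancels exactly in the mean folded error
(θ<sub>d</sub> is symmetrically distributed when stimuli are uniform on
the circle), while genuine attraction survives: positive mean folded
error ⇒ attraction, negative ⇒ repulsion. Serial-bias curves are means in
sliding windows of π/2 every π/30 over |θ<sub>d</sub>|; the scalar
statistic averages folded errors at |θ<sub>d</sub>| ≤ 90°. Within-session
**build-up** is the OLS slope of folded error against trial number (one
slope per session, averaged per subject), with bootstrap inference either
subject-weighted or experiment-weighted.

The package also ships the generative model used to validate all of this:
each trial's memory trace is a circular random walk
θ<sub>t</sub> = θ<sub>t−1</sub> + σξ<sub>t</sub> − DoG(θ<sub>t−1</sub> − θ<sub>prev</sub>),
whose derivative-of-Gaussian drift
DoG(δ) = a·w·c·δ·exp(−(δw)²), c = √(2e), pulls the trace toward the
previous trial; reports add an inhomogeneity bias −0.2·cos(4θ₀), a
constant 1.4° rotation, and optional uniform guesses (reports > 90° from
the target are classified as guesses and excluded from bias analyses).

## Worked example

```python
import serialdep as sd

cfg = sd.SimConfig(n_subjects=20, n_trials=500, seed=7)   # defaults: a=0.09 kernel,
trials = sd.simulate_experiment(cfg)                      # both systematic biases on
res = sd.SerialBiasModel(trials).fit(sd.ResamplingPlan(n_boot=2000, seed=7))
print(res.summary())
```

```
Serial dependence (folded-error) analysis
=============================================
reference: previous target     folded: True
subjects: 20     trials kept: 10000  guesses excluded: 0
mean folded error (|th_d| <= 90 deg): +3.176 deg
  95% bootstrap CI [+2.928, +3.433] deg  (n = 5006 trials)
group test over subjects: bootstrap p = 0.0005
one-sample t(19) = 23.312, p = 1.931e-15
positive = attraction to previous trial; negative = repulsion
```

The simulated reports are attracted to the previous target by about 3°
on average within 90°, despite the strong inhomogeneity and rotational
biases — folding removed them without any bias model. Ramping the kernel
amplitude from 0 to 0.09 across the session and fitting the build-up
model recovers the injected growth:

```python
ramp = sd.SimConfig(n_subjects=20, n_trials=500, seed=8,
                    a_schedule="ramp", a_start=0.0, a_end=0.09)
print(sd.BuildUpModel(sd.simulate_experiment(ramp)).fit(
    sd.ResamplingPlan(n_boot=2000, seed=8)).summary())
```

```
Serial-dependence build-up (folded error vs. trial number)
==========================================================
subjects: 20   experiments: 1
group slope, deg of folded error per trial:
  subject-weighted   : +0.01329  CI [+0.01223, +0.01441]  p = 0.0005
  experiment-weighted: +0.01329  CI [+0.01223, +0.01441]  p = 0.0005
positive slope = serial dependence grows through the session
```

A slope of +0.013°/trial over 500 trials is ~6.6° of growth in the folded
error — the build-up injected by the ramp. The CLI wraps the same
pipeline:

```bash
serialdep report --config examples/pipeline.yaml --out out --seed 1
serialdep simulate --config examples/pipeline.yaml --out trials.csv --seed 1
serialdep analyze --input trials.csv --reference target --folded
serialdep buildup --input trials.csv --thirds first,last
```

Trial tables are plain CSV with degrees at the file boundary
(`experiment, subject, session, trial_index, target_deg, report_deg,
set_size`); everything internal is radians.

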