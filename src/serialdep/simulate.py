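"""Generative model of consecutive delayed-estimation trials.

Each trial's memory trace is a random walk on the circle that starts at the
trial's stimulus angle, diffuses with per-step Gaussian noise of scale
``sigma``, and drifts toward the previous trial's reference (its stimulus,
or the end of its simulated trace) through the DoG kernel:

    theta_t = theta_{t-1} + sigma * xi_t - DoG(theta_{t-1} - prev_ref)

with ``xi_t`` i.i.d. standard normal.  Subtracting the DoG term of the
signed distance to ``prev_ref`` moves the trace toward ``prev_ref``
(attraction).  The report is the trace endpoint distorted by a
target-dependent inhomogeneity bias ``-A * cos(f * theta_0)``, a constant
rotational bias, and (optionally) uniform-random guesses.

Internally everything is in radians.  Parameter values are interpreted per
``SimConfig.angle_convention``: with the default ``"radians"`` the numeric
defaults (sigma=0.006, inhomogeneity amplitude 0.2, DoG a=0.09, w=0.007)
are used verbatim as radian-based quantities; with ``"degrees"`` they are
converted.  The rotational bias is always given in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .circular import TWO_PI, wrap_angle, wrap_signed
from .kernel import DoGParams

__all__ = [
    "SimConfig",
    "simulate_trace",
    "apply_report_distortions",
    "simulate_experiment",
]

REFERENCE_MODES = ("previous-stimulus", "previous-trace-end")
A_SCHEDULES = ("constant", "ramp")
ANGLE_CONVENTIONS = ("radians", "degrees")


@dataclass
class SimConfig:
    """Session parameters of the trial simulator.

    Attributes
    ----------
    sigma : float
        Per-step diffusion scale (angle units per sqrt(step)).
    n_steps : int
        Timesteps per memory delay (the walk length T).
    n_trials : int
        Trials per subject session (>= 2 so a previous trial exists).
    n_subjects : int
        Number of simulated subjects (one session each).
    inhom_amplitude : float
        Amplitude of the target-dependent (inhomogeneity) report bias.
    inhom_frequency : int
        Integer number of bias cycles per full circle.
    rotation_bias : float
        Constant report offset, ALWAYS in degrees (converted internally).
    guess_prob : float
        Probability that a report is replaced by a uniform random angle.
    reference_mode : str
        ``"previous-stimulus"`` (default): drift references the previous
        trial's stimulus angle.  ``"previous-trace-end"``: references the
        endpoint of the previous trial's simulated trace.
    a_schedule : str
        ``"constant"`` uses the DoG amplitude as given; ``"ramp"`` sweeps
        it linearly from ``a_start`` to ``a_end`` across the session
        (build-up experiments).
    a_start, a_end : float or None
        Ramp endpoints (same units as ``DoGParams.a``).  Defaults: 0 and
        the kernel's ``a``.
    angle_convention : str
        Interpretation of sigma, inhom_amplitude and the DoG parameters:
        ``"radians"`` (default) or ``"degrees"``.
    seed : int or None
        Seed for the experiment-level RNG.
    experiment : str
        Label written into the output table.
    """

    sigma: float = 0.006
    n_steps: int = 50
    n_trials: int = 1000
    n_subjects: int = 100
    inhom_amplitude: float = 0.2
    inhom_frequency: int = 4
    rotation_bias: float = 1.4
    guess_prob: float = 0.0
    reference_mode: str = "previous-stimulus"
    a_schedule: str = "constant"
    a_start: Optional[float] = None
    a_end: Optional[float] = None
    angle_convention: str = "radians"
    seed: Optional[int] = None
    experiment: str = "sim"

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.sigma < 0 or not np.isfinite(self.sigma):
            raise ValueError(f"sigma must be finite and >= 0, got {self.sigma}")
        if not 0.0 <= self.guess_prob <= 1.0:
            raise ValueError(f"guess_prob must be in [0, 1], got {self.guess_prob}")
        if self.reference_mode not in REFERENCE_MODES:
            raise ValueError(
                f"reference_mode must be one of {REFERENCE_MODES}, got {self.reference_mode!r}"
            )
        if self.a_schedule not in A_SCHEDULES:
            raise ValueError(
                f"a_schedule must be one of {A_SCHEDULES}, got {self.a_schedule!r}"
            )
        if self.angle_convention not in ANGLE_CONVENTIONS:
            raise ValueError(
                f"angle_convention must be one of {ANGLE_CONVENTIONS}, "
                f"got {self.angle_convention!r}"
            )
        if self.inhom_frequency != int(self.inhom_frequency) or self.inhom_frequency < 0:
            raise ValueError("inhom_frequency must be a non-negative integer")


def _as_rng(rng) -> np.random.Generator:
    if rng is None:
        return np.random.default_rng()
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _resolve_units(config: SimConfig, dog: DoGParams):
    """Return (sigma, inhom_amplitude, rotation_rad, dog, a_start, a_end) in radians."""
    a_start = 0.0 if config.a_start is None else float(config.a_start)
    a_end = dog.a if config.a_end is None else float(config.a_end)
    if config.angle_convention == "degrees":
        sigma = np.radians(config.sigma)
        amp = np.radians(config.inhom_amplitude)
        # w is per-degree; per-radian inverse width scales by 180/pi
        dog = DoGParams(a=np.radians(dog.a), w=np.degrees(dog.w), c=dog.c)
        a_start, a_end = np.radians(a_start), np.radians(a_end)
    else:
        sigma = config.sigma
        amp = config.inhom_amplitude
    rotation = np.radians(config.rotation_bias)
    return sigma, amp, rotation, dog, a_start, a_end


def _a_values(config: SimConfig, dog: DoGParams, a_start: float, a_end: float) -> np.ndarray:
    if config.a_schedule == "constant":
        return np.full(config.n_trials, dog.a)
    return np.linspace(a_start, a_end, config.n_trials)


def _walk(theta0: np.ndarray, refs: np.ndarray, a: np.ndarray, sigma: float,
          w: float, c: float, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Run the drift-diffusion walk; NaN in ``refs`` means no attractor."""
    theta = np.array(theta0, dtype=float)
    no_ref = ~np.isfinite(refs)
    ref = np.where(no_ref, 0.0, refs)
    for _ in range(n_steps):
        xi = rng.standard_normal(theta.shape)
        delta = wrap_signed(theta - ref)
        drift = a * w * c * delta * np.exp(-((delta * w) ** 2))
        drift = np.where(no_ref, 0.0, drift)
        theta = theta + sigma * xi - drift
    return theta


def simulate_trace(start, prev_ref, params: DoGParams, config: SimConfig, rng) -> float:
    """Simulate one memory delay; return the final trace angle in [0, 2*pi).

    ``prev_ref=None`` disables the drift (first trial of a session).
    ``rng`` is an int seed or a numpy Generator; supplying it makes the
    walk reproducible.
    """
    gen = _as_rng(rng)
    sigma, _, _, dogr, _, _ = _resolve_units(config, params)
    ref = np.nan if prev_ref is None else float(prev_ref)
    out = _walk(
        np.array([float(start)]), np.array([ref]), np.array([dogr.a]),
        sigma, dogr.w, dogr.c, config.n_steps, gen,
    )
    return float(wrap_angle(out[0]))


def apply_report_distortions(theta_t, theta_0, config: SimConfig, rng):
    """Turn trace endpoint(s) into report(s).

    Applies the inhomogeneity bias ``-A*cos(f*theta_0)``, the constant
    rotational bias, and with probability ``guess_prob`` replaces the
    report by a uniform draw on the circle.  Vectorised over arrays.
    """
    gen = _as_rng(rng)
    _, amp, rotation, _, _, _ = _resolve_units(config, DoGParams())
    t = np.asarray(theta_t, dtype=float)
    t0 = np.asarray(theta_0, dtype=float)
    report = t - amp * np.cos(config.inhom_frequency * t0) + rotation
    if config.guess_prob > 0:
        guesses = gen.uniform(0.0, TWO_PI, size=report.shape)
        u = gen.random(report.shape)
        report = np.where(u < config.guess_prob, guesses, report)
    report = wrap_angle(report)
    return report if np.asarray(theta_t).ndim else float(report)


def simulate_experiment(config: SimConfig, dog: DoGParams = None, rng=None) -> pd.DataFrame:
    """Simulate a full experiment and return a tidy trial table.

    Per subject, stimulus angles are i.i.d. uniform on the circle and
    trials are chained so trial k's drift references trial k-1 according
    to ``config.reference_mode``.  The first trial of each session has no
    attractor.

    Returns
    -------
    DataFrame with columns ``experiment, subject, session, trial_index,
    target, report, set_size`` (angles in radians, canonical domain).
    Deterministic for a given seed.
    """
    if dog is None:
        dog = DoGParams()
    if config.n_trials < 2:
        raise ValueError(
            f"n_trials must be >= 2 (a previous trial must exist), got {config.n_trials}"
        )
    if config.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    gen = _as_rng(config.seed if rng is None else rng)
    sigma, _, _, dogr, a_start, a_end = _resolve_units(config, dog)
    a_per_trial = _a_values(config, dogr, a_start, a_end)
    n_sub, n_tr = config.n_subjects, config.n_trials

    targets = gen.uniform(0.0, TWO_PI, size=(n_sub, n_tr))

    if config.reference_mode == "previous-stimulus":
        refs = np.full((n_sub, n_tr), np.nan)
        refs[:, 1:] = targets[:, :-1]
        ends = _walk(targets, refs, a_per_trial, sigma, dogr.w, dogr.c,
                     config.n_steps, gen)
    else:  # previous-trace-end: sequential over trials, vectorised over subjects
        ends = np.empty((n_sub, n_tr))
        prev_end = np.full(n_sub, np.nan)
        for k in range(n_tr):
            ends[:, k] = _walk(
                targets[:, k], prev_end, np.array([a_per_trial[k]]),
                sigma, dogr.w, dogr.c, config.n_steps, gen,
            )
            prev_end = wrap_angle(ends[:, k])
    ends = wrap_angle(ends)

    reports = apply_report_distortions(ends, targets, config, gen)

    subjects = np.repeat([f"s{i:03d}" for i in range(n_sub)], n_tr)
    df = pd.DataFrame(
        {
            "experiment": config.experiment,
            "subject": subjects,
            "session": "1",
            "trial_index": np.tile(np.arange(n_tr), n_sub),
            "target": targets.ravel(),
            "report": np.asarray(reports).ravel(),
            "set_size": 1,
        }
    )
    return df


def ramped(config: SimConfig, a_end: float, a_start: float = 0.0) -> SimConfig:
    """Convenience: a copy of ``config`` with a linear drift-amplitude ramp."""
    return replace(config, a_schedule="ramp", a_start=a_start, a_end=a_end)
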