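"""Serial-bias curves and the mean-folded-error statistic.

The serial-bias curve is the mean report error as a function of the
distance between the previous and current targets, computed in sliding
windows (size pi/2, step pi/30 by default).  Its folded version averages
the folded error against |theta_d|, which cancels additive systematic
biases (target inhomogeneities, constant rotations) without any model of
them.  The scalar strength of serial dependence is the mean folded error
over trials with |theta_d| up to 90 degrees; positive means attraction,
negative repulsion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .derive import GUESS_THRESHOLD, derive_trials, exclude_guesses
from .resampling import ResamplingPlan, bootstrap_t_test, one_sample_t
from .windows import WINDOW_SIZE, WINDOW_STEP, window_centers, window_membership

__all__ = [
    "SerialBiasCurve",
    "serial_bias_curve",
    "MeanFoldedError",
    "mean_folded_error",
    "NoUsableTrialsError",
    "SerialBiasModel",
    "SerialBiasResults",
]


class NoUsableTrialsError(ValueError):
    """No trial has a usable previous-trial reference (distinct from a zero mean)."""


@dataclass
class SerialBiasCurve:
    """Sliding-window mean (folded) error versus previous-trial distance."""

    centers: np.ndarray
    mean_error: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_trials: np.ndarray
    window_size: float
    step: float
    folded: bool
    ci_level: float
    resample_unit: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "center_deg": np.degrees(self.centers),
                "mean_deg": np.degrees(self.mean_error),
                "ci_low_deg": np.degrees(self.ci_low),
                "ci_high_deg": np.degrees(self.ci_high),
                "n": self.n_trials,
            }
        )

    def plot(self, ax=None, **kwargs):
        from .plotting import plot_serial_bias_curve

        return plot_serial_bias_curve(self, ax=ax, **kwargs)


def _resample_sums(y, member, unit_codes, n_units, plan, rng):
    """Bootstrap window means by resampling units (subjects or trials)."""
    n_windows = member.shape[0]
    sums = np.zeros((n_units, n_windows))
    counts = np.zeros((n_units, n_windows))
    for w in range(n_windows):
        idx = np.flatnonzero(member[w])
        np.add.at(sums[:, w], unit_codes[idx], y[idx])
        np.add.at(counts[:, w], unit_codes[idx], 1.0)
    weights = rng.multinomial(n_units, np.full(n_units, 1.0 / n_units), size=plan.n_boot)
    num = weights @ sums
    den = weights @ counts
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(den > 0, num / den, np.nan)
    return means  # (n_boot, n_windows)


def serial_bias_curve(derived: pd.DataFrame, folded: bool = True,
                      window_size: float = WINDOW_SIZE, step: float = WINDOW_STEP,
                      plan: ResamplingPlan = None,
                      resample_unit: str = "subject") -> SerialBiasCurve:
    """Compute the sliding-window serial-bias curve with a bootstrap band.

    Parameters
    ----------
    derived : DataFrame
        Output of :func:`serialdep.derive_trials` (guess trials should be
        excluded beforehand for the standard analysis); rows without a
        previous-trial reference are dropped here.
    folded : bool
        Folded mode slides over |theta_d| in [0, pi] averaging the folded
        error; unfolded mode slides over theta_d on the circle averaging
        the signed error.
    resample_unit : {"subject", "trial"}
        Bootstrap unit for the confidence band.  Subject-level resampling
        (the default when a ``subject`` column is present) treats subjects
        as the exchangeable unit of a group curve.

    Empty windows are reported as NaN (missing), never as zero.
    """
    plan = plan or ResamplingPlan()
    if resample_unit not in ("subject", "trial"):
        raise ValueError(f"resample_unit must be 'subject' or 'trial', got {resample_unit!r}")
    if "has_reference" not in derived.columns:
        raise ValueError("run derive_trials first")
    usable = derived.loc[derived["has_reference"]]
    if len(usable) < 1:
        raise NoUsableTrialsError("no trial has a previous-trial reference")

    if folded:
        x = np.abs(usable["prev_distance"].to_numpy())
        y = usable["folded_error"].to_numpy()
    else:
        x = usable["prev_distance"].to_numpy()
        y = usable["error"].to_numpy()

    centers = window_centers(folded, step)
    member = window_membership(x, centers, folded, window_size)
    n = member.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, member @ y / np.maximum(n, 1), np.nan)

    if resample_unit == "subject" and "subject" in usable.columns:
        codes, uniques = pd.factorize(usable["subject"].to_numpy())
        n_units = len(uniques)
    else:
        codes = np.arange(len(usable))
        n_units = len(usable)
    rng = plan.rng()
    boots = _resample_sums(y, member, codes, n_units, plan, rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN (empty) windows
        lo = np.nanpercentile(boots, 100 * plan.alpha / 2, axis=0)
        hi = np.nanpercentile(boots, 100 * (1 - plan.alpha / 2), axis=0)
    lo = np.where(n > 0, lo, np.nan)
    hi = np.where(n > 0, hi, np.nan)

    return SerialBiasCurve(
        centers=centers, mean_error=mean, ci_low=lo, ci_high=hi,
        n_trials=n.astype(int), window_size=window_size, step=step,
        folded=folded, ci_level=1 - plan.alpha,
        resample_unit=resample_unit if "subject" in usable.columns else "trial",
    )


@dataclass
class MeanFoldedError:
    """Scalar serial-dependence strength: mean folded error with its CI."""

    estimate: float
    ci_low: float
    ci_high: float
    n: int
    max_distance: float
    ci_level: float

    @property
    def estimate_deg(self) -> float:
        return float(np.degrees(self.estimate))

    def to_dict(self) -> dict:
        return {
            "estimate_deg": self.estimate_deg,
            "ci_low_deg": float(np.degrees(self.ci_low)),
            "ci_high_deg": float(np.degrees(self.ci_high)),
            "n": self.n,
            "max_distance_deg": float(np.degrees(self.max_distance)),
            "ci_level": self.ci_level,
        }


def mean_folded_error(derived: pd.DataFrame, max_distance: float = np.pi / 2,
                      plan: ResamplingPlan = None,
                      resample_unit: str = "subject") -> MeanFoldedError:
    """Mean folded error over trials with |theta_d| <= max_distance.

    Positive values indicate attraction to the previous trial, negative
    repulsion.  The CI is a percentile bootstrap over subjects (or trials
    when no subject labels exist or ``resample_unit="trial"``).  Raises
    :class:`NoUsableTrialsError` when no trial qualifies, which is
    distinct from a genuine zero mean.
    """
    plan = plan or ResamplingPlan()
    if "has_reference" not in derived.columns:
        raise ValueError("run derive_trials first")
    sel = derived.loc[
        derived["has_reference"] & (np.abs(derived["prev_distance"]) <= max_distance)
    ]
    if len(sel) < 2:
        raise NoUsableTrialsError(
            f"need >= 2 usable trials within {np.degrees(max_distance):.0f} deg, got {len(sel)}"
        )
    y = sel["folded_error"].to_numpy()
    member = np.ones((1, y.size), dtype=bool)
    if resample_unit == "subject" and "subject" in sel.columns:
        codes, uniques = pd.factorize(sel["subject"].to_numpy())
        n_units = len(uniques)
    else:
        codes = np.arange(y.size)
        n_units = y.size
    boots = _resample_sums(y, member, codes, n_units, plan, plan.rng())[:, 0]
    lo, hi = np.percentile(boots, [100 * plan.alpha / 2, 100 * (1 - plan.alpha / 2)])
    return MeanFoldedError(
        estimate=float(y.mean()), ci_low=float(lo), ci_high=float(hi),
        n=int(y.size), max_distance=max_distance, ci_level=1 - plan.alpha,
    )


class SerialBiasModel:
    """Serial-dependence analysis of a delayed-estimation trial table.

    Statsmodels-style: build the model from data, then :meth:`fit` to get
    a :class:`SerialBiasResults` carrying the bias curve, the scalar
    mean-folded-error statistic with bootstrap uncertainty, and group
    inference over subjects.

    Parameters
    ----------
    data : DataFrame
        Trial table with columns ``experiment, subject, session,
        trial_index, target, report`` (radians; see
        :func:`serialdep.io.read_trials` for degree-based files).
    reference : {"target", "report"}
        Previous-trial reference for theta_d.
    folded : bool
        Whether the fitted curve is the folded one (default) or the raw
        signed curve.
    guess_threshold : float
        Guess classification threshold on |error| (radians); guess trials
        are excluded from the bias statistics.
    max_distance : float
        |theta_d| cut for the scalar statistic (default pi/2).
    """

    def __init__(self, data: pd.DataFrame, reference: str = "target",
                 folded: bool = True, guess_threshold: float = GUESS_THRESHOLD,
                 drop_guesses: bool = True, max_distance: float = np.pi / 2,
                 window_size: float = WINDOW_SIZE, step: float = WINDOW_STEP,
                 resample_unit: str = "subject"):
        self.reference = reference
        self.folded = folded
        self.guess_threshold = guess_threshold
        self.max_distance = max_distance
        self.window_size = window_size
        self.step = step
        self.resample_unit = resample_unit
        self.derived = derive_trials(data, reference=reference)
        if drop_guesses:
            self.kept, self.excluded = exclude_guesses(self.derived, guess_threshold)
        else:
            self.kept, self.excluded = self.derived, self.derived.iloc[0:0]

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "SerialBiasModel":
        return cls(data, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "SerialBiasModel":
        from .io import read_trials

        return cls(read_trials(path), **kwargs)

    @classmethod
    def from_simulation(cls, config, dog=None, **kwargs) -> "SerialBiasModel":
        from .simulate import simulate_experiment

        return cls(simulate_experiment(config, dog), **kwargs)

    def subject_means(self) -> pd.DataFrame:
        """Per-subject mean folded error within ``max_distance``."""
        sel = self.kept.loc[
            self.kept["has_reference"]
            & (np.abs(self.kept["prev_distance"]) <= self.max_distance)
        ]
        out = (
            sel.groupby(["experiment", "subject"], sort=False)["folded_error"]
            .agg(["mean", "size"])
            .reset_index()
            .rename(columns={"mean": "mean_folded_error", "size": "n_trials"})
        )
        return out

    def fit(self, plan: ResamplingPlan = None) -> "SerialBiasResults":
        plan = plan or ResamplingPlan()
        curve = serial_bias_curve(
            self.kept, folded=self.folded, window_size=self.window_size,
            step=self.step, plan=plan, resample_unit=self.resample_unit,
        )
        mfe = mean_folded_error(
            self.kept, max_distance=self.max_distance, plan=plan,
            resample_unit=self.resample_unit,
        )
        subj = self.subject_means()
        p_boot = t_stat = df = p_t = None
        if len(subj) >= 2:
            vals = subj["mean_folded_error"].to_numpy()
            p_boot = bootstrap_t_test(vals, plan)
            if np.var(vals) > 0:
                t_stat, df, p_t = one_sample_t(vals)
        return SerialBiasResults(
            model=self, plan=plan, curve=curve, mean_folded=mfe,
            subject_means_=subj, pvalue_bootstrap=p_boot,
            tvalue=t_stat, df=df, pvalue_t=p_t,
        )


@dataclass
class SerialBiasResults:
    """Fitted serial-dependence statistics for one trial table."""

    model: SerialBiasModel
    plan: ResamplingPlan
    curve: SerialBiasCurve
    mean_folded: MeanFoldedError
    subject_means_: pd.DataFrame
    pvalue_bootstrap: Optional[float]
    tvalue: Optional[float]
    df: Optional[int]
    pvalue_t: Optional[float]

    @property
    def n_trials(self) -> int:
        return int(len(self.model.kept))

    @property
    def n_guesses(self) -> int:
        return int(len(self.model.excluded))

    @property
    def n_subjects(self) -> int:
        return int(len(self.subject_means_))

    def conf_int(self):
        return self.mean_folded.ci_low, self.mean_folded.ci_high

    def to_dict(self) -> dict:
        out = {
            "reference": self.model.reference,
            "folded": self.model.folded,
            "n_trials": self.n_trials,
            "n_guesses_excluded": self.n_guesses,
            "n_subjects": self.n_subjects,
            "mean_folded_error": self.mean_folded.to_dict(),
            "pvalue_bootstrap_subjects": self.pvalue_bootstrap,
            "t": self.tvalue,
            "df": self.df,
            "pvalue_t": self.pvalue_t,
        }
        return out

    def summary(self) -> str:
        m = self.mean_folded
        lines = [
            "Serial dependence (folded-error) analysis",
            "=" * 45,
            f"reference: previous {self.model.reference:<10} folded: {self.model.folded}",
            f"subjects: {self.n_subjects:<6d} trials kept: {self.n_trials}"
            f"  guesses excluded: {self.n_guesses}",
            f"mean folded error (|th_d| <= {np.degrees(m.max_distance):.0f} deg):"
            f" {m.estimate_deg:+.3f} deg",
            f"  {100 * m.ci_level:.0f}% bootstrap CI"
            f" [{np.degrees(m.ci_low):+.3f}, {np.degrees(m.ci_high):+.3f}] deg"
            f"  (n = {m.n} trials)",
        ]
        if self.pvalue_bootstrap is not None:
            lines.append(
                f"group test over subjects: bootstrap p = {self.pvalue_bootstrap:.4g}"
            )
        if self.tvalue is not None:
            lines.append(
                f"one-sample t({self.df}) = {self.tvalue:.3f}, p = {self.pvalue_t:.4g}"
            )
        lines.append("positive = attraction to previous trial; negative = repulsion")
        return "\n".join(lines)

    def plot(self, ax=None, **kwargs):
        return self.curve.plot(ax=ax, **kwargs)
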