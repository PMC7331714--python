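"""Within-session dynamics of serial dependence.

Serial-dependence build-up is quantified two ways: by splitting each
session into three consecutive thirds and comparing the bias curves of
the extremes, and by regressing the trial-wise folded error on trial
number (one ordinary-least-squares slope per session, averaged into one
slope per subject).  Control analyses track the guess fraction and the
mean squared error in independent 20-trial windows to rule out
fatigue/learning confounds, and a simple regression associates those
trend slopes with the build-up slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .derive import GROUP_KEYS, GUESS_THRESHOLD, derive_trials, exclude_guesses
from .resampling import (
    AggregateResult,
    ResamplingPlan,
    bootstrap_ci,
    bootstrap_t_test,
    permutation_curve_test,
    two_level_aggregate,
)
from .serialbias import serial_bias_curve
from .windows import WINDOW_SIZE, WINDOW_STEP

__all__ = [
    "split_thirds",
    "buildup_slope",
    "subject_slopes",
    "sliding_buildup",
    "guess_fraction_trend",
    "mse_trend",
    "slope_association",
    "TrendSeries",
    "SlopeAssociation",
    "BuildUpModel",
    "BuildUpResults",
]

THIRD_NAMES = ("first", "middle", "last")


def split_thirds(session: pd.DataFrame):
    """Split one session's trials into three contiguous near-equal thirds.

    Sizes differ by at most one; the remainder goes to the earlier thirds
    (10 trials -> 4/3/3).  Requires >= 3 trials.
    """
    n = len(session)
    if n < 3:
        raise ValueError(f"need at least 3 trials to split into thirds, got {n}")
    df = session.sort_values("trial_index", kind="stable")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    edges = np.cumsum([0] + sizes)
    return tuple(df.iloc[edges[i]:edges[i + 1]] for i in range(3))


def _session_slope(session: pd.DataFrame) -> float:
    """OLS slope of folded error on trial index for one session's usable trials."""
    use = session.loc[session["has_reference"]]
    x = use["trial_index"].to_numpy(dtype=float)
    y = use["folded_error"].to_numpy(dtype=float)
    if x.size < 2:
        raise ValueError(
            f"session has {x.size} usable trial(s); >= 2 required for a slope"
        )
    if np.ptp(x) == 0:
        raise ValueError("degenerate session: trial_index is constant")
    return float(np.polyfit(x, y, 1)[0])


def buildup_slope(subject_trials: pd.DataFrame) -> float:
    """Per-subject build-up slope (radians of folded error per trial).

    One OLS slope of folded error against trial number per session,
    averaged across the subject's sessions.  Positive = build-up.  The
    input should already have guesses excluded.
    """
    slopes = [
        _session_slope(sess) for _, sess in subject_trials.groupby("session", sort=False)
    ]
    return float(np.mean(slopes))


def subject_slopes(derived: pd.DataFrame) -> pd.DataFrame:
    """Build-up slope for every (experiment, subject) in a derived table."""
    rows = []
    for (exp, subj), g in derived.groupby(["experiment", "subject"], sort=False):
        rows.append(
            {"experiment": exp, "subject": subj, "slope": buildup_slope(g)}
        )
    out = pd.DataFrame(rows)
    out["slope_deg_per_trial"] = np.degrees(out["slope"])
    return out


@dataclass
class TrendSeries:
    """Windowed within-session series (mean folded error, guess fraction, MSE)."""

    positions: np.ndarray          # window positions (trial index of window start)
    values: np.ndarray
    window: int
    overlapping: bool
    kind: str = "folded_error"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "value": self.values}
        ).assign(window=self.window, kind=self.kind)


def sliding_buildup(session: pd.DataFrame, window_size: int, step: int = 1) -> TrendSeries:
    """Mean folded error in overlapping windows along one session.

    Windows slide over trial order (usable, reference-bearing trials);
    series length is ``n - window_size + 1`` at step 1.
    """
    if window_size < 2:
        raise ValueError(f"window_size must be >= 2, got {window_size}")
    use = session.loc[session["has_reference"]].sort_values("trial_index", kind="stable")
    y = use["folded_error"].to_numpy()
    if window_size > y.size:
        raise ValueError(
            f"window_size {window_size} exceeds session length {y.size}"
        )
    csum = np.concatenate([[0.0], np.cumsum(y)])
    starts = np.arange(0, y.size - window_size + 1, step)
    vals = (csum[starts + window_size] - csum[starts]) / window_size
    pos = use["trial_index"].to_numpy()[starts]
    return TrendSeries(positions=pos, values=vals, window=window_size,
                       overlapping=True, kind="folded_error")


def _independent_windows(y: np.ndarray, window: int):
    n_win = y.size // window
    if n_win < 1:
        raise ValueError(
            f"session of {y.size} trials is shorter than one window of {window}"
        )
    trimmed = y[: n_win * window].reshape(n_win, window)
    return trimmed, np.arange(n_win)


def guess_fraction_trend(session: pd.DataFrame, window: int = 20):
    """Guess fraction in independent (non-overlapping) windows, plus its slope.

    Operates on ALL of a session's trials (guesses must still be flagged,
    not yet excluded).  The slope is the OLS slope of the fraction on the
    window position index.  A trailing partial window is dropped.
    """
    df = session.sort_values("trial_index", kind="stable")
    g = df["is_guess"].to_numpy(dtype=float)
    windows, pos = _independent_windows(g, window)
    frac = windows.mean(axis=1)
    slope = float(np.polyfit(pos, frac, 1)[0]) if pos.size >= 2 else 0.0
    series = TrendSeries(positions=pos, values=frac, window=window,
                         overlapping=False, kind="guess_fraction")
    return series, slope


def mse_trend(session: pd.DataFrame, window: int = 20):
    """Mean squared error in independent windows, plus its slope.

    Expects guess-excluded trials; the squared error tracks performance
    (fatigue/learning) through the session.
    """
    df = session.sort_values("trial_index", kind="stable")
    e2 = np.square(df["error"].to_numpy(dtype=float))
    windows, pos = _independent_windows(e2, window)
    vals = windows.mean(axis=1)
    slope = float(np.polyfit(pos, vals, 1)[0]) if pos.size >= 2 else 0.0
    series = TrendSeries(positions=pos, values=vals, window=window,
                         overlapping=False, kind="mse")
    return series, slope


@dataclass
class SlopeAssociation:
    """OLS association between two sets of per-subject slopes."""

    slope: float
    intercept: float
    r: float
    pvalue: float
    n: int

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "r": self.r, "pvalue": self.pvalue, "n": self.n}


def slope_association(x_slopes, y_slopes) -> SlopeAssociation:
    """Least-squares regression of y on x over paired per-subject values."""
    x = np.asarray(x_slopes, dtype=float)
    y = np.asarray(y_slopes, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x_slopes and y_slopes must be paired (same length)")
    if x.size < 3:
        raise ValueError(f"need n >= 3 pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor")
    res = sps.linregress(x, y)
    return SlopeAssociation(
        slope=float(res.slope), intercept=float(res.intercept),
        r=float(res.rvalue), pvalue=float(res.pvalue), n=int(x.size),
    )


def _per_subject_control_slopes(derived: pd.DataFrame, window: int,
                                control: str) -> pd.DataFrame:
    """Per-subject control-trend slope (guess fraction or MSE), sessions averaged."""
    rows = []
    for (exp, subj), g in derived.groupby(["experiment", "subject"], sort=False):
        slopes = []
        for _, sess in g.groupby("session", sort=False):
            if control == "guess":
                _, s = guess_fraction_trend(sess, window)
            else:
                kept, _ = exclude_guesses(sess)
                _, s = mse_trend(kept, window)
            slopes.append(s)
        rows.append({"experiment": exp, "subject": subj, "slope": float(np.mean(slopes))})
    return pd.DataFrame(rows)


class BuildUpModel:
    """Within-session build-up of serial dependence for a trial table.

    :meth:`fit` regresses folded error on trial number per session,
    averages to one slope per subject, and aggregates with bootstrap
    inference both experiment-weighted and subject-weighted.  The model
    also exposes the session-thirds curve comparison and the guess/MSE
    control trends.
    """

    def __init__(self, data: pd.DataFrame, reference: str = "target",
                 guess_threshold: float = GUESS_THRESHOLD,
                 window_size: float = WINDOW_SIZE, step: float = WINDOW_STEP):
        self.reference = reference
        self.guess_threshold = guess_threshold
        self.window_size = window_size
        self.step = step
        self.derived = derive_trials(data, reference=reference)
        self.kept, self.excluded = exclude_guesses(self.derived, guess_threshold)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "BuildUpModel":
        return cls(data, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "BuildUpModel":
        from .io import read_trials

        return cls(read_trials(path), **kwargs)

    def fit(self, plan: ResamplingPlan = None) -> "BuildUpResults":
        plan = plan or ResamplingPlan()
        slopes = subject_slopes(self.kept)
        exp_rows = []
        for exp, g in slopes.groupby("experiment", sort=False):
            vals = g["slope"].to_numpy()
            if vals.size >= 2:
                est, lo, hi = bootstrap_ci(vals, plan)
                p = bootstrap_t_test(vals, plan)
            else:
                est, lo, hi, p = float(vals.mean()), np.nan, np.nan, np.nan
            exp_rows.append({"experiment": exp, "mean_slope": est, "ci_low": lo,
                             "ci_high": hi, "pvalue": p, "n_subjects": vals.size})
        experiment_table = pd.DataFrame(exp_rows)
        pooled = two_level_aggregate(
            slopes["slope"], slopes["experiment"], "subject-weighted", plan
        )
        if slopes["experiment"].nunique() >= 2:
            exp_weighted = two_level_aggregate(
                slopes["slope"], slopes["experiment"], "experiment-weighted", plan
            )
        else:
            exp_weighted = pooled
        return BuildUpResults(
            model=self, plan=plan, subject_slopes_=slopes,
            experiment_table=experiment_table, pooled=pooled,
            experiment_weighted=exp_weighted,
        )

    def thirds_comparison(self, thirds: Sequence[str] = ("first", "last"),
                          plan: ResamplingPlan = None, folded: bool = True):
        """Bias curves for two session thirds plus a pointwise permutation test.

        ``thirds`` picks two of ``("first", "middle", "last")``; the
        default compares the session extremes.
        """
        plan = plan or ResamplingPlan()
        names = tuple(thirds)
        if len(names) != 2 or any(t not in THIRD_NAMES for t in names):
            raise ValueError(f"thirds must be two of {THIRD_NAMES}, got {names!r}")
        parts = {name: [] for name in names}
        for _, sess in self.kept.groupby(GROUP_KEYS, sort=False):
            chunks = dict(zip(THIRD_NAMES, split_thirds(sess)))
            for name in names:
                parts[name].append(chunks[name])
        tables = {name: pd.concat(parts[name], ignore_index=True) for name in names}
        curves = {
            name: serial_bias_curve(tables[name], folded=folded,
                                    window_size=self.window_size, step=self.step,
                                    plan=plan)
            for name in names
        }
        perm = permutation_curve_test(
            tables[names[0]], tables[names[1]], folded=folded,
            window_size=self.window_size, step=self.step, plan=plan,
        )
        return curves, perm

    def guess_trend_slopes(self, window: int = 20) -> pd.DataFrame:
        """Per-subject slope of the guess fraction across 20-trial windows.

        Uses ALL trials (guesses flagged, not excluded)."""
        return _per_subject_control_slopes(self.derived, window, "guess")

    def mse_trend_slopes(self, window: int = 20) -> pd.DataFrame:
        """Per-subject slope of windowed mean squared error (guesses excluded)."""
        return _per_subject_control_slopes(self.derived, window, "mse")

    def control_association(self, control: str = "guess", window: int = 20,
                            fitted: "BuildUpResults" = None,
                            plan: ResamplingPlan = None):
        """Regress build-up slopes on a control-trend slope, per experiment and pooled."""
        fitted = fitted or self.fit(plan)
        ctrl = (self.guess_trend_slopes(window) if control == "guess"
                else self.mse_trend_slopes(window))
        merged = fitted.subject_slopes_.merge(
            ctrl, on=["experiment", "subject"], suffixes=("_buildup", "_control")
        )
        out = {"pooled": slope_association(
            merged["slope_control"], merged["slope_buildup"]).to_dict()}
        per_exp = {}
        for exp, g in merged.groupby("experiment", sort=False):
            if len(g) >= 3 and np.ptp(g["slope_control"]) > 0:
                per_exp[exp] = slope_association(
                    g["slope_control"], g["slope_buildup"]).to_dict()
        out["per_experiment"] = per_exp
        return out


@dataclass
class BuildUpResults:
    """Fitted build-up slopes and their group-level inference."""

    model: BuildUpModel
    plan: ResamplingPlan
    subject_slopes_: pd.DataFrame
    experiment_table: pd.DataFrame
    pooled: AggregateResult
    experiment_weighted: AggregateResult

    @property
    def n_subjects(self) -> int:
        return int(len(self.subject_slopes_))

    def to_dict(self) -> dict:
        def deg(r: AggregateResult) -> dict:
            d = r.to_dict()
            for k in ("estimate", "ci_low", "ci_high"):
                d[k + "_deg_per_trial"] = float(np.degrees(d.pop(k)))
            return d

        return {
            "reference": self.model.reference,
            "n_subjects": self.n_subjects,
            "subject_weighted": deg(self.pooled),
            "experiment_weighted": deg(self.experiment_weighted),
        }

    def summary(self) -> str:
        p, e = self.pooled, self.experiment_weighted
        lines = [
            "Serial-dependence build-up (folded error vs. trial number)",
            "=" * 58,
            f"subjects: {self.n_subjects}   experiments:"
            f" {self.subject_slopes_['experiment'].nunique()}",
            "group slope, deg of folded error per trial:",
            f"  subject-weighted   : {np.degrees(p.estimate):+.5f}"
            f"  CI [{np.degrees(p.ci_low):+.5f}, {np.degrees(p.ci_high):+.5f}]"
            f"  p = {p.pvalue:.4g}",
            f"  experiment-weighted: {np.degrees(e.estimate):+.5f}"
            f"  CI [{np.degrees(e.ci_low):+.5f}, {np.degrees(e.ci_high):+.5f}]"
            f"  p = {e.pvalue:.4g}",
            "positive slope = serial dependence grows through the session",
        ]
        return "\n".join(lines)
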