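"""Resampling inference: bootstrap CIs and tests, two-level aggregation,
pointwise permutation tests for curve differences, and the classical
one-sample t-test.

Conventions
-----------
* Percentile bootstrap throughout (no bias correction).
* Monte-Carlo p-values are floored at 1/draws: a resampling test can
  never return exactly 0.
* Every routine is deterministic under a seeded ``ResamplingPlan``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .windows import WINDOW_SIZE, WINDOW_STEP, window_centers, window_membership

logger = logging.getLogger(__name__)

__all__ = [
    "ResamplingPlan",
    "bootstrap_ci",
    "bootstrap_t_test",
    "two_level_aggregate",
    "AggregateResult",
    "permutation_curve_test",
    "PermutationCurveResult",
    "one_sample_t",
]


@dataclass
class ResamplingPlan:
    """How resampling inference is run (draw counts, level, seed)."""

    n_boot: int = 10_000
    n_perm: int = 10_000
    alpha: float = 0.05
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_boot < 1 or self.n_perm < 1:
            raise ValueError("n_boot and n_perm must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _values_1d(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    return arr


def _boot_means(arr: np.ndarray, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    n = arr.size
    idx = rng.integers(0, n, size=(n_boot, n))
    return arr[idx].mean(axis=1)


def bootstrap_ci(values, plan: ResamplingPlan = None, statistic=None, rng=None):
    """Percentile bootstrap CI of a statistic (default: the mean).

    Returns ``(estimate, ci_low, ci_high)`` at level ``1 - plan.alpha``.
    Units are resampled with replacement; n >= 2 required.
    """
    plan = plan or ResamplingPlan()
    arr = _values_1d(values)
    if arr.size < 2:
        raise ValueError(f"need at least 2 values, got {arr.size}")
    gen = rng if isinstance(rng, np.random.Generator) else plan.rng()
    if statistic is None:
        boots = _boot_means(arr, plan.n_boot, gen)
        estimate = float(arr.mean())
    else:
        idx = gen.integers(0, arr.size, size=(plan.n_boot, arr.size))
        boots = np.apply_along_axis(statistic, 1, arr[idx])
        estimate = float(statistic(arr))
    lo, hi = np.percentile(boots, [100 * plan.alpha / 2, 100 * (1 - plan.alpha / 2)])
    return estimate, float(lo), float(hi)


def bootstrap_t_test(values, plan: ResamplingPlan = None, two_tailed: bool = True,
                     rng=None) -> float:
    """Bootstrap test of H0: mean = 0 on the resampled distribution of the mean.

    Two-tailed p is ``2 * min(P(mean* <= 0), P(mean* >= 0))``; one-tailed
    (alternative mean > 0) is ``P(mean* <= 0)``.  Floored at ``1/n_boot``
    and capped at 1.  All-zero input returns 1 by convention.
    """
    plan = plan or ResamplingPlan()
    arr = _values_1d(values)
    if arr.size < 2:
        raise ValueError(f"need at least 2 values, got {arr.size}")
    if np.all(arr == 0):
        logger.warning("bootstrap_t_test: all values are exactly 0; p = 1 by convention")
        return 1.0
    gen = rng if isinstance(rng, np.random.Generator) else plan.rng()
    boots = _boot_means(arr, plan.n_boot, gen)
    p_low = np.mean(boots <= 0)
    p_high = np.mean(boots >= 0)
    p = 2.0 * min(p_low, p_high) if two_tailed else p_low
    return float(min(1.0, max(p, 1.0 / plan.n_boot)))


@dataclass
class AggregateResult:
    """Group-level estimate with bootstrap CI and p-value."""

    estimate: float
    ci_low: float
    ci_high: float
    pvalue: float
    mode: str
    n_units: int

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "pvalue": self.pvalue,
            "mode": self.mode, "n_units": self.n_units,
        }


def two_level_aggregate(subject_values, experiment_labels, mode: str = "experiment-weighted",
                        plan: ResamplingPlan = None) -> AggregateResult:
    """Aggregate per-subject values across experiments.

    ``"experiment-weighted"`` first averages subjects within experiment and
    then bootstraps over the experiment means (each study counts equally,
    regardless of its subject count); ``"subject-weighted"`` pools all
    subjects (each subject counts equally, regardless of study).  With a
    single experiment the two modes coincide and subjects are resampled.
    """
    if mode not in ("experiment-weighted", "subject-weighted"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    plan = plan or ResamplingPlan()
    arr = _values_1d(subject_values)
    labels = np.asarray(experiment_labels)
    if labels.shape[0] != arr.shape[0]:
        raise ValueError("subject_values and experiment_labels must align")
    counts = pd.Series(labels).value_counts()
    if (counts == 0).any():
        raise ValueError("every experiment must contain at least one subject")
    if mode == "experiment-weighted" and counts.size > 1:
        units = pd.Series(arr).groupby(labels).mean().to_numpy()
    else:
        units = arr
    gen = plan.rng()
    est, lo, hi = bootstrap_ci(units, plan, rng=gen)
    p = bootstrap_t_test(units, plan, rng=gen)
    return AggregateResult(est, lo, hi, p, mode, int(units.size))


@dataclass
class PermutationCurveResult:
    """Pointwise permutation test of the difference between two bias curves."""

    centers: np.ndarray
    observed_diff: np.ndarray
    pvalues: np.ndarray
    n_a: np.ndarray
    n_b: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "center": self.centers,
                "center_deg": np.degrees(self.centers),
                "diff": self.observed_diff,
                "pvalue": self.pvalues,
                "n_a": self.n_a,
                "n_b": self.n_b,
            }
        )


def _curve_xy(derived: pd.DataFrame, folded: bool):
    usable = derived.loc[derived["has_reference"]]
    if folded:
        return np.abs(usable["prev_distance"].to_numpy()), usable["folded_error"].to_numpy(), usable
    return usable["prev_distance"].to_numpy(), usable["error"].to_numpy(), usable


def permutation_curve_test(trials_a: pd.DataFrame, trials_b: pd.DataFrame,
                           folded: bool = True, window_size: float = WINDOW_SIZE,
                           step: float = WINDOW_STEP, plan: ResamplingPlan = None,
                           within_subject: bool = True) -> PermutationCurveResult:
    """Pointwise permutation test for a difference between two bias curves.

    The null is built by shuffling the group label over trials (within
    subject when both tables carry subject labels and ``within_subject``),
    recomputing each window's mean difference.  P-values are two-tailed,
    ``(1 + #{|d*| >= |d|}) / (n_perm + 1)``, with NO multiplicity
    correction across windows (flagged in ``metadata``).  Windows empty in
    either group get NaN.
    """
    plan = plan or ResamplingPlan()
    for name, t in (("trials_a", trials_a), ("trials_b", trials_b)):
        if len(t) == 0:
            raise ValueError(f"{name} is empty")
        if "has_reference" not in t.columns:
            raise ValueError(f"{name} lacks derived columns: run derive_trials first")

    xa, ya, ua = _curve_xy(trials_a, folded)
    xb, yb, ub = _curve_xy(trials_b, folded)
    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    in_a = np.concatenate([np.ones(xa.size, bool), np.zeros(xb.size, bool)])

    centers = window_centers(folded, step)
    member = window_membership(x, centers, folded, window_size).astype(float)  # (W, N)

    def window_diff(z: np.ndarray):
        cnt_a = member @ z
        cnt_b = member.sum(axis=1) - cnt_a
        num_a = member @ (y * z)
        num_b = member @ y - num_a
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cnt_a > 0, num_a / cnt_a, np.nan) - np.where(
                cnt_b > 0, num_b / cnt_b, np.nan
            ), cnt_a, cnt_b

    z_obs = in_a.astype(float)
    observed, n_a, n_b = window_diff(z_obs)

    gen = plan.rng()
    use_subjects = (
        within_subject
        and "subject" in ua.columns
        and "subject" in ub.columns
    )
    if use_subjects:
        subj = np.concatenate([ua["subject"].to_numpy(), ub["subject"].to_numpy()])
        codes, _ = pd.factorize(subj)
        blocks = [np.flatnonzero(codes == s) for s in range(codes.max() + 1)]

    exceed = np.zeros(centers.size)
    valid = np.isfinite(observed)
    for _ in range(plan.n_perm):
        if use_subjects:
            z = np.empty(x.size)
            for blk in blocks:
                z[blk] = gen.permutation(z_obs[blk])
        else:
            z = gen.permutation(z_obs)
        diff, _, _ = window_diff(z)
        with np.errstate(invalid="ignore"):
            exceed += np.where(
                np.isfinite(diff), np.abs(diff) >= np.abs(observed) - 1e-15, 0.0
            )
    pvalues = np.where(valid, (1.0 + exceed) / (plan.n_perm + 1.0), np.nan)

    return PermutationCurveResult(
        centers=centers,
        observed_diff=observed,
        pvalues=pvalues,
        n_a=n_a.astype(int),
        n_b=(n_b).astype(int),
        metadata={
            "n_perm": plan.n_perm,
            "within_subject": bool(use_subjects),
            "multiple_comparison_correction": "none (pointwise)",
        },
    )


def one_sample_t(values, two_tailed: bool = True):
    """Classical one-sample t-test of H0: mean = 0.

    Returns ``(t, df, p)``.  Requires n >= 2 and nonzero variance.
    """
    arr = _values_1d(values)
    if arr.size < 2:
        raise ValueError(f"need at least 2 values, got {arr.size}")
    if np.var(arr) == 0:
        raise ValueError("one_sample_t requires nonzero variance")
    res = sps.ttest_1samp(arr, 0.0, alternative="two-sided" if two_tailed else "greater")
    return float(res.statistic), int(arr.size - 1), float(res.pvalue)
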