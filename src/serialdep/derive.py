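"""Per-trial derived quantities: errors, previous-trial distances, folding.

The signed report error is theta_e = wrap(report - target); the distance to
the previous trial's reference is theta_d = wrap(prev_reference - target);
the folded error is theta_e * sign(theta_d).  Folding cancels any additive
report bias when theta_d is sign-symmetric, which isolates attraction
toward (positive mean) or repulsion from (negative mean) the previous
trial.  Trials with |error| > pi/2 are flagged as guesses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .circular import wrap_signed

__all__ = ["GROUP_KEYS", "derive_trials", "exclude_guesses"]

GROUP_KEYS = ["experiment", "subject", "session"]
REQUIRED = GROUP_KEYS + ["trial_index", "target", "report"]

#: Reports farther than this from the target are classified as guesses.
GUESS_THRESHOLD = np.pi / 2


def derive_trials(trials: pd.DataFrame, reference: str = "target",
                  drop_guess_references: bool = False) -> pd.DataFrame:
    """Augment a trial table with error, previous-trial distance and folded error.

    Parameters
    ----------
    trials : DataFrame
        Columns ``experiment, subject, session, trial_index, target,
        report`` (angles in radians).
    reference : {"target", "report"}
        Whether the previous trial's target or its report serves as the
        serial-dependence reference.
    drop_guess_references : bool
        If True, trials whose previous trial was itself a guess get no
        reference (default False: a guess trial's target/report still
        anchors the next trial; only the guess's own error is excluded).

    Returns
    -------
    DataFrame
        Copy sorted by session and trial order with added columns
        ``error``, ``prev_distance``, ``folded_error``, ``is_guess``,
        ``has_reference``.  The first trial of each session has
        ``has_reference=False`` and NaN ``prev_distance``/``folded_error``.
    """
    if reference not in ("target", "report"):
        raise ValueError(f"reference must be 'target' or 'report', got {reference!r}")
    missing = [c for c in REQUIRED if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing required columns: {missing}")

    df = trials.copy()
    dup = df.duplicated(subset=GROUP_KEYS + ["trial_index"])
    if dup.any():
        offending = df.loc[dup, GROUP_KEYS + ["trial_index"]].head(5)
        raise ValueError(
            "duplicate (experiment, subject, session, trial_index) keys:\n"
            f"{offending.to_string(index=False)}"
        )
    df = df.sort_values(GROUP_KEYS + ["trial_index"], kind="stable").reset_index(drop=True)

    df["error"] = wrap_signed(df["report"].to_numpy() - df["target"].to_numpy())
    df["is_guess"] = np.abs(df["error"]) > GUESS_THRESHOLD

    grouped = df.groupby(GROUP_KEYS, sort=False)
    prev_ref = grouped[reference].shift(1)
    if drop_guess_references:
        prev_guess = grouped["is_guess"].shift(1)
        prev_ref = prev_ref.where(prev_guess != True)  # noqa: E712 (NaN-safe)

    df["prev_distance"] = wrap_signed(prev_ref.to_numpy() - df["target"].to_numpy())
    df["has_reference"] = np.isfinite(df["prev_distance"])
    df["folded_error"] = df["error"] * np.sign(df["prev_distance"])
    return df


def exclude_guesses(trials: pd.DataFrame, threshold: float = GUESS_THRESHOLD):
    """Split a derived trial table into (kept, excluded) by |error| > threshold.

    The inequality is strict: an error of exactly the threshold is kept.
    ``threshold`` must lie in (0, pi].
    """
    if not (0.0 < threshold <= np.pi):
        raise ValueError(f"threshold must be in (0, pi], got {threshold}")
    if "error" not in trials.columns:
        raise ValueError("derived errors missing: run derive_trials first")
    mask = np.abs(trials["error"]) > threshold
    return trials.loc[~mask].copy(), trials.loc[mask].copy()
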