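"""Sliding-window machinery shared by the bias-curve and permutation code.

Folded curves live on the bounded domain |theta_d| in [0, pi]; their
windows are truncated at the domain edges (the folded distance is not
periodic).  Unfolded curves live on the circle; their windows wrap.
"""

from __future__ import annotations

import numpy as np

from .circular import TWO_PI, wrap_signed

#: Defaults for the sliding serial-bias windows.
WINDOW_SIZE = np.pi / 2
WINDOW_STEP = np.pi / 30

__all__ = ["WINDOW_SIZE", "WINDOW_STEP", "window_centers", "window_membership"]


def window_centers(folded: bool, step: float = WINDOW_STEP) -> np.ndarray:
    """Window centers at multiples of ``step`` spanning the domain."""
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    if folded:
        n = int(np.floor(np.pi / step + 1e-9)) + 1
        return step * np.arange(n)
    n = int(np.round(TWO_PI / step))
    return -np.pi + step * np.arange(n)


def window_membership(x: np.ndarray, centers: np.ndarray, folded: bool,
                      window_size: float = WINDOW_SIZE) -> np.ndarray:
    """Boolean membership matrix of shape (n_windows, n_trials)."""
    if window_size <= 0:
        raise ValueError(f"window_size must be > 0, got {window_size}")
    x = np.asarray(x, dtype=float)
    half = window_size / 2.0
    if folded:
        d = np.abs(x[None, :] - centers[:, None])
    else:
        d = np.abs(wrap_signed(x[None, :] - centers[:, None]))
    return d <= half + 1e-12
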