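"""Circular (angular) geometry helpers.

All analysis code works in radians with angles on the canonical domain
``[0, 2*pi)`` and signed angular quantities (errors, distances) on
``(-pi, pi]``.  Degrees appear only at file and CLI boundaries.
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi

__all__ = ["TWO_PI", "wrap_angle", "wrap_signed", "circ_dist"]


def _check_finite(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite; got non-finite values")
    return arr


def wrap_angle(theta):
    """Wrap angles to the canonical domain ``[0, 2*pi)``."""
    arr = np.asarray(theta, dtype=float)
    out = np.mod(arr, TWO_PI)
    # np.mod(-tiny, 2*pi) can round to exactly 2*pi; fold back to 0
    out = np.where(out >= TWO_PI, 0.0, out)
    return out if arr.ndim else float(out)


def wrap_signed(delta):
    """Wrap a signed angular quantity to ``(-pi, pi]``.

    NaN propagates (used for "no previous trial" markers).
    """
    arr = np.asarray(delta, dtype=float)
    out = -(np.mod(-arr + np.pi, TWO_PI) - np.pi)
    # guard the rounding case mod(...) == 2*pi, which would yield -pi
    out = np.where(out <= -np.pi, np.pi, out)
    return out if arr.ndim else float(out)


def circ_dist(x, y):
    """Signed circular distance ``wrap(x - y)`` in ``(-pi, pi]``.

    Antisymmetric away from the +/-pi boundary; ``circ_dist(x, x) == 0``.
    Non-finite inputs are rejected.
    """
    xa = _check_finite(x, "x")
    ya = _check_finite(y, "y")
    return wrap_signed(xa - ya)
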