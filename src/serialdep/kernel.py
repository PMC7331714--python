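"""Derivative-of-Gaussian (DoG) attraction kernel.

The kernel gives the per-timestep drift of a diffusing memory trace toward
the previous trial's trace, as a function of the signed circular distance
between them:

    DoG(delta) = a * w * c * delta * exp(-(delta * w)**2)

It is odd in ``delta`` (attraction is symmetric in direction), vanishes at
zero distance, peaks at ``delta = 1 / (w * sqrt(2))`` and, with the
conventional normalisation ``c = sqrt(2 e)``, the peak value equals the
amplitude parameter ``a`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

__all__ = ["SQRT_2E", "DoGParams", "dog_kernel"]

#: Normalisation constant making the kernel peak equal ``a``.
SQRT_2E = math.sqrt(2.0 * math.e)


@dataclass(frozen=True)
class DoGParams:
    """Parameters of the DoG drift kernel.

    Parameters
    ----------
    a : float
        Peak drift amplitude, in angle units per timestep.  ``a >= 0``;
        ``a = 0`` switches attraction off.
    w : float
        Inverse width of the kernel, in 1/angle units.  ``w > 0``.
    c : float
        Dimensionless normalisation; with the default ``sqrt(2e)`` the
        kernel maximum over distance equals ``a``.
    """

    a: float = 0.09
    w: float = 0.007
    c: float = field(default=SQRT_2E)

    def __post_init__(self) -> None:
        for name in ("a", "w", "c"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"DoGParams.{name} must be finite, got {v!r}")
        if self.a < 0:
            raise ValueError(f"DoGParams.a must be >= 0, got {self.a}")
        if self.w <= 0:
            raise ValueError(f"DoGParams.w must be > 0, got {self.w}")
        if self.c <= 0:
            raise ValueError(f"DoGParams.c must be > 0, got {self.c}")

    @property
    def peak_distance(self) -> float:
        """Distance at which the kernel attains its maximum: ``1/(w*sqrt(2))``."""
        return 1.0 / (self.w * math.sqrt(2.0))

    @property
    def peak_value(self) -> float:
        """Analytic kernel maximum, ``a * c * exp(-1/2) / sqrt(2)``.

        Equals ``a`` exactly when ``c == sqrt(2e)``.
        """
        return self.a * self.c * math.exp(-0.5) / math.sqrt(2.0)


def dog_kernel(delta, params: DoGParams = DoGParams()):
    """Evaluate the DoG drift kernel at signed distance(s) ``delta``.

    Parameters
    ----------
    delta : float or array_like
        Signed circular distance(s) between the current trace and the
        previous trial's reference, in the same angle units as ``params``.
    params : DoGParams
        Kernel parameters.

    Returns
    -------
    float or ndarray
        Drift increment(s), odd in ``delta``.
    """
    if not isinstance(params, DoGParams):
        raise TypeError(f"params must be DoGParams, got {type(params).__name__}")
    arr = np.asarray(delta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("delta must be finite")
    out = params.a * params.w * params.c * arr * np.exp(-((arr * params.w) ** 2))
    return out if arr.ndim else float(out)
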