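"""Convenience matplotlib plots (degrees on the axes)."""

from __future__ import annotations

import numpy as np


def plot_serial_bias_curve(curve, ax=None, color="C0", label=None):
    """Plot a serial-bias curve with its bootstrap band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.degrees(curve.centers)
    y = np.degrees(curve.mean_error)
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.plot(x, y, color=color, label=label)
    ax.fill_between(x, np.degrees(curve.ci_low), np.degrees(curve.ci_high),
                    color=color, alpha=0.25, linewidth=0)
    ax.set_xlabel(
        "|previous - current target| (deg)" if curve.folded
        else "previous - current target (deg)"
    )
    ax.set_ylabel("folded error (deg)" if curve.folded else "error (deg)")
    if label:
        ax.legend(frameon=False)
    return ax


def plot_trend(series, ax=None, color="C1", label=None):
    """Plot a within-session trend series (guess fraction, MSE, folded error)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(series.positions, series.values, color=color, label=label)
    ax.set_xlabel("trial index")
    ax.set_ylabel(series.kind.replace("_", " "))
    if label:
        ax.legend(frameon=False)
    return ax
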