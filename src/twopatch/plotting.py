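"""Plotting of dispersal-response curves.

Replicates the standard presentation: asymptotic total population size
against dispersal rate, a dashed horizontal line at the sum of the
carrying capacities (the no-dispersal baseline), a vertical guide at the
perfect-mixing rate 0.5 in discrete mode, and a marker at the maximum.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers can switch backends first

import matplotlib.pyplot as plt
import numpy as np

from .equilibrium import ResponseCurve
from .models import Mode

__all__ = ["plot_response_curve"]


def plot_response_curve(curve: ResponseCurve, ax=None, title: str | None = None):
    """Plot total equilibrium population size against dispersal rate."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    total = curve.N_A + curve.N_B
    baseline = total[0]  # K_A + K_B (the delta = 0 equilibrium)
    ax.plot(curve.grid, total, color="tab:blue", lw=1.8, label=r"$N_A+N_B$")
    ax.axhline(baseline, ls="--", color="grey", lw=1.0, label=r"$K_A+K_B$")
    if curve.mode is Mode.DISCRETE:
        ax.axvline(0.5, color="lightgrey", lw=1.0)
    imax = int(np.argmax(total))
    ax.plot(curve.grid[imax], total[imax], "x", color="tab:red", ms=9, mew=2)
    if curve.mode is Mode.CONTINUOUS and curve.grid[-1] > 100:
        ax.set_xscale("symlog", linthresh=1.0)
    ax.set_xlabel("dispersal rate")
    ax.set_ylabel("asymptotic total population size")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    return ax
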