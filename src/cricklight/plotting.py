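"""Figure rendering: actograms, daily profiles, circular phase plots.

Plots are presentation artifacts; every quantity they show is computed
by (and tested through) the analysis modules first.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .phase import mean_vector
from .report import DoubleActogram

__all__ = ["plot_actogram", "plot_daily_profile", "plot_phase_circle"]


def plot_actogram(acto: DoubleActogram, title: str = ""):
    """Render a double-plotted actogram with a light bar on top."""
    n_rows, width = acto.matrix.shape
    fig, (ax_bar, ax) = plt.subplots(
        2, 1, figsize=(8, 0.35 * n_rows + 1.2),
        gridspec_kw={"height_ratios": [1, 10 * max(n_rows, 1)]},
        sharex=True,
    )
    bar = np.where(acto.light_bar, 1.0, 0.0)[None, :]
    ax_bar.imshow(bar, aspect="auto", cmap="gray", vmin=0, vmax=1)
    ax_bar.set_yticks([])
    ax_bar.set_title(title)
    ax.imshow(acto.matrix, aspect="auto", cmap="Greys", vmin=0, vmax=1,
              interpolation="nearest")
    ax.set_xlabel("time (two consecutive days)")
    ax.set_ylabel("day")
    ax.set_yticks(range(n_rows))
    ax.set_yticklabels(acto.day_labels)
    hours = np.arange(0, 49, 12)
    ax.set_xticks(hours / 48 * width)
    ax.set_xticklabels(hours)
    fig.tight_layout()
    return fig


def plot_daily_profile(profile, title: str = ""):
    """Mean +- s.e. activity over the folded 24 h day."""
    fig, ax = plt.subplots(figsize=(7, 3.2))
    ax.plot(profile["hour"], profile["mean"], color="k", lw=1.2)
    ax.fill_between(
        profile["hour"],
        profile["mean"] - profile["sem"],
        profile["mean"] + profile["sem"],
        alpha=0.3,
        color="k",
        lw=0,
    )
    ax.axvspan(12, 24, color="0.85", zorder=0)  # scotophase shading
    ax.set_xlim(0, 24)
    ax.set_xticks(range(0, 25, 6))
    ax.set_xlabel("time of day (h)")
    ax.set_ylabel("activity index")
    ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_phase_circle(angles, title: str = "", grid_step: float = 0.25):
    """Circular phase plot: one point per individual plus the mean vector.

    Angles are on the 24 h clock (0 h at the top, clockwise); radial
    grid lines every ``grid_step`` of the unit radius.
    """
    a = np.asarray(angles, dtype=float)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.scatter(a, np.ones_like(a), s=25, alpha=0.8, zorder=3)
    mv = mean_vector(a) if a.size else None
    if mv is not None and mv.direction is not None:
        ax.annotate(
            "",
            xy=(mv.direction, mv.length),
            xytext=(0, 0),
            arrowprops=dict(arrowstyle="-|>", color="k", lw=2),
        )
    ax.set_rmax(1.05)
    ax.set_rticks(np.arange(grid_step, 1.0 + 1e-9, grid_step))
    ax.set_xticks(np.linspace(0, 2 * np.pi, 8, endpoint=False))
    ax.set_xticklabels([f"{h:d}" for h in range(0, 24, 3)])
    ax.set_title(title)
    fig.tight_layout()
    return fig
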