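"""Minimal figures: learning curves and topographic discriminancy maps.

Matplotlib is imported lazily; install the ``plot`` extra to use these.
No interchannel interpolation is attempted — maps are per-electrode dots
on the 10-20 grid.
"""

from __future__ import annotations

import pandas as pd

from .montage import channel_positions

__all__ = ["plot_learning_curve", "plot_topography"]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_learning_curve(curve: pd.DataFrame, ax=None, **line_kw):
    """Run-indexed metric values with one line per period."""
    ax = _axes(ax)
    for period, sub in curve.groupby("period"):
        ax.plot(sub["run"], sub["value"], marker="o", label=str(period),
                **line_kw)
    ax.set_xlabel("run")
    ax.set_ylabel(str(curve["metric"].iloc[0]) if "metric" in curve else
                  "value")
    ax.legend(title="period")
    return ax


def plot_topography(values: pd.Series, ax=None, cmap="viridis"):
    """Per-channel scalar map (e.g. Fisher-score discriminancy) as labelled
    dots at the electrode grid positions."""
    ax = _axes(ax)
    pos = channel_positions(list(values.index))
    sc = ax.scatter(pos[:, 0], pos[:, 1], c=values.values, s=600,
                    cmap=cmap, edgecolors="k")
    for (x, y), name in zip(pos, values.index):
        ax.annotate(name, (x, y), ha="center", va="center", fontsize=7)
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.figure.colorbar(sc, ax=ax, shrink=0.8)
    return ax
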