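"""Minimal plotting helpers (the accuracy plot lives on DecodingResults)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_topography"]


def plot_topography(values, sensor_positions, ax=None, cmap="RdBu_r",
                    mark=None):
    """Top-view scatter map of per-channel values.

    Sensors are projected to the xy-plane; ``mark`` is an optional boolean
    array flagging channels to outline (e.g. significant ones).
    """
    import matplotlib.pyplot as plt

    values = np.asarray(values, dtype=float)
    pos = np.asarray(sensor_positions)
    if ax is None:
        _, ax = plt.subplots()
    vmax = np.abs(values).max() or 1.0
    sc = ax.scatter(pos[:, 0], pos[:, 1], c=values, cmap=cmap,
                    vmin=-vmax, vmax=vmax, s=60)
    if mark is not None:
        m = np.asarray(mark, dtype=bool)
        ax.scatter(pos[m, 0], pos[m, 1], facecolors="none",
                   edgecolors="k", s=90, linewidths=1.2)
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    plt.colorbar(sc, ax=ax, shrink=0.8)
    return ax
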