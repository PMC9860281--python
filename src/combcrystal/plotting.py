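"""Matplotlib views of tessellations and annealing traces.

Cells are drawn in the usual crystallographic coloring: red for Z > 6,
blue for Z < 6, white for hexagons; non-interior cells are grey.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_tessellation", "plot_energy_trace"]


def plot_tessellation(tess, ax=None, moving_mask=None, show_centers=True):
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 7))
    colors = []
    for i in range(tess.n):
        if not tess.interior[i]:
            colors.append("0.85")
        elif tess.Z[i] > 6:
            colors.append("tab:red")
        elif tess.Z[i] < 6:
            colors.append("tab:blue")
        else:
            colors.append("white")
    ax.add_collection(PolyCollection(tess.polygons, facecolors=colors,
                                     edgecolors="0.4", linewidths=0.6))
    if show_centers:
        if moving_mask is None:
            moving_mask = np.zeros(tess.n, dtype=bool)
        ax.plot(*tess.points[~moving_mask].T, ".", color="0.2", ms=3)
        if moving_mask.any():
            ax.plot(*tess.points[moving_mask].T, ".", color="k", ms=5)
    lo, hi = tess.box
    ax.set_xlim(lo[0], hi[0])
    ax.set_ylim(lo[1], hi[1])
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    return ax


def plot_energy_trace(trace, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    stages = np.arange(len(trace))
    ax.plot(stages, trace.total_energy, "k.-")
    ax.set_xlabel("annealing stage")
    ax.set_ylabel("total potential energy")
    ax2 = ax.twinx()
    ax2.plot(stages, trace.temperature, "r--", alpha=0.6)
    ax2.set_ylabel("temperature", color="r")
    return ax
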