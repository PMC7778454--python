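"""Minimal surface-map plotting (3-D scatter of the cortical shell)."""

from __future__ import annotations

import numpy as np


def plot_surface_map(rmap, spots=(), ax=None, cmap="RdBu_r", title=None):
    """Scatter the cortical voxels coloured by map amplitude.

    ``spots`` may contain activation spots whose centres are marked.
    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        fig = plt.figure(figsize=(5, 5))
        ax = fig.add_subplot(111, projection="3d")
    v = np.asarray(rmap.values, float)
    if v.ndim != 1:
        raise ValueError("plot a single map, not a series (use .at_time)")
    p = rmap.positions
    lim = np.abs(v).max() or 1.0
    sc = ax.scatter(p[:, 0], p[:, 1], p[:, 2], c=v, cmap=cmap, vmin=-lim,
                    vmax=lim, s=8)
    for spot in spots:
        c = spot.center
        ax.scatter([c[0]], [c[1]], [c[2]], marker="*", s=120, color="green")
    ax.figure.colorbar(sc, ax=ax, shrink=0.7)
    if title:
        ax.set_title(title)
    ax.set_box_aspect((1, 1, 1))
    return ax
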