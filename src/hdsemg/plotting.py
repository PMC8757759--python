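"""Matplotlib views of activation maps and CoG trajectories."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .cog import CoGTrajectory
from .grid import ActivationMap, GridGeometry

__all__ = ["plot_activation_map", "plot_cog_trajectory"]


def plot_activation_map(amap: ActivationMap, ax=None, cmap: str = "turbo", colorbar: bool = True):
    """Colour map of one activation map (missing positions blanked)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3, 6))
    values = np.ma.masked_array(amap.values, mask=~amap.valid_mask)
    im = ax.imshow(
        values,
        origin="upper",
        cmap=cmap,
        aspect="equal",
        extent=(0.5, amap.n_cols + 0.5, amap.n_rows + 0.5, 0.5),
    )
    ax.set_xlabel("column (y)")
    ax.set_ylabel("row (x, fiber axis)")
    ax.set_title(f"RMS map, {amap.window[0]:.2f}-{amap.window[1]:.2f} s")
    if colorbar:
        ax.figure.colorbar(im, ax=ax, label="RMS (mV)")
    return ax


def plot_cog_trajectory(
    traj: CoGTrajectory, geometry: Optional[GridGeometry] = None, ax=None, **line_kwargs
):
    """CoG path on the grid, start marked with a circle, end with a square."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3, 6))
    line_kwargs.setdefault("marker", ".")
    ax.plot(traj.ys, traj.xs, **line_kwargs)
    ax.plot(traj.ys[0], traj.xs[0], "o", color="tab:green", label="start")
    ax.plot(traj.ys[-1], traj.xs[-1], "s", color="tab:red", label="end")
    if geometry is not None:
        ax.set_xlim(0.5, geometry.n_cols + 0.5)
        ax.set_ylim(geometry.n_rows + 0.5, 0.5)
    else:
        ax.invert_yaxis()
    ax.set_xlabel("column (y)")
    ax.set_ylabel("row (x, fiber axis)")
    ax.set_title("CoG trajectory")
    ax.legend(loc="best", fontsize="small")
    return ax
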