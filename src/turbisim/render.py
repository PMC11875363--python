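"""Deterministic rendering of simulation states."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import LineCollection

from .growth import SimState

__all__ = ["snapshot_render"]


def snapshot_render(state: SimState, params, path=None, color="k"):
    """Render the thickened tree inside its boundary circle.

    The root is marked in red; line width approximates the branch
    thickness ``w`` at the figure scale.  Output is deterministic for a
    given state.
    """
    tree = state.tree
    b = state.boundary.b
    fig, ax = plt.subplots(figsize=(6, 6))
    pos = tree.positions
    if tree.n > 1:
        segs = np.stack([pos[1:], pos[tree.parents[1:]]], axis=1)
        lw = max(0.5, 72 * 6 / (2.2 * 2 * b) * params.w / 4)
        ax.add_collection(LineCollection(segs, colors=color, linewidths=lw,
                                         capstyle="round"))
    th = np.linspace(0, 2 * np.pi, 256)
    ax.plot(b * np.cos(th), b * np.sin(th), "k-", lw=2)
    ax.plot([pos[0, 0]], [pos[0, 1]], "r*", markersize=10)
    ax.set_xlim(-1.1 * b, 1.1 * b)
    ax.set_ylim(-1.1 * b, 1.1 * b)
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.set_title(f"t* = {state.t_star:.3f}")
    if path is not None:
        fig.savefig(path, dpi=110)
        plt.close(fig)
        return path
    return fig
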