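"""Minimal raster plots: mode maps and efficiency-plane trajectories.

Diagnostic quality only; CSV exports are the primary output surface.
Requires matplotlib (optional ``plot`` extra).
"""

from __future__ import annotations

import numpy as np

from .ib import Frontier, NamingSystem, mode_map
from .trajectory import Trajectory
from .universe import Universe

__all__ = ["plot_mode_map", "plot_trajectory"]


def plot_mode_map(naming: NamingSystem, universe: Universe, ax=None):
    """Raster of the per-chip modal term on the (lightness row, hue column) grid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    rows = sorted({c.grid_row for c in universe.chips})
    cols = sorted({c.grid_col for c in universe.chips})
    img = np.full((len(rows), len(cols)), np.nan)
    modes = mode_map(naming)
    for i, chip in enumerate(universe.chips):
        img[rows.index(chip.grid_row), cols.index(chip.grid_col)] = modes[i]
    ax.imshow(img, cmap="tab20", interpolation="nearest")
    ax.set_xlabel("hue column")
    ax.set_ylabel("lightness row")
    ax.set_yticks(range(len(rows)), rows)
    return ax


def plot_trajectory(trajectory: Trajectory, frontier: Frontier | None = None, ax=None):
    """Acquisition path in the (complexity, information-loss) plane."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if frontier is not None:
        ax.plot(frontier.complexity, frontier.information_loss,
                color="C0", label="IB frontier")
    cx = [p.score.complexity for p in trajectory.points]
    loss = [p.score.information_loss for p in trajectory.points]
    ax.plot(cx, loss, marker=".", color="C1", label="learner")
    ax.set_xlabel("complexity I(M;W) [bits]")
    ax.set_ylabel("information loss [bits]")
    ax.legend()
    return ax
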