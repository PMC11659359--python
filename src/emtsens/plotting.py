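"""Convenience figures: bifurcation diagrams, PRCC bars, significance grids.

Plotting is a thin layer over the analysis containers; nothing here is used
by the analysis itself.  matplotlib is imported lazily.
"""

from __future__ import annotations

import numpy as np

from .bifurcation import BifurcationDiagram


def plot_bifurcation(diagram: BifurcationDiagram, output: str = "E", ax=None):
    """Equilibrium branches vs the control input; stable solid, saddle dashed."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    pts = diagram.points
    for bid, branch in pts.groupby("branch_id"):
        style = "-" if (branch["stability"] == "stable").all() else "--"
        ax.plot(branch["control"], branch[output], style, color="C0" if style == "-" else "C3")
    for f in diagram.folds:
        ax.plot(f.control_value, getattr(f, output), "ko", ms=5)
    ax.set_xlabel(diagram.control)
    ax.set_ylabel(output)
    return ax


def plot_prcc_bars(rho: dict, threshold: float = 0.5, ax=None, title: str = ""):
    """Bar chart of PRCC values with the +/- significance cutoff marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    names = list(rho)
    vals = [rho[n] for n in names]
    ax.bar(np.arange(len(names)), vals, color=["C1" if abs(v) >= threshold else "C7" for v in vals])
    ax.axhline(threshold, ls="--", c="k", lw=0.8)
    ax.axhline(-threshold, ls="--", c="k", lw=0.8)
    ax.set_xticks(np.arange(len(names)), names, rotation=60)
    ax.set_ylim(-1.05, 1.05)
    ax.set_ylabel(r"PRCC $\rho$")
    if title:
        ax.set_title(title)
    return ax


def plot_significance_grid(grid: dict, parameters: list, ax=None):
    """Frame x parameter panel per treatment cell: E/e and S/s significance.

    ``grid`` maps frame -> (group label, output) -> significant-name set,
    as produced by the comparison report.
    """
    import matplotlib.pyplot as plt

    frames = list(grid)
    cells = sorted({key for cells in grid.values() for key in cells})
    fig, axes = plt.subplots(1, len(cells), figsize=(2.2 * len(cells), 0.35 * len(frames) + 1),
                             squeeze=False)
    for ci, cell in enumerate(cells):
        a = axes[0][ci]
        img = np.zeros((len(frames), len(parameters)))
        for fi, f in enumerate(frames):
            sig = grid[f].get(cell, set())
            for pi, p in enumerate(parameters):
                img[fi, pi] = 1.0 if p in sig else 0.0
        a.imshow(img, cmap="cividis", vmin=0, vmax=1, aspect="auto")
        a.set_xticks(range(len(parameters)), parameters, rotation=90, fontsize=6)
        a.set_yticks(range(len(frames)), frames, fontsize=6)
        a.set_title("|".join(map(str, cell)), fontsize=7)
    fig.tight_layout()
    return fig
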