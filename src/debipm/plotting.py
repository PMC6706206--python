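"""Convenience contour plots of grid-sweep and elasticity results.

Plots are a visual aid only; the exported long-format tables are the
quantitative output.  matplotlib is imported lazily so headless use of the
library never touches a plotting backend.
"""

from __future__ import annotations

import numpy as np

from .perturbation import PERTURBABLE_PARAMETERS, DominantParameterMap
from .projection import ResultGrid

__all__ = ["plot_grid_metric", "plot_dominant_map"]


def _axes(ax):
    if ax is not None:
        return ax.figure, ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt.subplots()


def plot_grid_metric(grid: ResultGrid, metric: str = "log_lambda_s", ax=None):
    """Filled contours of a grid metric over (q, p), with f = const guides."""
    fig, ax = _axes(ax)
    Z = getattr(grid, metric)
    Q, P = np.meshgrid(grid.q_values, grid.p_values)
    cs = ax.contourf(Q, P, Z, levels=12, cmap="viridis")
    fig.colorbar(cs, ax=ax, label=metric)
    for f in (0.25, 0.5, 0.75):
        # constant f = q/(p+q) is the ray p = q (1 - f) / f
        q_line = np.linspace(0, 1, 50)
        ax.plot(q_line, q_line * (1 - f) / f, "w--", lw=0.8)
    ax.set_xlim(grid.q_values.min(), grid.q_values.max())
    ax.set_ylim(grid.p_values.min(), grid.p_values.max())
    ax.set_xlabel("q (bad → good switch probability)")
    ax.set_ylabel("p (good → bad switch probability)")
    return ax


def plot_dominant_map(dmap: DominantParameterMap, ax=None):
    """Categorical map of the most-influential trait over (q, p)."""
    fig, ax = _axes(ax)
    codes = {name: k for k, name in enumerate(PERTURBABLE_PARAMETERS)}
    Z = np.vectorize(codes.get)(dmap.dominant)
    mesh = ax.pcolormesh(
        dmap.q_values, dmap.p_values, Z, cmap="Greys", vmin=0, vmax=len(codes) - 1
    )
    cbar = fig.colorbar(mesh, ax=ax, ticks=list(codes.values()))
    cbar.ax.set_yticklabels(list(codes))
    ax.set_xlabel("q (bad → good switch probability)")
    ax.set_ylabel("p (good → bad switch probability)")
    return ax
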