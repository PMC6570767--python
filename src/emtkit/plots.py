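"""Figures: SOM node-composition heatmap and bifurcation diagrams.

Matplotlib Agg-safe; each function returns the Figure so callers can save or
embed it.  Stable branches are drawn solid, unstable branches dashed, and
fixed points are colored by their position on the EMT spectrum.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .model import BifurcationDiagram
from .som import SOMClassifier


def plot_som_nodes(som: SOMClassifier, ax=None):
    """E/M composition of each grid node (red = E-dominant, blue = M-dominant,
    black = empty), mirroring the standard map-composition view."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    lab = som.node_labeling_
    n = lab.labels.size
    for node in range(n):
        x, y = som.grid_positions_[node]
        total = lab.e_counts[node] + lab.m_counts[node]
        if lab.n_genes[node] == 0:
            color = "black"
        elif total == 0:
            color = "lightgray"
        else:
            frac_m = lab.m_counts[node] / total
            color = (1 - frac_m, 0.1, frac_m)
        ax.scatter([x], [y], s=300, marker="h", color=color)
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.set_title("SOM node composition (red E / blue M / black empty)")
    return ax.figure


def plot_bifurcation(diagram: BifurcationDiagram, node: int | None = None, ax=None):
    """EMT score (or one node's value) of every fixed point along the signal
    axis; solid markers for stable states, open dashed for unstable."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    scores = [
        fp.emt_score if node is None else fp.x[node]
        for fps in diagram.fixed_points
        for fp in fps
    ]
    lo, hi = (min(scores), max(scores)) if scores else (0, 1)
    for v, fps in zip(diagram.grid, diagram.fixed_points):
        for fp in fps:
            y = fp.emt_score if node is None else fp.x[node]
            c = plt.cm.coolwarm((fp.emt_score + 1) / 4.0)
            if fp.stable:
                ax.plot([v], [y], "o", color=c, markersize=5)
            else:
                ax.plot([v], [y], "o", mfc="none", mec=c, markersize=5, ls="--")
    ax.set_xlabel("exogenous TGF-β" if diagram.axis == "s_t" else "exogenous ZEB1")
    ax.set_ylabel("EMT score" if node is None else f"node {node}")
    ax.set_ylim(lo - 0.2, hi + 0.2)
    return ax.figure
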