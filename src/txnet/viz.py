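"""Static plot exports: log-log degree distributions and layout scatters."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .degreedist import PowerLawFit
from .layout import LayoutState

__all__ = ["plot_degree_distribution", "plot_layout"]

_CATEGORY_COLORS = {
    "high_hub": "green",
    "hub": "red",
    "vip": "blue",
    "none": "0.7",
    "leaf": "0.7",
}


def plot_degree_distribution(hist, path, fit: PowerLawFit | None = None) -> None:
    """Normalized degree distribution on log-log axes with the fitted line."""
    freq_col = "frequency" if "frequency" in hist.columns else "count"
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.loglog(hist["k"], hist[freq_col], "o", ms=4, label="observed")
    if fit is not None:
        from scipy.special import zeta

        ks = np.arange(fit.x_min, int(hist["k"].max()) + 1)
        pk = ks ** (-fit.gamma) / zeta(fit.gamma, fit.x_min)
        if freq_col == "count":
            pk = pk * hist[freq_col].sum()
        ax.loglog(ks, pk, "-", label=rf"$k^{{-{fit.gamma:.2f}}}$")
    ax.set_xlabel("node degree $k$")
    ax.set_ylabel("P(k)" if freq_col == "frequency" else "count")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_layout(
    net: nx.Graph,
    state: LayoutState,
    path,
    categories: dict | None = None,
) -> None:
    """2D scatter of the layout (3D layouts are projected onto x/y).

    Without categories, nodes are colored red-to-blue by decreasing degree;
    with categories, by role (high-hub green, hub red, VIP blue).
    """
    pos = state.positions
    fig, ax = plt.subplots(figsize=(6, 6))
    idx = {n: i for i, n in enumerate(state.nodes)}
    for u, v in net.edges():
        a, b = pos[idx[u]], pos[idx[v]]
        ax.plot([a[0], b[0]], [a[1], b[1]], "-", color="0.85", lw=0.5, zorder=1)
    if categories:
        colors = [_CATEGORY_COLORS.get(categories.get(n, "none"), "0.7")
                  for n in state.nodes]
        ax.scatter(pos[:, 0], pos[:, 1], c=colors, s=18, zorder=2)
    else:
        degs = np.array([net.degree(n) for n in state.nodes], dtype=float)
        ax.scatter(pos[:, 0], pos[:, 1], c=degs, cmap="coolwarm", s=18, zorder=2)
    ax.set_aspect("equal")
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
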