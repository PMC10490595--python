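"""Minimal topographic plotting on the 24-channel montage."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .montage import Montage, default_montage


def plot_topomap(values: np.ndarray, montage: Montage | None = None,
                 highlight: tuple[str, ...] = (), title: str = "",
                 path: str | Path | None = None):
    """Scatter ``values`` (one per channel) on the head circle.

    ``highlight`` channels (e.g. a significant cluster) are ring-marked.
    Returns the matplotlib figure; saves to ``path`` when given.
    """
    montage = montage or default_montage()
    if len(values) != len(montage.labels):
        raise ValueError("one value per montage channel required")
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.add_patch(plt.Circle((0, 0), 1.0, fill=False, lw=1.5))
    ax.plot([-0.08, 0, 0.08], [0.995, 1.08, 0.995], color="k", lw=1.5)  # nose
    x, y = montage.positions.T
    sc = ax.scatter(x, y, c=values, s=320, cmap="RdBu_r", zorder=3,
                    edgecolors="k", linewidths=0.5)
    for lab in highlight:
        i = montage.index(lab)
        ax.scatter(x[i], y[i], s=520, facecolors="none", edgecolors="lime",
                   linewidths=2.5, zorder=4)
    for i, lab in enumerate(montage.labels):
        ax.annotate(lab, (x[i], y[i]), ha="center", va="center", fontsize=6,
                    zorder=5)
    fig.colorbar(sc, ax=ax, shrink=0.8)
    ax.set_title(title)
    ax.set_xlim(-1.25, 1.25)
    ax.set_ylim(-1.25, 1.25)
    ax.set_aspect("equal")
    ax.axis("off")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
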