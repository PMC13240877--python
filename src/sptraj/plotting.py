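"""Static figures: pseudotime maps and streamline overlays."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_pseudotime_map", "plot_streamline_field"]


def plot_pseudotime_map(coords, tau, path, s: float = 12):
    """Cells in space colored by pseudotime (the pseudo-spatiotemporal map)."""
    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(coords[:, 0], coords[:, 1], c=tau, cmap="viridis", s=s)
    fig.colorbar(sc, ax=ax, label="pseudotime")
    ax.set_aspect("equal")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_streamline_field(grid, coords, tau, path, lines=None, s: float = 10):
    """Pseudotime scatter with the integrated velocity streamlines overlaid."""
    from .velocity import streamlines as _stream

    if lines is None:
        lines = _stream(grid)
    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(coords[:, 0], coords[:, 1], c=tau, cmap="viridis",
                    s=s, alpha=0.7)
    fig.colorbar(sc, ax=ax, label="pseudotime")
    for ln in lines:
        ax.plot(ln[:, 0], ln[:, 1], color="k", lw=0.6, alpha=0.7)
        if len(ln) > 1:
            ax.annotate("", xy=ln[-1], xytext=ln[-2],
                        arrowprops=dict(arrowstyle="->", color="k", lw=0.6))
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
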