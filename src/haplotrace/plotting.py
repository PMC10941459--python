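"""Heatmap export for distance and ratio matrices."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_distance_matrix(
    matrix: np.ndarray,
    path=None,
    title: str = "",
    cmap: str = "magma_r",
    cbar_label: str = "distance (µm)",
    vmin=None,
    vmax=None,
):
    """Render a region x region matrix as a heatmap.

    NaN (masked) entries are shown in gray.  For observed/expected ratio
    maps pass a diverging colormap (e.g. ``"coolwarm_r"``) centered at 1.
    Returns the figure; writes a PNG when ``path`` is given.
    """
    matrix = np.asarray(matrix, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    cmap_obj = plt.get_cmap(cmap).copy()
    cmap_obj.set_bad("0.8")
    im = ax.imshow(
        np.ma.masked_invalid(matrix),
        cmap=cmap_obj,
        vmin=vmin,
        vmax=vmax,
        origin="lower",
        interpolation="nearest",
    )
    n = matrix.shape[0]
    ticks = np.arange(0, n, max(n // 7, 1))
    ax.set_xticks(ticks, ticks + 1)
    ax.set_yticks(ticks, ticks + 1)
    ax.set_xlabel("region")
    ax.set_ylabel("region")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label=cbar_label)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
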