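"""Plotting helpers (matplotlib)."""

from __future__ import annotations

import numpy as np


def plot_hildebrand(matrix, ax=None, title=None):
    """Render a Hildebrand raster (limbs x stride phase, stance probability)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 2))
    ax.imshow(matrix.to_numpy(), aspect="auto", cmap="Greys",
              vmin=0, vmax=1, extent=(0, 1, len(matrix), 0))
    ax.set_yticks(np.arange(len(matrix)) + 0.5, list(matrix.index))
    ax.set_xlabel("stride phase")
    if title:
        ax.set_title(title)
    return ax


def plot_landing_heatmap(heatmap, ax=None):
    """Render actual-vs-predicted landing distributions (column normalized)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    edges = heatmap.columns.to_numpy(float)
    ax.imshow(heatmap.to_numpy(), origin="lower", aspect="auto",
              extent=(edges[0], edges[-1], edges[0], edges[-1]),
              cmap="magma")
    ax.plot(edges, edges, color="w", lw=0.5, ls="--")
    ax.set_xlabel("predicted landing distance (mm)")
    ax.set_ylabel("actual landing distance (mm)")
    return ax
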