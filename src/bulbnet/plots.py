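"""Summary figures for saved runs: spike rasters and weight maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["raster_axes", "weight_map_axes", "summary_figure"]


def raster_axes(ax, spikes_cell, spikes_t, n_mitral, title="spikes"):
    """Mitral (bottom) and granule (top) spike raster."""
    ax.plot(spikes_t[spikes_cell < n_mitral] * 1e-3,
            spikes_cell[spikes_cell < n_mitral], ".", ms=1.5, color="k")
    gc = spikes_cell >= n_mitral
    if gc.any():
        ax.plot(spikes_t[gc] * 1e-3, spikes_cell[gc], ".", ms=0.5,
                color="tab:red", alpha=0.4)
    ax.axhline(n_mitral - 0.5, color="0.6", lw=0.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cell (site order)")
    ax.set_title(title)


def weight_map_axes(ax, matrix, title="normalized inhibitory weights"):
    im = ax.imshow(matrix.T, origin="lower", aspect="auto",
                   cmap="viridis", vmin=0.0)
    ax.set_xlabel("mitral cell")
    ax.set_ylabel("granule cell")
    ax.set_title(title)
    return im


def summary_figure(spikes_cell, spikes_t, n_mitral, inh_matrix, exc_matrix,
                   path):
    """Raster plus excitatory/inhibitory weight maps, written to ``path``."""
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    raster_axes(axes[0], np.asarray(spikes_cell), np.asarray(spikes_t),
                n_mitral)
    weight_map_axes(axes[1], np.asarray(exc_matrix),
                    "normalized excitatory weights")
    im = weight_map_axes(axes[2], np.asarray(inh_matrix))
    fig.colorbar(im, ax=axes[2], shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
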