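"""Head-map and loading plots (derived artifacts, never inputs)."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.interpolate import griddata

from .montage import Montage


def plot_headmap(values: np.ndarray, montage: Montage, ax=None,
                 title: str = "", cmap: str = "RdBu_r"):
    """Interpolated scalp map of one value per scalp channel."""
    xy = montage.coords()
    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3))
    gx, gy = np.meshgrid(np.linspace(-1.1, 1.1, 101), np.linspace(-1.1, 1.1, 101))
    gz = griddata(xy, values, (gx, gy), method="cubic")
    mask = gx ** 2 + gy ** 2 > 1.1 ** 2
    gz[mask] = np.nan
    vmax = np.nanmax(np.abs(values)) or 1.0
    ax.imshow(gz, extent=(-1.1, 1.1, -1.1, 1.1), origin="lower",
              cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.scatter(xy[:, 0], xy[:, 1], s=6, c="k")
    ax.add_patch(plt.Circle((0, 0), 1.0, fill=False, lw=1))
    ax.set_xticks([]); ax.set_yticks([])
    ax.set_title(title, fontsize=8)
    ax.set_aspect("equal")
    return ax


def plot_loadings(times_s: np.ndarray, loadings: np.ndarray,
                  labels: list[str], path: str | Path | None = None):
    """Scaled factor-loading waveforms (uV) against time."""
    fig, ax = plt.subplots(figsize=(5, 3))
    for k, lab in enumerate(labels):
        ax.plot(times_s * 1000.0, loadings[:, k], label=lab, lw=1)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("loading (µV)")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
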