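"""Thin optional plotting layer over the comparison/report tables."""

from __future__ import annotations

import pandas as pd

from .comparison import DensityGrid
from .gc_tracks import GCProfile


def plot_density_grid(grid: DensityGrid, ax=None, log_counts: bool = True):
    """Render a density grid as a pcolormesh heat map."""
    import matplotlib.pyplot as plt
    import numpy as np

    if ax is None:
        _, ax = plt.subplots()
    counts = grid.counts.T
    if log_counts:
        counts = np.log10(counts + 1)
    mesh = ax.pcolormesh(grid.x_edges, grid.y_edges, counts, cmap="viridis")
    ax.figure.colorbar(mesh, ax=ax, label="log10(bp count + 1)" if log_counts else "bp count")
    return ax


def plot_gc_profile(profile: GCProfile, ax=None, genome_gc: float | None = None):
    """GC percent versus offset around read starts, fragment band boxed."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.offsets, 100 * profile.gc_frequency, lw=1)
    if genome_gc is not None:
        ax.axhline(100 * genome_gc, ls="--", color="gray")
    ax.axvspan(0, 149, alpha=0.15, color="orange")
    ax.set_xlabel("offset from read start (bp)")
    ax.set_ylabel("GC content (%)")
    return ax


def plot_region(report: pd.DataFrame, track_columns: list[str], ax=None):
    """Per-base region profiles with the genome-average reference at 1."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for col in track_columns:
        ax.plot(report["position"], report[col], lw=0.8, label=col)
    ax.axhline(1.0, ls="--", color="gray")
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("coverage / genome mean")
    ax.legend()
    return ax
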