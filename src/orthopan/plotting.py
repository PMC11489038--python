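"""Optional matplotlib views of the main results."""
from __future__ import annotations

from typing import Sequence

import numpy as np

from .growth import CurveFitResult, SubsetPoint, mean_sizes
from .hotspots import WindowTrack


def plot_growth_fit(
    points: Sequence[SubsetPoint],
    pan_fit: CurveFitResult | None = None,
    core_fit: CurveFitResult | None = None,
    ax=None,
):
    """Subset pan/core sizes with fitted growth curves overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    k = np.array([p.k for p in points])
    jitter = (np.arange(len(points)) % 7 - 3) * 0.02
    ax.scatter(k + jitter, [p.pan_size for p in points], s=8, alpha=0.4, label="pan (subsets)")
    ax.scatter(k + jitter, [p.core_size for p in points], s=8, alpha=0.4, label="core (subsets)")
    grid = np.linspace(k.min(), k.max(), 200)
    if pan_fit is not None:
        ax.plot(grid, pan_fit.predict(grid), lw=2, label="pan fit $Ax^B+C$")
    if core_fit is not None:
        ax.plot(grid, core_fit.predict(grid), lw=2, label="core fit $Ae^{Bx}+C$")
    ax.set_xlabel("number of haplomes")
    ax.set_ylabel("orthogroups")
    ax.legend()
    return ax


def plot_window_density(track: WindowTrack, hotspot_indices=None, ax=None):
    """Per-window SV breakpoint and gene counts along the genome."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    x = np.arange(track.n_windows)
    if track.sv_count is not None:
        ax.plot(x, track.sv_count, lw=0.8, label="SV breakpoints")
    if track.gene_count is not None:
        ax.plot(x, track.gene_count, lw=0.8, alpha=0.7, label="genes")
    if hotspot_indices is not None and len(hotspot_indices):
        ax.scatter(hotspot_indices, np.asarray(track.sv_count)[hotspot_indices],
                   color="red", s=12, zorder=3, label="hotspots")
    ax.set_xlabel("window index")
    ax.set_ylabel("count per window")
    ax.legend()
    return ax
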