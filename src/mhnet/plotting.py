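"""Matplotlib helpers for connectome time series.

One panel per indicator, one curve per group, optional vertical markers
at wave boundaries.  These are convenience plots for eyeballing runs;
publication styling is left to the caller.
"""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .connectome import ConnectomeSeries
from .ingest import WaveBoundaries


def plot_connectome(series: ConnectomeSeries, metric: str = "correlation",
                    waves: WaveBoundaries | None = None, ax=None):
    """Plot one metric's per-group curves; returns the axes."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3.5))
    M = (series.mean_correlation if metric == "correlation"
         else series.mean_centrality)
    for gi, group in enumerate(series.groups):
        ax.plot(series.window_starts, M[gi], label=group, lw=1.2)
    if waves is not None:
        for _, start, end in waves.waves:
            ax.axvline(start, color="tab:blue", ls="-.", lw=0.8)
            ax.axvline(end, color="tab:blue", ls="-.", lw=0.8)
    ax.set_ylabel(f"mean {metric}")
    ax.set_title(series.indicator)
    ax.legend(fontsize="small", ncol=2)
    return ax


def save_connectome_figure(series_by_indicator: dict[str, ConnectomeSeries],
                           path, metric: str = "correlation",
                           waves: WaveBoundaries | None = None) -> None:
    """Stacked per-indicator panels written to ``path``."""
    n = len(series_by_indicator)
    fig, axes = plt.subplots(n, 1, figsize=(9, 3.2 * n), squeeze=False,
                             sharex=True)
    for ax, (name, series) in zip(axes[:, 0], series_by_indicator.items()):
        plot_connectome(series, metric=metric, waves=waves, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
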