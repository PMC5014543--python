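"""Trajectory plots: fitted group mean speeds over visits, with observed spaghetti."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .gbtm import GbtmModel
from .ingest import VISIT_BASE, SpeedSeries


def plot_trajectories(
    model: GbtmModel,
    series: list[SpeedSeries] | None = None,
    path: str | Path | None = None,
    title: str = "Fitted response-speed trajectories",
    max_spaghetti: int = 150,
):
    """Plot fitted group means (speed vs visit); optionally overlay a sample of
    observed per-participant series.  Returns the matplotlib figure."""
    t_max = (
        int(max(s.times.max() for s in series))
        if series
        else 8
    )
    grid = np.linspace(0, t_max, 200)
    mu = model.mean_at(grid)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    if series:
        for s in series[:max_spaghetti]:
            ax.plot(s.times + VISIT_BASE, s.speeds, color="grey", alpha=0.15, lw=0.6)
    for j in range(model.K):
        ax.plot(
            grid + VISIT_BASE,
            mu[j],
            lw=2.2,
            label=f"group {j + 1} ({100 * model.pi[j]:.1f}%)",
        )
    ax.set_xlabel("visit")
    ax.set_ylabel("response speed (words/s)")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
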