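"""Minimal figure output: abundance heatmap and peak-time histogram."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io import SampleRecord
from .report import bait_profile

__all__ = ["plot_phase_histogram", "plot_heatmap"]


def plot_phase_histogram(counts: pd.Series, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar([str(int(z)) for z in counts.index], counts.to_numpy(), color="0.3")
    ax.set_xlabel("peak Zeitgeber time (h)")
    ax.set_ylabel("proteins")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_heatmap(
    table: pd.DataFrame,
    design: Sequence[SampleRecord],
    order: Sequence[str],
    path: str | Path,
) -> None:
    profiles = np.vstack([bait_profile(table, design, a).to_numpy() for a in order])
    sd = profiles.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (profiles - profiles.mean(axis=1, keepdims=True)) / sd[:, None]
    zts = bait_profile(table, design, order[0]).index
    fig, ax = plt.subplots(figsize=(4, max(3, 0.12 * len(order))))
    im = ax.imshow(z, aspect="auto", cmap="RdBu_r", vmin=-2, vmax=2)
    ax.set_xticks(range(len(zts)), [str(int(t)) for t in zts])
    ax.set_yticks(range(len(order)), list(order), fontsize=4)
    ax.set_xlabel("Zeitgeber time (h)")
    fig.colorbar(im, ax=ax, label="z-scored abundance")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
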