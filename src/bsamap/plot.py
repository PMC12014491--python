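"""A single scan figure: per-window mean allelic distance ± s.e.m."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .models import Window


def plot_scan(windows: Sequence[Window], path: str | Path) -> None:
    """Dot-and-error-bar scan plot, one panel per chromosome."""
    chroms = sorted({w.chrom for w in windows})
    fig, axes = plt.subplots(
        1, len(chroms), figsize=(4 * len(chroms), 3), sharey=True, squeeze=False
    )
    for ax, chrom in zip(axes[0], chroms):
        ws = [w for w in windows if w.chrom == chrom and w.mean_distance is not None]
        x = [(w.start + w.end) / 2 / 1e6 for w in ws]
        y = [w.mean_distance for w in ws]
        yerr = [w.sem if w.sem is not None else 0.0 for w in ws]
        ax.errorbar(x, y, yerr=yerr, fmt="o", ms=3, lw=1, capsize=2)
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_title(chrom)
        ax.set_xlabel("position (Mbp)")
    axes[0][0].set_ylabel("mean allelic distance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
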