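"""Matplotlib figures for the variant comparison and sub-band report."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .evaluate import PerformanceDistribution


def variant_bar_chart(
    dists: Sequence[PerformanceDistribution], path: str | Path, title: str = ""
) -> None:
    """Mean MCC per variant with standard-error bars."""
    fig, ax = plt.subplots(figsize=(7, 4))
    names = [d.variant_id for d in dists]
    means = [d.mean_mcc for d in dists]
    ses = [d.se_mcc for d in dists]
    colors = ["#3465a4" if n == "original" else "#73d216" for n in names]
    ax.bar(names, means, yerr=ses, capsize=4, color=colors)
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_ylabel("MCC (mean ± SE)")
    ax.set_xlabel("variant")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def subband_histograms(histograms: pd.DataFrame, path: str | Path) -> None:
    """Per-band dual histograms of bootstrapped coupling magnitude."""
    bands = sorted(
        {(r.band_low, r.band_high) for r in histograms.itertuples()}
    )
    n = len(bands)
    ncols = min(3, n)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False
    )
    for ax, (low, high) in zip(axes.ravel(), bands):
        sub = histograms[
            (histograms["band_low"] == low) & (histograms["band_high"] == high)
        ]
        for group, color in (("stayed", "#3465a4"), ("separated", "#888a85")):
            g = sub[sub["group"] == group]
            ax.bar(
                g["bin_left"],
                g["count"],
                width=g["bin_right"] - g["bin_left"],
                align="edge",
                alpha=0.6,
                color=color,
                label=group,
            )
        ax.set_title(f"{low:g}–{high:g} cpm")
        ax.set_xlabel("mean log10 |CPSD|")
        ax.set_ylabel("count")
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    axes[0, 0].legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
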