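"""Genome-scan figures: raw per-SNP points, fitted line, threshold lines."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_scan(result, path: str | Path, statistic: str = "delta") -> None:
    """One panel per chromosome: per-SNP statistic, LOESS track, thresholds.

    ``statistic`` is ``"delta"`` (ΔSNP-index with the 95%/99% simulation
    CI) or ``"ed4"`` (ED⁴ with the genome-wide top-fraction threshold).
    """
    sites = result.sites
    windows = result.windows
    chroms = list(dict.fromkeys(sites["chrom"]))
    n = len(chroms)
    ncol = min(4, n)
    nrow = (n + ncol - 1) // ncol
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(3.2 * ncol, 2.4 * nrow), sharey=True, squeeze=False
    )
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    for ax, chrom in zip(axes.flat, chroms):
        s = sites[sites["chrom"] == chrom]
        w = windows[windows["chrom"] == chrom]
        mid = (w["start"] + w["end"]) / 2e6
        if statistic == "delta":
            ax.plot(s["pos"] / 1e6, s["delta"], ".", ms=2, color="0.6", alpha=0.5)
            ax.plot(mid, w["fitted_delta"], "-", color="crimson", lw=1.5)
            for col, color in (("ci95", "green"), ("ci99", "blue")):
                if col in w:
                    ax.plot(mid, w[col], "--", color=color, lw=0.8)
                    ax.plot(mid, -w[col], "--", color=color, lw=0.8)
            ax.set_ylim(-1.05, 1.05)
        else:
            ax.plot(s["pos"] / 1e6, s["ed4"], ".", ms=2, color="0.6", alpha=0.5)
            ax.plot(mid, w["fitted_ed4"], "-", color="black", lw=1.5)
            ax.axhline(result.ed4_threshold, ls=":", color="red", lw=1)
            ax.set_ylim(-0.1, 4.2)
        ax.set_title(chrom, fontsize=8)
        ax.tick_params(labelsize=7)
    label = "ΔSNP-index" if statistic == "delta" else "ED$^4$"
    fig.supxlabel("position (Mb)", fontsize=9)
    fig.supylabel(label, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
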