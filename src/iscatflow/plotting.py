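"""Small plotting helpers (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_contrast_histogram(hist: pd.DataFrame, cutoff: float, path=None):
    """Contrast-magnitude histogram with the background/signal cutoff line."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.step(hist["bin_center"], hist["count"], where="mid")
    ax.axvline(cutoff, ls="--", color="k", label=f"cutoff {cutoff:g}")
    ax.set_xscale("log")
    ax.set_xlabel("|contrast|")
    ax.set_ylabel("counts")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_density_bars(summary: pd.DataFrame, path=None):
    """Per-condition mean densities with SD error bars."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    x = np.arange(len(summary))
    ax.bar(x, summary["mean"], yerr=summary.get("sd"), capsize=3)
    ax.set_xticks(x, summary["group"], rotation=45, ha="right")
    ax.set_ylabel("density (per 100 um$^2$)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
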