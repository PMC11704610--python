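"""Simple diagnostic figures: CV2-vs-mean clouds and reciprocity scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_cv2_vs_mean", "plot_reciprocity"]


def plot_cv2_vs_mean(summaries: dict[str, pd.DataFrame], ax=None):
    """Log-log CV2 against mean, one cloud per labelled summary.

    The 1/mean reference line marks pure Poisson (Fano = 1) scaling.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for label, s in summaries.items():
        ok = ~s["undefined"]
        ax.scatter(s.loc[ok, "mean"], s.loc[ok, "cv2"], s=8, alpha=0.5, label=label)
    lo, hi = ax.get_xlim()
    grid = np.logspace(np.log10(max(lo, 1e-3)), np.log10(max(hi, 1.0)), 50)
    ax.plot(grid, 1.0 / grid, "k--", lw=1, label="Poisson (CV2 = 1/mean)")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("mean expression")
    ax.set_ylabel("CV$^2$")
    ax.legend(fontsize=7)
    return ax


def plot_reciprocity(per_replicate: pd.DataFrame, regression: dict | None = None, ax=None):
    """log2 burst-size vs log2 burst-frequency fold changes per gene/replicate."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for gid, grp in per_replicate.groupby("gene_id"):
        ax.scatter(grp["log2_d_f"], grp["log2_d_b"], s=14, label=gid)
    ax.axhline(0, color="r", lw=0.6)
    ax.axvline(0, color="r", lw=0.6)
    if regression is not None:
        x = np.array(ax.get_xlim())
        ax.plot(x, regression["intercept"] + regression["slope"] * x, "k-", lw=1)
    ax.set_xlabel("log$_2$ $\\Delta$ burst frequency")
    ax.set_ylabel("log$_2$ $\\Delta$ burst size")
    return ax
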