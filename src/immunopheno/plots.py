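"""Presentation-only figure exports (heatmaps, stacked bars, dotplots)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["heatmap", "stacked_bar", "dotplot"]


def heatmap(df: pd.DataFrame, path, title: str = "", cmap: str = "viridis"):
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * df.shape[1] + 2), max(3, 0.3 * df.shape[0] + 1.5)))
    im = ax.imshow(df.to_numpy(dtype=float), aspect="auto", cmap=cmap)
    ax.set_xticks(range(df.shape[1]), [str(c) for c in df.columns], rotation=90, fontsize=7)
    ax.set_yticks(range(df.shape[0]), [str(i) for i in df.index], fontsize=7)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def stacked_bar(comp: pd.DataFrame, path, title: str = "composition"):
    fig, ax = plt.subplots(figsize=(max(4, 0.8 * len(comp) + 2), 4))
    bottom = np.zeros(len(comp))
    for col in comp.columns:
        vals = comp[col].to_numpy(dtype=float)
        ax.bar(range(len(comp)), vals, bottom=bottom, label=str(col))
        bottom += np.nan_to_num(vals)
    ax.set_xticks(range(len(comp)), [str(i) for i in comp.index], rotation=45, fontsize=8)
    ax.set_ylabel("fraction")
    ax.set_title(title)
    ax.legend(fontsize=6, ncols=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def dotplot(frac: pd.DataFrame, path, title: str = "overexpressed gene fractions"):
    """Dot size (and color) encodes the fraction of overexpressed genes."""
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * frac.shape[1] + 2), max(3, 0.4 * frac.shape[0] + 1.5)))
    for yi, idx in enumerate(frac.index):
        for xi, col in enumerate(frac.columns):
            v = float(frac.loc[idx, col])
            ax.scatter(xi, yi, s=20 + 350 * v, c=[[1 - v, 1 - v, 1.0]], edgecolors="k", linewidths=0.4)
    ax.set_xticks(range(frac.shape[1]), [str(c) for c in frac.columns], rotation=45, fontsize=8)
    ax.set_yticks(range(frac.shape[0]), [str(i) for i in frac.index], fontsize=8)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
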