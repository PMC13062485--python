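"""Static figures: replicate scatter and nLFC heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .library_io import CountMatrix


def plot_replicate_scatter(cm: CountMatrix, sample_a: str, sample_b: str,
                           path: str | Path) -> None:
    """log2(count+1) replicate scatter with median dashed lines."""
    xa = np.log2(cm.counts[sample_a] + 1.0)
    xb = np.log2(cm.counts[sample_b] + 1.0)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(xa, xb, s=4, alpha=0.3, rasterized=True)
    ax.axvline(np.median(xa), ls="--", c="grey", lw=0.8)
    ax.axhline(np.median(xb), ls="--", c="grey", lw=0.8)
    ax.set_xlabel(f"{sample_a} log2(count+1)")
    ax.set_ylabel(f"{sample_b} log2(count+1)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_nlfc_heatmap(matrix: pd.DataFrame, labels: pd.Series,
                      path: str | Path) -> None:
    """Guide x cell-line nLFC heatmap, rows grouped by cluster label."""
    order = labels.sort_values(kind="stable").index
    data = matrix.loc[order]
    fig, ax = plt.subplots(figsize=(4, max(3, len(data) * 0.02)))
    vmax = float(np.nanmax(np.abs(data.values))) or 1.0
    im = ax.imshow(data.values, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(data.shape[1]), data.columns, rotation=45, ha="right")
    ax.set_yticks([])
    ax.set_ylabel(f"{len(data)} significant guides (grouped by cluster)")
    fig.colorbar(im, ax=ax, label="nLFC")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
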