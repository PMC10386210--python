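"""Rendering: volcano plot, cluster dendrogram, PCA score/loading biplot.

Every renderer writes the figure (PNG/SVG inferred from the suffix) and, by
design, the plotted coordinates are also available as plain CSV from the
pipeline so no number exists only inside an image.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd
from scipy.cluster import hierarchy

from srs_signal.dispro import DisproResult, volcano_data
from srs_signal.structure import ClusterResult, LnRorMatrix, PcaResult

_CLUSTER_COLORS = ["tab:red", "tab:green", "tab:blue", "tab:orange", "tab:purple", "tab:brown"]


def render_volcano(results: Sequence[DisproResult], path: str | Path, alpha: float = 0.05) -> Path:
    """Scatter of lnROR vs -log10 p, coloured by log10 of the report count."""
    frame = volcano_data(results, alpha=alpha)
    fig, ax = plt.subplots(figsize=(7, 5))
    sc = ax.scatter(frame["x"], frame["y"], c=frame["color"], cmap="coolwarm_r", s=25, edgecolors="none")
    ax.axhline(frame.attrs["reference_y"], linestyle=":", color="grey", linewidth=1)
    ax.axvline(0.0, linestyle=":", color="grey", linewidth=1)
    ax.set_xlabel("lnROR")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    fig.colorbar(sc, ax=ax, label=r"$\log_{10}$(reports)")
    for _, row in frame[frame["is_signal"]].iterrows():
        ax.annotate(row["drug"], (row["x"], row["y"]), fontsize=5, alpha=0.8)
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def render_dendrogram(matrix: LnRorMatrix, clusters: ClusterResult, path: str | Path) -> Path:
    """Ward dendrogram over the drug rows, colour-coded at the k-cluster cut."""
    fig, ax = plt.subplots(figsize=(8, 4.5))
    # colour threshold just above the (n-k)th merge height reproduces the cut
    heights = clusters.linkage[:, 2]
    n_merges = len(heights)
    if clusters.k <= 1 or clusters.k > n_merges:
        threshold = 0.0
    else:
        threshold = (heights[n_merges - clusters.k] + heights[n_merges - clusters.k + 1]) / 2.0
    hierarchy.dendrogram(
        clusters.linkage,
        labels=list(matrix.values.index),
        color_threshold=threshold,
        leaf_rotation=90,
        ax=ax,
    )
    ax.set_ylabel("Ward distance")
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def render_biplot(pca: PcaResult, clusters: ClusterResult | None, path: str | Path) -> Path:
    """Two panels: PC1/PC2 drug scores (coloured by cluster) and PT loadings."""
    fig, (ax_scores, ax_load) = plt.subplots(1, 2, figsize=(11, 5))

    scores = pca.pc1_pc2_scores
    if clusters is not None:
        colors = [_CLUSTER_COLORS[(clusters.labels[d] - 1) % len(_CLUSTER_COLORS)] for d in scores.index]
    else:
        colors = ["tab:blue"] * len(scores)
    ax_scores.scatter(scores["PC1"], scores["PC2"], c=colors, s=30)
    for name, row in scores.iterrows():
        ax_scores.annotate(name, (row["PC1"], row["PC2"]), fontsize=6)
    ax_scores.axhline(0, color="grey", linewidth=0.5)
    ax_scores.axvline(0, color="grey", linewidth=0.5)
    ax_scores.set_xlabel(f"PC1 ({pca.contributions['PC1']:.1f}%)")
    ax_scores.set_ylabel(f"PC2 ({pca.contributions['PC2']:.1f}%)")
    ax_scores.set_title("scores (drugs)")

    loadings = pca.pc1_pc2_loadings
    for name, row in loadings.iterrows():
        ax_load.annotate(
            "", xy=(row["PC1"], row["PC2"]), xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="tab:red", lw=1.2),
        )
        ax_load.annotate(name, (row["PC1"], row["PC2"]), fontsize=7)
    lim = max(1.05, float(loadings.abs().to_numpy().max()) * 1.2)
    ax_load.set_xlim(-lim, lim)
    ax_load.set_ylim(-lim, lim)
    ax_load.axhline(0, color="grey", linewidth=0.5)
    ax_load.axvline(0, color="grey", linewidth=0.5)
    ax_load.set_xlabel("PC1 loading")
    ax_load.set_ylabel("PC2 loading")
    ax_load.set_title("loadings (PTs)")

    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def save_frame(frame: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    frame.to_csv(path, index=index)
    return path
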