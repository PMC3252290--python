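"""Plotting: R1 x R2 heatmaps and the annotated structure-space map.

Heatmaps follow the screen's color convention: green = negative NSI
(cleared, desirable), red = positive (retained), grey = missing — a
compound absent from the library or an empty well, kept distinct from
NSI = 0.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_heatmap", "plot_chemspace"]


def plot_heatmap(heatmap: pd.DataFrame, path, title: str = "") -> None:
    """Render one R1 x R2 NSI heatmap to an image file."""
    data = heatmap.to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(10, 4))
    lim = np.nanmax(np.abs(data)) if np.isfinite(data).any() else 1.0
    cmap = plt.get_cmap("RdYlGn_r").copy()  # green low (negative), red high
    cmap.set_bad("0.7")
    im = ax.imshow(np.ma.masked_invalid(data), cmap=cmap, vmin=-lim,
                   vmax=lim, aspect="auto")
    ax.set_xticks(range(len(heatmap.columns)),
                  [str(c) for c in heatmap.columns], fontsize=7)
    ax.set_yticks(range(len(heatmap.index)), list(heatmap.index), fontsize=8)
    ax.set_xlabel("R2")
    ax.set_ylabel("R1")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="NSI")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_chemspace(embedding: np.ndarray, r1_labels: list[str],
                   nsi: dict[str, float] | None, compound_ids: list[str],
                   path, top_k: int = 10) -> None:
    """Scatter the MDS embedding, colored by R1 block.

    If per-compound NSI values are given, the ``top_k`` most negative
    compounds are drawn as large green circles on top.
    """
    emb = np.asarray(embedding)
    blocks = sorted(set(r1_labels))
    cmap = plt.get_cmap("tab20")
    fig, ax = plt.subplots(figsize=(6, 6))
    for i, b in enumerate(blocks):
        idx = [j for j, lab in enumerate(r1_labels) if lab == b]
        ax.scatter(emb[idx, 0], emb[idx, 1], s=18, color=cmap(i % 20),
                   label=b, alpha=0.8)
    if nsi:
        ranked = sorted((v, c) for c, v in nsi.items()
                        if c in set(compound_ids))
        hits = {c for _, c in ranked[:top_k]}
        idx = [j for j, c in enumerate(compound_ids) if c in hits]
        ax.scatter(emb[idx, 0], emb[idx, 1], s=160, facecolors="none",
                   edgecolors="green", linewidths=2.0, label="top hits")
    ax.legend(fontsize=7, ncol=2, title="R1")
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
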