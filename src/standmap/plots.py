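"""Optional figure output: dendrogram, silhouette profile, colored maps.

Requires matplotlib (the ``plot`` extra); everything else in the package
works without it.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from scipy.cluster import hierarchy

from .cluster import ClusterModel, Embedding, LinkageTree


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_dendrogram(tree: LinkageTree, path: str | Path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(8, 4))
    hierarchy.dendrogram(tree.merges, labels=tree.trial_ids, ax=ax, leaf_rotation=90)
    ax.set_ylabel("merge height (m)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_silhouette_profile(model: ClusterModel, path: str | Path) -> None:
    plt = _plt()
    ks = sorted(model.silhouette_by_k)
    vals = [model.silhouette_by_k[k] for k in ks]
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(ks, vals, "o-")
    ax.axvline(model.selected_k, color="r", ls="--", label=f"selected k={model.selected_k}")
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("mean silhouette")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_map(map_table: pd.DataFrame, color_by: str, path: str | Path) -> None:
    """One 2-D behavior map colored by ``product``, ``BI`` or ``MMSE``."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 5))
    if map_table[color_by].dtype == object:
        for value, grp in map_table.groupby(color_by):
            ax.scatter(grp.x, grp.y, label=str(value))
        ax.legend(title=color_by)
    else:
        sc = ax.scatter(map_table.x, map_table.y, c=map_table[color_by])
        fig.colorbar(sc, ax=ax, label=color_by)
    for row in map_table.itertuples(index=False):
        ax.annotate(row.trial_id, (row.x, row.y), fontsize=6)
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_all(
    out_dir: str | Path,
    tree: LinkageTree,
    model: ClusterModel,
    emb: Embedding,
    map_table: pd.DataFrame,
) -> None:
    out = Path(out_dir)
    plot_dendrogram(tree, out / "dendrogram.png")
    plot_silhouette_profile(model, out / "silhouette.png")
    for col in ("product", "BI", "MMSE"):
        plot_map(map_table, col, out / f"map_{col}.png")
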