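"""Hierarchical clustering, silhouette model selection, cluster-average
behavior and 2-D stress-minimizing embedding of a behavior library.

With only a couple of dozen trials and no prior cluster count, behaviors
are clustered agglomeratively on the precomputed Manhattan trajectory
distance matrix: UPGMA (average linkage) by default, Ward's update as an
alternative.  The number of clusters is chosen by the mean silhouette
coefficient over a scan of candidate k.  Each cluster's representative
motion is the elementwise mean of its members' resampled trajectories, and
the whole library is laid out in two dimensions by metric multidimensional
scaling (SMACOF), minimizing the raw stress

    sum_{i<j} ( d_ij - || z_i - z_j || )^2 .

Ward's method formally assumes squared Euclidean dissimilarities; applying
it to the Manhattan-sum matrix is a pragmatic cross-check (it reproduces
the UPGMA partition on this kind of data), so UPGMA is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.manifold import smacof as _sk_smacof
from sklearn.metrics import silhouette_samples as _sk_silhouette_samples

from .metrics import BehaviorDistanceMatrix, ResampledSequence

__all__ = [
    "LinkageTree",
    "ClusterModel",
    "AverageBehavior",
    "Embedding",
    "linkage",
    "silhouette_score",
    "select_k",
    "average_behavior",
    "mds_embed",
    "annotate_map",
]


def _as_square(D: BehaviorDistanceMatrix | NDArray[np.float64]) -> NDArray[np.float64]:
    M = D.total if isinstance(D, BehaviorDistanceMatrix) else np.asarray(D, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(M, M.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if np.any(M < 0):
        raise ValueError("distance matrix must be non-negative")
    if not np.allclose(np.diag(M), 0.0, atol=1e-9):
        raise ValueError("distance matrix must have a zero diagonal")
    return M


@dataclass
class LinkageTree:
    """Agglomerative merge history in scipy linkage format.

    ``merges`` is the (n-1) x 4 scipy matrix: children, merge height, size.
    """

    method: str
    merges: NDArray[np.float64]
    trial_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.trial_ids)

    def cut(self, k: int) -> NDArray[np.int_]:
        """Labels (0..k-1) from cutting the tree into exactly k clusters."""
        if not 1 <= k <= self.n_leaves:
            raise ValueError("k out of range")
        return hierarchy.cut_tree(self.merges, n_clusters=k).ravel()

    def leaf_order(self) -> list[int]:
        return hierarchy.leaves_list(self.merges).tolist()

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as node depths."""
        tree = hierarchy.to_tree(self.merges)

        def rec(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.trial_ids[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


@dataclass
class ClusterModel:
    """Result of the silhouette scan: labels at the selected cluster count."""

    tree: LinkageTree
    silhouette_by_k: dict[int, float]
    selected_k: int
    labels: NDArray[np.int_]

    @property
    def cluster_sizes(self) -> list[int]:
        return np.bincount(self.labels).tolist()

    def members(self, cluster: int) -> list[str]:
        return [t for t, lab in zip(self.tree.trial_ids, self.labels) if lab == cluster]


@dataclass
class AverageBehavior:
    """Elementwise mean trajectory of a cluster's members."""

    cluster_id: int
    n: int
    frames: NDArray[np.float64]  # n_frames x 13 x 3


@dataclass
class Embedding:
    """2-D metric MDS configuration with its raw stress."""

    trial_ids: list[str]
    coordinates: NDArray[np.float64]  # n x dim
    stress: float
    seed: int
    n_restarts: int


_METHODS = {"upgma": "average", "average": "average", "ward": "ward"}


def linkage(
    D: BehaviorDistanceMatrix | NDArray[np.float64],
    method: str = "upgma",
    trial_ids: list[str] | None = None,
) -> LinkageTree:
    """Agglomerative clustering of a precomputed dissimilarity matrix.

    ``method`` is ``"upgma"`` (average linkage, the default) or ``"ward"``.
    """
    key = method.lower()
    if key not in _METHODS:
        raise ValueError(f"unknown linkage method {method!r}")
    M = _as_square(D)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    if trial_ids is None:
        trial_ids = (
            D.trial_ids
            if isinstance(D, BehaviorDistanceMatrix)
            else [f"trial_{i}" for i in range(M.shape[0])]
        )
    merges = hierarchy.linkage(squareform(M, checks=False), method=_METHODS[key])
    return LinkageTree(method=key, merges=merges, trial_ids=list(trial_ids))


def silhouette_score(
    D: BehaviorDistanceMatrix | NDArray[np.float64], labels: NDArray[np.int_]
) -> float:
    """Mean silhouette coefficient of a labeling on a precomputed matrix.

    Per trial, s_i = (b_i - a_i) / max(a_i, b_i) with a_i the mean distance
    to the other members of its own cluster and b_i the smallest mean
    distance to another cluster; members of singleton clusters score 0.
    Undefined for k = 1 or k = n.
    """
    M = _as_square(D)
    labels = np.asarray(labels)
    k = len(np.unique(labels))
    if k < 2 or k >= M.shape[0]:
        raise ValueError("silhouette requires 2 <= k <= n - 1")
    return float(np.mean(_sk_silhouette_samples(M, labels, metric="precomputed")))


def select_k(
    tree: LinkageTree,
    D: BehaviorDistanceMatrix | NDArray[np.float64],
    k_range: range | None = None,
) -> ClusterModel:
    """Scan cluster counts and keep the one with the best mean silhouette.

    ``k_range`` defaults to 2..min(12, n-1).  Ties go to the smallest k
    (parsimony).  The full silhouette-vs-k profile is retained.
    """
    n = tree.n_leaves
    if k_range is None:
        k_range = range(2, min(12, n - 1) + 1)
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("empty k_range")
    M = _as_square(D)
    profile: dict[int, float] = {}
    for k in ks:
        profile[k] = silhouette_score(M, tree.cut(k))
    best = max(profile, key=lambda k: (profile[k], -k))
    return ClusterModel(
        tree=tree, silhouette_by_k=profile, selected_k=best, labels=tree.cut(best)
    )


def average_behavior(
    members: list[ResampledSequence], cluster_id: int = 0
) -> AverageBehavior:
    """Elementwise arithmetic mean of the members' resampled trajectories."""
    if not members:
        raise ValueError("empty member list")
    shapes = {m.frames.shape for m in members}
    if len(shapes) != 1:
        raise ValueError("members must share the same frame count")
    stack = np.stack([m.frames for m in members])
    return AverageBehavior(cluster_id=cluster_id, n=len(members), frames=stack.mean(axis=0))


def _fix_gauge(X: NDArray[np.float64]) -> NDArray[np.float64]:
    """Center and rotate to principal axes with a deterministic sign, so
    configurations from different runs are directly comparable (MDS solutions
    are arbitrary up to translation/rotation/reflection)."""
    X = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    Y = X @ vt.T
    for c in range(Y.shape[1]):
        j = np.argmax(np.abs(Y[:, c]))
        if Y[j, c] < 0:
            Y[:, c] = -Y[:, c]
    return Y


def mds_embed(
    D: BehaviorDistanceMatrix | NDArray[np.float64],
    dim: int = 2,
    seed: int = 0,
    n_restarts: int = 8,
    max_iter: int = 1000,
) -> Embedding:
    """Metric MDS of the behavior distance matrix by SMACOF majorization.

    Runs ``n_restarts`` seeded restarts and keeps the lowest-stress
    configuration; the reported stress is the raw stress
    sum_{i<j} (d_ij - ||z_i - z_j||)^2.  The configuration is centered and
    aligned to its principal axes for reproducibility.
    """
    M = _as_square(D)
    n = M.shape[0]
    if n < 3:
        raise ValueError("embedding needs at least 3 trials")
    # Flag grossly non-metric input; SMACOF still runs but stress may be large.
    tri = M[:, :, None] > M[:, None, :] + M.T[None, :, :] + 1e-9
    if tri.any():
        warnings.warn("dissimilarities violate the triangle inequality", stacklevel=2)
    X, stress = _sk_smacof(
        M,
        n_components=dim,
        n_init=n_restarts,
        random_state=seed,
        max_iter=max_iter,
        eps=1e-12,
        normalized_stress=False,
    )
    ids = (
        D.trial_ids
        if isinstance(D, BehaviorDistanceMatrix)
        else [f"trial_{i}" for i in range(n)]
    )
    return Embedding(
        trial_ids=list(ids),
        coordinates=_fix_gauge(X),
        stress=float(stress),
        seed=seed,
        n_restarts=n_restarts,
    )


def annotate_map(emb: Embedding, metadata: pd.DataFrame) -> pd.DataFrame:
    """Join embedding coordinates with trial metadata for the colored maps.

    Returns one row per embedded trial with columns
    ``trial_id, x, y, product, BI, MMSE``.
    """
    required = {"trial_id", "product", "BI", "MMSE"}
    missing_cols = required - set(metadata.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns {sorted(missing_cols)}")
    coords = pd.DataFrame(
        {
            "trial_id": emb.trial_ids,
            "x": emb.coordinates[:, 0],
            "y": emb.coordinates[:, 1],
        }
    )
    missing = set(coords.trial_id) - set(metadata.trial_id)
    if missing:
        raise ValueError(f"metadata missing trials {sorted(missing)}")
    out = coords.merge(
        metadata[["trial_id", "product", "BI", "MMSE"]], on="trial_id", how="left"
    )
    return out
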