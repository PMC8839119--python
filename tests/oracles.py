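"""Independent brute-force reference implementations used only by tests.

Each function re-derives a pipeline quantity by the most literal possible
route (explicit loops, normal equations in extended precision, naive
agglomeration) so the production code can be checked against something it
shares no code with.
"""

from __future__ import annotations

import numpy as np


def plane_normal_equations(points: np.ndarray) -> tuple[float, float, float]:
    """(a, b, d) of a*X + b*Y + Z + d = 0 via explicit normal equations in
    extended precision."""
    pts = np.asarray(points, dtype=np.longdouble)
    P = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts), dtype=np.longdouble)])
    Z = pts[:, 2]
    coef = -np.linalg.solve(
        (P.T @ P).astype(float), (P.T @ Z).astype(float)
    )
    return float(coef[0]), float(coef[1]), float(coef[2])


def manhattan_joint_distance(A: np.ndarray, B: np.ndarray, j: int) -> float:
    """Triple loop over frames and coordinates for one joint."""
    total = 0.0
    for t in range(A.shape[0]):
        for c in range(3):
            total += abs(A[t, j, c] - B[t, j, c])
    return total


def summed_distance(A: np.ndarray, B: np.ndarray) -> float:
    return sum(manhattan_joint_distance(A, B, j) for j in range(A.shape[1]))


def naive_upgma(D: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """O(n^3) average-linkage agglomeration on a square dissimilarity matrix.

    Returns the merge sequence as (members_a, members_b, height) with
    cluster members given as frozensets of leaf indices; minimal-distance
    ties go to the lexicographically smallest cluster pair.
    """
    n = D.shape[0]
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([D[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0] - 1e-15:
                    best = (d, i, j)
        d, i, j = best
        merges.append((clusters[i], clusters[j], float(d)))
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


def scipy_merge_sets(Z: np.ndarray, n: int) -> list[tuple[frozenset, frozenset, float]]:
    """Re-express a scipy linkage matrix in the same form as naive_upgma."""
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for row_idx, (a, b, h, _) in enumerate(Z):
        fa, fb = members[int(a)], members[int(b)]
        out.append((fa, fb, float(h)))
        members[n + row_idx] = fa | fb
    return out


def silhouette_by_hand(D: np.ndarray, labels: np.ndarray) -> float:
    """Per-point silhouette with explicit loops; singletons score 0."""
    labels = np.asarray(labels)
    scores = []
    for i in range(len(labels)):
        own = [j for j in range(len(labels)) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = np.mean([D[i, j] for j in own])
        b = min(
            np.mean([D[i, j] for j in range(len(labels)) if labels[j] == lab])
            for lab in set(labels)
            if lab != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def elementwise_mean(arrays: list[np.ndarray]) -> np.ndarray:
    """Average a list of equal-shape arrays with explicit loops."""
    out = np.zeros_like(arrays[0])
    it = np.nditer(out, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        out[idx] = sum(a[idx] for a in arrays) / len(arrays)
    return out


def procrustes_error(X: np.ndarray, Y: np.ndarray) -> float:
    """Residual of the best similarity alignment of Y onto X (scipy's
    normalized Procrustes disparity)."""
    from scipy.spatial import procrustes

    _, _, disparity = procrustes(X, Y)
    return float(disparity)
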