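"""Time normalization and behavior dissimilarity.

Trials differ in duration, so each object-frame skeleton sequence is first
interpolated by a natural cubic spline over normalized time and resampled to
a fixed 500 frames.  The dissimilarity between two trials K and L is then,
per joint j,

    D_j(K, L) = sum_{t=1..500} | J_Kt - J_Lt |_1

— the Manhattan distance between the two joint trajectories, summed over
frames — and the overall behavior dissimilarity is the sum over the 13
joints, D_sum = sum_j D_j.  D_sum inherits the metric axioms of the L1 norm
(symmetry, identity, triangle inequality) and scales linearly with the
coordinates, so it is a true distance on behaviors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.interpolate import CubicSpline

from .object_frame import CANONICAL_JOINTS, SkeletonSequence

__all__ = [
    "N_RESAMPLED_FRAMES",
    "ResampledSequence",
    "BehaviorDistanceMatrix",
    "resample_sequence",
    "joint_distance",
    "distance_matrix",
]

#: Fixed frame count every trial is normalized to before comparison.
N_RESAMPLED_FRAMES = 500


@dataclass
class ResampledSequence:
    """A trial resampled to a fixed number of frames (object coordinates)."""

    trial_id: str
    frames: NDArray[np.float64]  # n_frames x 13 x 3

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (13, 3):
            raise ValueError("frames must be n x 13 x 3")


@dataclass
class BehaviorDistanceMatrix:
    """Per-joint and summed trajectory distance matrices over a trial library."""

    trial_ids: list[str]
    per_joint: NDArray[np.float64]  # 13 x n x n
    total: NDArray[np.float64]  # n x n

    @property
    def n(self) -> int:
        return len(self.trial_ids)

    def joint_matrix(self, joint: str) -> NDArray[np.float64]:
        return self.per_joint[CANONICAL_JOINTS.index(joint)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.total, index=self.trial_ids, columns=self.trial_ids)


def resample_sequence(
    seq: SkeletonSequence, n_out: int = N_RESAMPLED_FRAMES
) -> ResampledSequence:
    """Resample a sequence to ``n_out`` frames with a natural cubic spline.

    Each of the 39 coordinate channels is interpolated over normalized time.
    By default time is uniform in frame index, u = (frame-1)/(T-1); if the
    sequence carries timestamps they are used instead, rescaled to [0, 1].
    The first and last output frames are pinned to the input endpoints.

    Raises
    ------
    ValueError
        If the sequence has fewer than 4 frames (a cubic spline needs at
        least 4 knots) or non-finite coordinates.
    """
    T = seq.n_frames
    if T < 4:
        raise ValueError("resampling needs at least 4 frames")
    if not np.all(np.isfinite(seq.frames)):
        raise ValueError("non-finite coordinates")
    if seq.timestamps is not None:
        ts = np.asarray(seq.timestamps, dtype=float)
        if ts.shape != (T,) or np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be strictly increasing, one per frame")
        u = (ts - ts[0]) / (ts[-1] - ts[0])
    else:
        u = np.linspace(0.0, 1.0, T)

    spline = CubicSpline(u, seq.frames, axis=0, bc_type="natural")
    out = spline(np.linspace(0.0, 1.0, n_out))
    out[0] = seq.frames[0]
    out[-1] = seq.frames[-1]
    return ResampledSequence(trial_id=seq.trial_id, frames=out)


def _pairwise(
    A: NDArray[np.float64], B: NDArray[np.float64], norm: str
) -> NDArray[np.float64]:
    """Per-joint distance between two n x 13 x 3 trajectories: 13-vector."""
    diff = A - B
    if norm == "manhattan":
        return np.abs(diff).sum(axis=(0, 2))
    if norm == "euclidean_per_frame":
        return np.sqrt((diff**2).sum(axis=2)).sum(axis=0)
    raise ValueError(f"unknown norm {norm!r}")


def joint_distance(
    A: ResampledSequence, B: ResampledSequence, joint: str | int, norm: str = "manhattan"
) -> float:
    """Trajectory distance of one joint between two resampled trials (m)."""
    if A.frames.shape != B.frames.shape:
        raise ValueError("sequences have different frame counts")
    j = joint if isinstance(joint, int) else CANONICAL_JOINTS.index(joint)
    return float(_pairwise(A.frames, B.frames, norm)[j])


def distance_matrix(
    library: list[ResampledSequence], norm: str = "manhattan"
) -> BehaviorDistanceMatrix:
    """All 13 per-joint distance matrices and their sum over a trial library.

    ``norm`` selects the per-frame norm: ``"manhattan"`` (default, the L1
    norm over the three coordinates) or ``"euclidean_per_frame"``.
    """
    n = len(library)
    if n < 2:
        raise ValueError("need at least 2 trials")
    ids = [s.trial_id for s in library]
    if len(set(ids)) != n:
        raise ValueError("duplicate trial_ids in library")
    shapes = {s.frames.shape for s in library}
    if len(shapes) != 1:
        raise ValueError("all trials must be resampled to the same frame count")

    per_joint = np.zeros((13, n, n))
    for k in range(n):
        for l in range(k + 1, n):
            dj = _pairwise(library[k].frames, library[l].frames, norm)
            per_joint[:, k, l] = dj
            per_joint[:, l, k] = dj
    return BehaviorDistanceMatrix(
        trial_ids=ids, per_joint=per_joint, total=per_joint.sum(axis=0)
    )
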