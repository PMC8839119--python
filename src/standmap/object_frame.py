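"""Seat-anchored ("object-centered") coordinate frames for sit-to-stand analysis.

Depth cameras record each trial in their own camera frame, and every seat
(chair, sofa, nursing bed) sits at a different place in the room.  To compare
standing behaviors across seats and camera placements, every skeleton
sequence is re-expressed in a coordinate system anchored to the seat itself:

* origin ``P0`` -- the annotated point at the base of the armrest or handrail
  (the intrinsic "standing aid" of the seat);
* ``ez`` -- the unit normal of the seat surface ("up");
* ``ex`` -- the front-back direction, derived from the backrest (chair/sofa)
  or side-frame (bed) plane and re-orthogonalized;
* ``ey`` -- the left-right direction, completing a right-handed basis.

Both planes are fitted by ordinary least squares in the parameterization
``a*X + b*Y + Z + d = 0`` (the coefficient of ``Z`` fixed to 1), which is
well-posed because a depth camera always views a seat surface obliquely from
above, never edge-on.  Near-vertical surfaces, where that parameterization
degenerates, are rejected explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "CANONICAL_JOINTS",
    "SHOULDER_JOINTS",
    "PELVIS_CENTER_JOINT",
    "SeatScan",
    "PlaneFit",
    "ObjectFrame",
    "SkeletonSequence",
    "fit_seat_plane",
    "build_basis",
    "make_transform",
    "normalize_sequence",
]

#: The 13 joints tracked per frame, in canonical order.  Readers and the
#: synthetic generator must emit exactly these names in exactly this order.
CANONICAL_JOINTS: tuple[str, ...] = (
    "left_shoulder",
    "left_elbow",
    "left_wrist",
    "right_shoulder",
    "right_elbow",
    "right_wrist",
    "center_pelvis",
    "left_pelvis",
    "left_knee",
    "left_ankle",
    "right_pelvis",
    "right_knee",
    "right_ankle",
)

SHOULDER_JOINTS = ("left_shoulder", "right_shoulder")
PELVIS_CENTER_JOINT = "center_pelvis"

SEAT_TYPES = ("chair", "sofa", "nursing_bed")

# |n_z| of the total-least-squares unit normal below which the c=1 plane
# parameterization is considered degenerate.
_VERTICAL_NZ_LIMIT = 0.1


@dataclass
class SeatScan:
    """Point-cloud patches of one seat, in camera coordinates (meters).

    ``surface_points`` samples the seat surface; ``reference_points`` samples
    the backrest (chair/sofa) or side frame (bed); ``anchor_point`` is the
    annotated base of the armrest/handrail and becomes the frame origin.
    """

    surface_points: NDArray[np.float64]
    reference_points: NDArray[np.float64]
    anchor_point: NDArray[np.float64]
    seat_type: str
    # Ground truth carried by the synthetic generator; None for real scans.
    true_frame: "ObjectFrame | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.surface_points = np.asarray(self.surface_points, dtype=float)
        self.reference_points = np.asarray(self.reference_points, dtype=float)
        self.anchor_point = np.asarray(self.anchor_point, dtype=float).reshape(3)
        if self.surface_points.ndim != 2 or self.surface_points.shape[1] != 3:
            raise ValueError("surface_points must be N x 3")
        if self.reference_points.ndim != 2 or self.reference_points.shape[1] != 3:
            raise ValueError("reference_points must be M x 3")
        if len(self.surface_points) < 3 or len(self.reference_points) < 3:
            raise ValueError("each patch needs at least 3 points")
        if self.seat_type not in SEAT_TYPES:
            raise ValueError(f"unknown seat_type {self.seat_type!r}")


@dataclass(frozen=True)
class PlaneFit:
    """Least-squares plane a*X + b*Y + c*Z + d = 0 with c fixed to 1."""

    a: float
    b: float
    d: float
    rms_residual: float
    c: float = 1.0

    @property
    def normal(self) -> NDArray[np.float64]:
        """Unnormalized plane normal [a, b, 1]."""
        return np.array([self.a, self.b, self.c])

    @property
    def unit_normal(self) -> NDArray[np.float64]:
        n = self.normal
        return n / np.linalg.norm(n)


@dataclass(frozen=True)
class ObjectFrame:
    """Rigid map from camera coordinates to seat-anchored coordinates.

    ``R`` has rows ``ex, ey, ez``; a camera point ``p`` maps to
    ``R @ (p - P0)``.  ``H`` is the same map in homogeneous form.
    """

    ex: NDArray[np.float64]
    ey: NDArray[np.float64]
    ez: NDArray[np.float64]
    R: NDArray[np.float64]
    P0: NDArray[np.float64]
    H: NDArray[np.float64]
    # The backrest/side-frame normal before re-orthogonalization.
    ex_raw: NDArray[np.float64] | None = None

    def apply(self, points: NDArray[np.float64]) -> NDArray[np.float64]:
        """Transform camera-frame points (..., 3) to object coordinates."""
        pts = np.asarray(points, dtype=float)
        return (pts - self.P0) @ self.R.T

    def invert(self, points: NDArray[np.float64]) -> NDArray[np.float64]:
        """Transform object-frame points (..., 3) back to camera coordinates."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.R + self.P0

    def to_dict(self) -> dict:
        return {
            "R": self.R.ravel().tolist(),
            "P0": self.P0.tolist(),
            "H": self.H.ravel().tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ObjectFrame":
        R = np.asarray(d["R"], dtype=float).reshape(3, 3)
        P0 = np.asarray(d["P0"], dtype=float)
        return make_transform((R[0], R[1], R[2]), P0)


@dataclass
class SkeletonSequence:
    """Time series of the 13 canonical joints: ``frames`` is T x 13 x 3 (m)."""

    trial_id: str
    frames: NDArray[np.float64]
    coordinate_frame: str = "camera"  # "camera" or "object"
    joint_names: tuple[str, ...] = CANONICAL_JOINTS
    timestamps: NDArray[np.float64] | None = None
    # Ground truth attached by the synthetic generator.
    true_object_frames: NDArray[np.float64] | None = field(default=None, repr=False)
    archetype: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (13, 3):
            raise ValueError("frames must be T x 13 x 3")
        if self.frames.shape[0] < 2:
            raise ValueError("sequence needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite joint coordinates")
        if tuple(self.joint_names) != CANONICAL_JOINTS:
            raise ValueError("joint_names must be the canonical 13 joints in order")
        if self.coordinate_frame not in ("camera", "object"):
            raise ValueError("coordinate_frame must be 'camera' or 'object'")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def joint(self, name: str) -> NDArray[np.float64]:
        """T x 3 trajectory of one named joint."""
        return self.frames[:, CANONICAL_JOINTS.index(name), :]


def fit_seat_plane(points: NDArray[np.float64]) -> PlaneFit:
    """Fit a*X + b*Y + Z + d = 0 to a point patch by ordinary least squares.

    Solves ``[X Y 1] [a b d]^T = -Z`` through the normal equations
    ``[a b d]^T = -(P'^T P')^{-1} P'^T Z`` with ``P' = [X Y 1]``.

    Raises
    ------
    ValueError
        If the design matrix is rank-deficient (collinear patch) or the
        patch is near-vertical (|z-component| of the total-least-squares
        unit normal below 0.1), where fixing c = 1 is ill-conditioned.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be N x 3")
    if len(pts) < 3:
        raise ValueError("plane fit needs at least 3 points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates in point patch")

    centered = pts - pts.mean(axis=0)
    # Orientation-free total-least-squares normal: smallest right singular
    # vector.  Used only to detect degenerate (collinear / vertical) patches.
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] < 1e-12 * max(1.0, svals[0]):
        raise ValueError("plane fit is rank-deficient: patch points are collinear")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    tls_normal = vt[-1]
    if abs(tls_normal[2]) < _VERTICAL_NZ_LIMIT:
        raise ValueError(
            "patch is near-vertical: the c=1 plane parameterization cannot "
            "represent planes parallel to the camera z-axis"
        )

    design = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts))])
    coef, *_ = np.linalg.lstsq(design, -pts[:, 2], rcond=None)
    a, b, d = (float(v) for v in coef)
    residual = a * pts[:, 0] + b * pts[:, 1] + pts[:, 2] + d
    rms = float(np.sqrt(np.mean(residual**2)))
    return PlaneFit(a=a, b=b, d=d, rms_residual=rms)


def _plane_signed_values(fit: PlaneFit, points: NDArray[np.float64]) -> NDArray[np.float64]:
    """a*X + b*Y + Z + d for each point: sign = side of the plane along [a,b,1]."""
    p = np.asarray(points, dtype=float)
    return fit.a * p[..., 0] + fit.b * p[..., 1] + p[..., 2] + fit.d


def build_basis(
    seat_fit: PlaneFit,
    reference_fit: PlaneFit,
    skeleton_hint: SkeletonSequence | None = None,
) -> tuple[NDArray[np.float64], NDArray[np.float64], NDArray[np.float64]]:
    """Construct the orthonormal (ex, ey, ez) basis of the object frame.

    ``ez`` is the unit seat-surface normal; the raw front-back direction
    ``ex'`` is the unit backrest/side-frame normal; ``ey = ez x ex'``
    (normalized) and ``ex = ey x ez`` re-orthogonalizes the triad.

    The two plane normals leave a sign ambiguity in ``ez`` and ``ex``.  When
    a camera-frame ``skeleton_hint`` is supplied, signs are fixed so that the
    temporal mean of the shoulder joints lies on the positive-``ez`` side of
    the seat plane ("up" points from seat toward shoulders), and the net
    first-to-last displacement of the pelvis center has non-negative ``ex``
    component ("forward" is the direction of standing travel).  Flipping
    ``ex`` flips ``ey`` with it, preserving right-handedness.
    """
    ez = seat_fit.unit_normal
    ex_raw = reference_fit.unit_normal

    cross = np.cross(ez, ex_raw)
    norm = np.linalg.norm(cross)
    if norm < 1e-8:
        raise ValueError(
            "backrest/side-frame plane is parallel to the seat plane; "
            "cannot define a front-back direction"
        )
    ey = cross / norm
    ex = np.cross(ey, ez)

    if skeleton_hint is not None:
        shoulder_idx = [CANONICAL_JOINTS.index(j) for j in SHOULDER_JOINTS]
        shoulders = skeleton_hint.frames[:, shoulder_idx, :]
        if np.mean(_plane_signed_values(seat_fit, shoulders)) < 0:
            ez = -ez
            ey = -ey  # keep ey = ez x ex_raw, ex = ey x ez unchanged
        pelvis = skeleton_hint.joint(PELVIS_CENTER_JOINT)
        travel = pelvis[-1] - pelvis[0]
        if float(travel @ ex) < 0:
            ex = -ex
            ey = -ey
    return ex, ey, ez


def make_transform(
    basis: tuple[NDArray[np.float64], NDArray[np.float64], NDArray[np.float64]],
    origin: NDArray[np.float64],
) -> ObjectFrame:
    """Assemble the rigid camera-to-object transform from a basis and origin.

    ``R`` stacks ``ex, ey, ez`` as rows; the homogeneous transform is
    ``H = [[R, -R @ P0], [0, 1]]`` so that ``H`` maps the camera-frame
    anchor ``P0`` to the object-frame origin.
    """
    ex, ey, ez = (np.asarray(v, dtype=float).reshape(3) for v in basis)
    R = np.vstack([ex, ey, ez])
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
        raise ValueError("basis is not orthonormal")
    if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
        raise ValueError("basis is not right-handed (det R != +1)")
    P0 = np.asarray(origin, dtype=float).reshape(3)
    H = np.eye(4)
    H[:3, :3] = R
    H[:3, 3] = -R @ P0
    return ObjectFrame(ex=ex, ey=ey, ez=ez, R=R, P0=P0, H=H)


def frame_from_scan(
    scan: SeatScan, skeleton_hint: SkeletonSequence | None = None
) -> ObjectFrame:
    """Fit both planes of a scan and assemble its ObjectFrame.

    Convenience composition of :func:`fit_seat_plane`, :func:`build_basis`
    and :func:`make_transform` anchored at the scan's annotated point.
    """
    seat_fit = fit_seat_plane(scan.surface_points)
    ref_fit = fit_seat_plane(scan.reference_points)
    basis = build_basis(seat_fit, ref_fit, skeleton_hint)
    frame = make_transform(basis, scan.anchor_point)
    return replace(frame, ex_raw=ref_fit.unit_normal)


def normalize_sequence(seq: SkeletonSequence, frame: ObjectFrame) -> SkeletonSequence:
    """Re-express a camera-frame skeleton sequence in object coordinates."""
    if seq.coordinate_frame != "camera":
        raise ValueError("sequence is already in object coordinates")
    transformed = frame.apply(seq.frames)
    return SkeletonSequence(
        trial_id=seq.trial_id,
        frames=transformed,
        coordinate_frame="object",
        timestamps=seq.timestamps,
        true_object_frames=seq.true_object_frames,
        archetype=seq.archetype,
    )
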