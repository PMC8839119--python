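"""Synthetic seat scans and standing behaviors with planted cluster structure.

The real study data are 24 sit-to-stand trials of six elderly participants
recorded by a ceiling-mounted RGB-D camera in nursing homes (the public
"elderly behavior library").  This module generates stand-ins for every
input the pipeline consumes, so the whole analysis is testable without any
download:

* planar seat-surface and backrest/side-frame point clouds under arbitrary
  rigid camera poses, with isotropic Gaussian noise and an annotated
  armrest/handrail base point;
* skeleton sequences of the 13 canonical joints built from three key poses
  (seated, transition, standing) interpolated with a smooth cubic time
  profile, in two archetypes:

  - ``armrest_assisted`` -- the sitter is next to the armrest, keeps the
    trunk fairly upright and places a hand on the armrest base during the
    transition (the dominant behavior in the study);
  - ``forward_lean`` -- the sitter is away from the armrest (center of the
    seat), pitches the trunk far forward with a large forward shoulder
    excursion, hands pushing on the knees (the minority, riskier behavior);

* a 24-trial library whose participant IDs, sex, Barthel Index, MMSE and
  seat types copy the study's roster row for row, with the two known
  forward-lean trials (``no31_4`` and ``no32_2``) planted as the minority
  archetype.

Every generator records its ground truth (object frame, noise-free geometry,
archetype label) so downstream stages can be tested against it.  All
coordinates are meters.

Noise is drawn in the seat-anchored canonical frame *before* the camera pose
is applied: isotropic Gaussian jitter is statistically identical in any
rigid frame, and this choice makes a fixed behavior seed reproduce the exact
same behavior under every camera pose — which is what the pipeline's
camera-pose-invariance property quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.interpolate import CubicSpline

from .object_frame import (
    CANONICAL_JOINTS,
    ObjectFrame,
    SeatScan,
    SkeletonSequence,
    make_transform,
)

__all__ = [
    "SeatSpec",
    "CameraPose",
    "ArchetypeSpec",
    "SyntheticTrial",
    "seat_defaults",
    "archetype_defaults",
    "generate_seat_scan",
    "generate_standing_behavior",
    "elderly_library",
    "TABLE1_ROWS",
    "FORWARD_LEAN_TRIALS",
]

# Backrest/side-frame recline from vertical (rad).  A reclined reference
# patch keeps its plane representable by the c=1 parameterization under the
# moderate camera tilts produced by random_overhead().
_RECLINE = np.deg2rad(25.0)
_TORSO_LEN = 0.50


@dataclass(frozen=True)
class SeatSpec:
    """Geometry of one seat, in its own canonical frame (meters).

    The canonical frame has the floor at z=0, the seat-surface center at
    (0, 0, seat_height), x pointing forward (away from the backrest) and y
    to the sitter's left.  ``anchor_offset`` locates the armrest/handrail
    base relative to the seat-surface center.
    """

    seat_type: str
    seat_height: float
    seat_depth: float
    seat_width: float
    armrest_height: float
    anchor_offset: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name in ("seat_height", "seat_depth", "seat_width", "armrest_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def surface_center(self) -> NDArray[np.float64]:
        return np.array([0.0, 0.0, self.seat_height])

    @property
    def anchor(self) -> NDArray[np.float64]:
        """Armrest/handrail base point in the canonical frame."""
        return self.surface_center + np.asarray(self.anchor_offset, dtype=float)


_SEAT_DEFAULTS = {
    "chair": dict(seat_height=0.42, seat_depth=0.45, seat_width=0.55, armrest_height=0.20),
    "sofa": dict(seat_height=0.40, seat_depth=0.55, seat_width=1.60, armrest_height=0.22),
    "nursing_bed": dict(seat_height=0.45, seat_depth=0.90, seat_width=1.20, armrest_height=0.35),
}


def seat_defaults(seat_type: str) -> SeatSpec:
    """Default dimensions per seat class (plausible furniture, not measured)."""
    if seat_type not in _SEAT_DEFAULTS:
        raise ValueError(f"unknown seat_type {seat_type!r}")
    dims = _SEAT_DEFAULTS[seat_type]
    return SeatSpec(
        seat_type=seat_type,
        anchor_offset=(0.0, dims["seat_width"] / 2 + 0.03, 0.0),
        **dims,
    )


@dataclass(frozen=True)
class CameraPose:
    """Rigid map from the seat's canonical frame to camera coordinates."""

    rotation: NDArray[np.float64]
    translation: NDArray[np.float64]
    seed: int = 0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be a 3x3 orthonormal matrix")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "CameraPose":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    @classmethod
    def random_overhead(cls, seed: int, max_tilt_deg: float = 10.0) -> "CameraPose":
        """A random placement: free yaw, limited tilt, offset of a few meters.

        The tilt bound keeps both seat and backrest planes obliquely visible,
        which emulates a camera mounted near the ceiling and keeps the c=1
        plane parameterization valid.
        """
        rng = np.random.default_rng(seed)
        yaw = rng.uniform(0.0, 2 * np.pi)
        tilt = np.deg2rad(rng.uniform(0.0, max_tilt_deg))
        tilt_axis_angle = rng.uniform(0.0, 2 * np.pi)
        cz, sz = np.cos(yaw), np.sin(yaw)
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1.0]])
        axis = np.array([np.cos(tilt_axis_angle), np.sin(tilt_axis_angle), 0.0])
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        Rt = np.eye(3) + np.sin(tilt) * K + (1 - np.cos(tilt)) * (K @ K)
        t = np.concatenate([rng.uniform(-2.0, 2.0, 2), rng.uniform(1.5, 2.5, 1)])
        return cls(rotation=Rt @ Rz, translation=t, seed=int(seed))

    def apply(self, points: NDArray[np.float64]) -> NDArray[np.float64]:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class ArchetypeSpec:
    """Parameters of one synthetic standing behavior.

    ``trunk_pitch_peak`` is the forward trunk pitch at the transition key
    pose (rad from vertical); ``shoulder_forward_excursion`` is how far the
    shoulder midpoint travels forward between the seated and transition key
    poses (m).  ``hand_target`` selects the support strategy and with it the
    seated lateral position: hands to the armrest base mean sitting right
    next to the armrest, hands to the knees mean sitting at the seat center.
    """

    archetype: str
    duration_frames: int = 100
    trunk_pitch_peak: float = 0.30
    shoulder_forward_excursion: float = 0.12
    hand_target: str = "armrest_anchor"
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ("armrest_assisted", "forward_lean"):
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.duration_frames < 10:
            raise ValueError("duration_frames must be >= 10")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.hand_target not in ("armrest_anchor", "knees"):
            raise ValueError(f"unknown hand_target {self.hand_target!r}")


def archetype_defaults(
    archetype: str, duration_frames: int = 100, noise_sd: float = 0.01, seed: int = 0
) -> ArchetypeSpec:
    """Default parameterization of the two behavior archetypes.

    Defaults are chosen so the archetypes are cleanly separable at jitter
    sd 0.01 m: the forward-lean template pitches the trunk ~0.8 rad with a
    0.30 m forward shoulder excursion around the middle of the movement,
    against ~0.3 rad and 0.12 m for the armrest-assisted template.
    """
    if archetype == "armrest_assisted":
        return ArchetypeSpec(
            archetype=archetype,
            duration_frames=duration_frames,
            trunk_pitch_peak=0.30,
            shoulder_forward_excursion=0.12,
            hand_target="armrest_anchor",
            noise_sd=noise_sd,
            seed=seed,
        )
    if archetype == "forward_lean":
        return ArchetypeSpec(
            archetype=archetype,
            duration_frames=duration_frames,
            trunk_pitch_peak=0.80,
            shoulder_forward_excursion=0.30,
            hand_target="knees",
            noise_sd=noise_sd,
            seed=seed,
        )
    raise ValueError(f"unknown archetype {archetype!r}")


def _true_frame_in_camera(spec: SeatSpec, pose: CameraPose) -> ObjectFrame:
    """Ground-truth object frame of a seat, expressed in camera coordinates."""
    Q = pose.rotation
    basis = (Q @ np.array([1.0, 0, 0]), Q @ np.array([0, 1.0, 0]), Q @ np.array([0, 0, 1.0]))
    return make_transform(basis, pose.apply(spec.anchor))


def generate_seat_scan(
    spec: SeatSpec,
    pose: CameraPose,
    noise_sd: float = 0.005,
    n_points: int = 400,
    seed: int = 0,
) -> SeatScan:
    """Sample the seat-surface and backrest/side-frame patches of one seat.

    Points are drawn uniformly on each planar patch in the seat's canonical
    frame, rigidly moved into camera coordinates by ``pose``, then perturbed
    by isotropic Gaussian noise of standard deviation ``noise_sd``.  The
    annotated anchor point is transformed exactly (it is an annotation, not
    a measurement).  The returned scan carries the ground-truth object frame
    for testing.
    """
    if n_points < 10:
        raise ValueError("n_points must be >= 10 per patch")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    # Seat surface: horizontal rectangle at z = seat_height.
    xs = rng.uniform(-spec.seat_depth / 2, spec.seat_depth / 2, n_points)
    ys = rng.uniform(-spec.seat_width / 2, spec.seat_width / 2, n_points)
    surface = np.column_stack([xs, ys, np.full(n_points, spec.seat_height)])

    # Backrest (chair/sofa) or side frame (bed): a planar patch behind the
    # sitting area, reclined by _RECLINE from vertical.
    c_ref = np.array([-spec.seat_depth / 2 - 0.02, 0.0, spec.seat_height + 0.25])
    u_width = np.array([0.0, 1.0, 0.0])
    u_up = np.array([-np.sin(_RECLINE), 0.0, np.cos(_RECLINE)])
    s = rng.uniform(-spec.seat_width / 2, spec.seat_width / 2, n_points)
    t = rng.uniform(0.0, 0.45, n_points)
    reference = c_ref + s[:, None] * u_width + t[:, None] * u_up

    surface_cam = pose.apply(surface)
    reference_cam = pose.apply(reference)
    if noise_sd > 0:
        surface_cam = surface_cam + rng.normal(0.0, noise_sd, surface_cam.shape)
        reference_cam = reference_cam + rng.normal(0.0, noise_sd, reference_cam.shape)

    return SeatScan(
        surface_points=surface_cam,
        reference_points=reference_cam,
        anchor_point=pose.apply(spec.anchor),
        seat_type=spec.seat_type,
        true_frame=_true_frame_in_camera(spec, pose),
    )


def _key_poses(arch: ArchetypeSpec, seat: SeatSpec) -> NDArray[np.float64]:
    """The three key poses (seated, transition, standing) as a 3 x 13 x 3 array
    in the seat's canonical frame."""
    h = seat.seat_height
    anchor = seat.anchor
    if arch.hand_target == "armrest_anchor":
        y0 = anchor[1] - 0.25  # sit next to the armrest
    else:
        y0 = 0.0  # sit at the seat center
    half_sh, half_pelv, half_leg = 0.18, 0.12, 0.12

    def pose_dict() -> dict[str, NDArray[np.float64]]:
        return {}

    keys = []

    # --- seated ---
    p = pose_dict()
    pelvis = np.array([-0.05, y0, h + 0.06])
    sh_c = pelvis + np.array([_TORSO_LEN * np.sin(0.10), 0.0, _TORSO_LEN * np.cos(0.10)])
    p["center_pelvis"] = pelvis
    p["left_pelvis"] = pelvis + [0, half_pelv, 0]
    p["right_pelvis"] = pelvis - [0, half_pelv, 0]
    p["left_shoulder"] = sh_c + [0, half_sh, 0]
    p["right_shoulder"] = sh_c - [0, half_sh, 0]
    p["left_knee"] = np.array([0.33, y0 + half_leg, h + 0.05])
    p["right_knee"] = np.array([0.33, y0 - half_leg, h + 0.05])
    p["left_ankle"] = np.array([0.30, y0 + half_leg, 0.07])
    p["right_ankle"] = np.array([0.30, y0 - half_leg, 0.07])
    p["left_wrist"] = np.array([0.15, y0 + 0.16, h + 0.10])
    p["right_wrist"] = np.array([0.15, y0 - 0.16, h + 0.10])
    p["left_elbow"] = (p["left_shoulder"] + p["left_wrist"]) / 2 + [0, 0.04, 0]
    p["right_elbow"] = (p["right_shoulder"] + p["right_wrist"]) / 2 - [0, 0.04, 0]
    keys.append(p)
    seated_sh_c = sh_c

    # --- transition: trunk pitched forward, hands on the support ---
    p = pose_dict()
    pelvis = np.array([0.08, y0, h + 0.22])
    sh_c = np.array(
        [
            seated_sh_c[0] + arch.shoulder_forward_excursion,
            y0,
            pelvis[2] + _TORSO_LEN * np.cos(arch.trunk_pitch_peak),
        ]
    )
    p["center_pelvis"] = pelvis
    p["left_pelvis"] = pelvis + [0, half_pelv, 0]
    p["right_pelvis"] = pelvis - [0, half_pelv, 0]
    p["left_shoulder"] = sh_c + [0, half_sh, 0]
    p["right_shoulder"] = sh_c - [0, half_sh, 0]
    p["left_knee"] = np.array([0.30, y0 + half_leg, h + 0.04])
    p["right_knee"] = np.array([0.30, y0 - half_leg, h + 0.04])
    p["left_ankle"] = np.array([0.30, y0 + half_leg, 0.07])
    p["right_ankle"] = np.array([0.30, y0 - half_leg, 0.07])
    if arch.hand_target == "armrest_anchor":
        # Left hand (armrest side) pushes at the armrest base; right hand
        # pushes on the seat surface.
        p["left_wrist"] = anchor.copy()
        p["right_wrist"] = np.array([0.05, y0 - 0.18, h + 0.02])
    else:
        p["left_wrist"] = p["left_knee"] + [0.02, 0, 0.05]
        p["right_wrist"] = p["right_knee"] + [0.02, 0, 0.05]
    p["left_elbow"] = (p["left_shoulder"] + p["left_wrist"]) / 2 + [0, 0.04, 0]
    p["right_elbow"] = (p["right_shoulder"] + p["right_wrist"]) / 2 - [0, 0.04, 0]
    keys.append(p)

    # --- standing ---
    p = pose_dict()
    pelvis = np.array([0.18, y0, 0.92])
    sh_c = pelvis + np.array([0.0, 0.0, _TORSO_LEN])
    p["center_pelvis"] = pelvis
    p["left_pelvis"] = pelvis + [0, half_pelv, 0]
    p["right_pelvis"] = pelvis - [0, half_pelv, 0]
    p["left_shoulder"] = sh_c + [0, half_sh, 0]
    p["right_shoulder"] = sh_c - [0, half_sh, 0]
    p["left_knee"] = np.array([0.28, y0 + half_leg, 0.50])
    p["right_knee"] = np.array([0.28, y0 - half_leg, 0.50])
    p["left_ankle"] = np.array([0.30, y0 + half_leg, 0.07])
    p["right_ankle"] = np.array([0.30, y0 - half_leg, 0.07])
    p["left_wrist"] = np.array([0.20, y0 + 0.20, 0.85])
    p["right_wrist"] = np.array([0.20, y0 - 0.20, 0.85])
    p["left_elbow"] = (p["left_shoulder"] + p["left_wrist"]) / 2 + [0, 0.04, 0]
    p["right_elbow"] = (p["right_shoulder"] + p["right_wrist"]) / 2 - [0, 0.04, 0]
    keys.append(p)

    return np.stack(
        [np.stack([k[j] for j in CANONICAL_JOINTS]) for k in keys]
    )  # 3 x 13 x 3


def generate_standing_behavior(
    arch: ArchetypeSpec, seat: SeatSpec, pose: CameraPose
) -> SkeletonSequence:
    """Render one synthetic sit-to-stand trial in camera coordinates.

    The three key poses are placed at normalized times 0, 0.5 and 1 and each
    joint coordinate is interpolated by a natural cubic spline, sampled at
    ``duration_frames`` equispaced times.  Gaussian jitter of sd
    ``arch.noise_sd`` is added in the canonical frame (see module docstring),
    then the whole sequence is rigidly moved by ``pose``.  The ground-truth
    object-frame trajectory (jitter included) is stored on the result.
    """
    keys = _key_poses(arch, seat)  # 3 x 13 x 3
    T = arch.duration_frames
    u = np.linspace(0.0, 1.0, T)
    spline = CubicSpline([0.0, 0.5, 1.0], keys, axis=0, bc_type="natural")
    canonical = spline(u)  # T x 13 x 3
    if arch.noise_sd > 0:
        rng = np.random.default_rng(arch.seed)
        canonical = canonical + rng.normal(0.0, arch.noise_sd, canonical.shape)

    trial = SkeletonSequence(
        trial_id=f"{arch.archetype}_{arch.seed}",
        frames=pose.apply(canonical),
        coordinate_frame="camera",
        true_object_frames=canonical - seat.anchor,
        archetype=arch.archetype,
    )
    return trial


# ---------------------------------------------------------------------------
# The 24-trial reference library
# ---------------------------------------------------------------------------

#: Trial roster of the study: (trial_id, participant_id, sex, BI, MMSE, product).
TABLE1_ROWS: tuple[tuple[str, str, str, int, int, str], ...] = (
    ("no9_1", "no9", "M", 55, 22, "nursing_bed"),
    ("no9_2", "no9", "M", 55, 22, "nursing_bed"),
    ("no9_3", "no9", "M", 55, 22, "nursing_bed"),
    ("no9_4", "no9", "M", 55, 22, "nursing_bed"),
    ("no9_5", "no9", "M", 55, 22, "nursing_bed"),
    ("no29_1", "no29", "F", 85, 19, "chair"),
    ("no29_2", "no29", "F", 85, 19, "chair"),
    ("no29_3", "no29", "F", 85, 19, "chair"),
    ("no29_4", "no29", "F", 85, 19, "chair"),
    ("no30_1", "no30", "M", 80, 24, "sofa"),
    ("no30_2", "no30", "M", 80, 24, "sofa"),
    ("no30_3", "no30", "M", 80, 24, "chair"),
    ("no30_4", "no30", "M", 80, 24, "sofa"),
    ("no31_1", "no31", "F", 55, 6, "chair"),
    ("no31_2", "no31", "F", 55, 6, "sofa"),
    ("no31_3", "no31", "F", 55, 6, "chair"),
    ("no31_4", "no31", "F", 55, 6, "sofa"),
    ("no32_1", "no32", "M", 55, 17, "sofa"),
    ("no32_2", "no32", "M", 55, 17, "sofa"),
    ("no32_3", "no32", "M", 55, 17, "sofa"),
    ("no33_1", "no33", "F", 55, 15, "sofa"),
    ("no33_2", "no33", "F", 55, 15, "chair"),
    ("no33_3", "no33", "F", 55, 15, "sofa"),
    ("no33_4", "no33", "F", 55, 15, "sofa"),
)

#: The two trials known to stand without using the armrest.
FORWARD_LEAN_TRIALS: tuple[str, str] = ("no31_4", "no32_2")


@dataclass
class SyntheticTrial:
    """One generated trial: skeleton sequence plus the seat scan it used."""

    sequence: SkeletonSequence
    scan: SeatScan
    seat_spec: SeatSpec = field(repr=False, default=None)
    pose: CameraPose = field(repr=False, default=None)


def elderly_library(
    seed: int,
    behavior_noise_sd: float = 0.01,
    scan_noise_sd: float = 0.005,
    scan_points: int = 400,
) -> tuple[list[SyntheticTrial], pd.DataFrame]:
    """Generate the 24-trial synthetic reference library.

    Seat types, participant IDs, sex, Barthel Index and MMSE copy the study
    roster verbatim; trials ``no31_4`` and ``no32_2`` carry the forward-lean
    archetype and the remaining 22 the armrest-assisted archetype.  Camera
    pose and duration (uniform 60-150 frames, i.e. 2-5 s at the depth
    camera's ~30 fps) are randomized per trial from ``seed``.

    Returns the list of trials and the metadata table with columns
    ``trial_id, participant_id, sex, BI, MMSE, product``.
    """
    rng = np.random.default_rng(seed)
    trials: list[SyntheticTrial] = []
    for trial_id, pid, sex, bi, mmse, product in TABLE1_ROWS:
        behavior_seed = int(rng.integers(0, 2**31 - 1))
        scan_seed = int(rng.integers(0, 2**31 - 1))
        pose_seed = int(rng.integers(0, 2**31 - 1))
        duration = int(rng.integers(60, 151))

        seat = seat_defaults(product)
        pose = CameraPose.random_overhead(pose_seed)
        archetype = (
            "forward_lean" if trial_id in FORWARD_LEAN_TRIALS else "armrest_assisted"
        )
        arch = archetype_defaults(
            archetype,
            duration_frames=duration,
            noise_sd=behavior_noise_sd,
            seed=behavior_seed,
        )
        seq = generate_standing_behavior(arch, seat, pose)
        seq.trial_id = trial_id
        scan = generate_seat_scan(
            seat, pose, noise_sd=scan_noise_sd, n_points=scan_points, seed=scan_seed
        )
        trials.append(SyntheticTrial(sequence=seq, scan=scan, seat_spec=seat, pose=pose))

    metadata = pd.DataFrame(
        TABLE1_ROWS,
        columns=["trial_id", "participant_id", "sex", "BI", "MMSE", "product"],
    )
    return trials, metadata
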