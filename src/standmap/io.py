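"""File formats: skeleton CSV, ascii PLY point clouds, metadata TSV, JSON.

All formats are plain text, UTF-8, '.' decimal, units meters (declared in a
``# units: m`` comment where the format allows comments).  Every writer has
a matching reader and round-trips exactly (floats are serialized with
``repr``-level precision, which Python parses back bit-identically).

PLY files are written as ascii with ``double`` vertex properties; common
mesh libraries export ascii PLY at float32 precision, which would break the
exact round-trip this pipeline's audit trail relies on, so the (tiny)
reader/writer pair lives here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from numpy.typing import NDArray

from .metrics import BehaviorDistanceMatrix, ResampledSequence
from .object_frame import CANONICAL_JOINTS, ObjectFrame, SeatScan, SkeletonSequence

__all__ = [
    "TrialMetadata",
    "read_skeleton_csv",
    "write_skeleton_csv",
    "read_point_cloud",
    "write_point_cloud",
    "read_seat_scan",
    "write_seat_scan",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "write_object_frame_json",
    "read_object_frame_json",
    "write_distance_matrix_csv",
    "read_distance_matrix_csv",
]

_UNITS_LINE = "# units: m"

SEX_VALUES = ("M", "F")


@dataclass(frozen=True)
class TrialMetadata:
    """One roster row: who performed the trial, on which seat, with which
    Barthel Index (0-100, physical ability) and MMSE (0-30, cognition)."""

    trial_id: str
    participant_id: str
    sex: str
    BI: int
    MMSE: int
    product: str

    def __post_init__(self) -> None:
        if self.sex not in SEX_VALUES:
            raise ValueError(f"sex must be one of {SEX_VALUES}")
        if not 0 <= self.BI <= 100:
            raise ValueError("BI must be in [0, 100]")
        if not 0 <= self.MMSE <= 30:
            raise ValueError("MMSE must be in [0, 30]")


# ---------------------------------------------------------------------------
# Skeleton CSV: columns trial_id, frame, joint, x, y, z; frame is 1-based.
# ---------------------------------------------------------------------------


def write_skeleton_csv(
    seq: SkeletonSequence | ResampledSequence, path: str | Path
) -> None:
    """Write a sequence in long form (one row per frame per joint)."""
    frames = seq.frames
    T = frames.shape[0]
    rows = {
        "trial_id": np.repeat(seq.trial_id, T * 13),
        "frame": np.repeat(np.arange(1, T + 1), 13),
        "joint": np.tile(np.array(CANONICAL_JOINTS), T),
        "x": frames[:, :, 0].ravel(),
        "y": frames[:, :, 1].ravel(),
        "z": frames[:, :, 2].ravel(),
    }
    df = pd.DataFrame(rows)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_UNITS_LINE + "\n")
        # %.17g round-trips any float64 bit-exactly
        df.to_csv(fh, index=False, float_format="%.17g")


def read_skeleton_csv(path: str | Path, coordinate_frame: str = "camera") -> SkeletonSequence:
    """Read and validate a skeleton CSV.

    Enforces the canonical 13-joint set, contiguous 1-based frames and
    finite coordinates, each with a distinct error message.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"trial_id", "frame", "joint", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"skeleton CSV missing columns {sorted(required - set(df.columns))}")
    trial_ids = df["trial_id"].unique()
    if len(trial_ids) != 1:
        raise ValueError("skeleton CSV must contain exactly one trial")
    joints = set(df["joint"].unique())
    unknown = joints - set(CANONICAL_JOINTS)
    if unknown:
        raise ValueError(f"unknown joint name(s): {sorted(unknown)}")
    absent = set(CANONICAL_JOINTS) - joints
    if absent:
        raise ValueError(f"missing joint(s): {sorted(absent)}")
    bad = df[["x", "y", "z"]].apply(lambda c: ~np.isfinite(c)).any(axis=1)
    if bad.any():
        # +2 -> 1-based line number after the units comment and header.
        rows = (df.index[bad] + 3).tolist()
        raise ValueError(f"non-finite coordinate(s) at file row(s) {rows}")
    frames_idx = np.sort(df["frame"].unique())
    T = len(frames_idx)
    if not np.array_equal(frames_idx, np.arange(1, T + 1)):
        raise ValueError("frame numbers must be contiguous and 1-based")

    df = df.sort_values(["frame", "joint"], key=_joint_sort_key)
    coords = df[["x", "y", "z"]].to_numpy(dtype=float).reshape(T, 13, 3)
    return SkeletonSequence(
        trial_id=str(trial_ids[0]), frames=coords, coordinate_frame=coordinate_frame
    )


def _joint_sort_key(col: pd.Series) -> pd.Series:
    if col.name == "joint":
        order = {j: i for i, j in enumerate(CANONICAL_JOINTS)}
        return col.map(order)
    return col


# ---------------------------------------------------------------------------
# Ascii PLY point clouds (double precision x, y, z)
# ---------------------------------------------------------------------------


def write_point_cloud(points: NDArray[np.float64], path: str | Path) -> None:
    """Write an N x 3 point cloud as an ascii PLY with double properties."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be N x 3")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("ply\nformat ascii 1.0\ncomment units: m\n")
        fh.write(f"element vertex {len(pts)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write("end_header\n")
        for p in pts:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")


def read_point_cloud(path: str | Path) -> NDArray[np.float64]:
    """Read an ascii PLY (x, y, z vertex properties) or an x,y,z CSV."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        if not {"x", "y", "z"}.issubset(df.columns):
            raise ValueError("point-cloud CSV needs columns x, y, z")
        return df[["x", "y", "z"]].to_numpy(dtype=float)

    with open(path, encoding="utf-8") as fh:
        if fh.readline().strip() != "ply":
            raise ValueError("not a PLY file")
        n_vertex = None
        props: list[str] = []
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "format" and tok[1] != "ascii":
                raise ValueError("only ascii PLY is supported")
            if tok[0] == "element" and tok[1] == "vertex":
                n_vertex = int(tok[2])
            elif tok[0] == "property" and n_vertex is not None:
                props.append(tok[2])
            elif tok[0] == "end_header":
                break
        if n_vertex is None:
            raise ValueError("PLY has no vertex element")
        try:
            cols = [props.index(c) for c in ("x", "y", "z")]
        except ValueError as exc:
            raise ValueError("PLY vertex element lacks x/y/z properties") from exc
        data = np.loadtxt(fh, dtype=float, max_rows=n_vertex, ndmin=2)
        if data.shape[0] != n_vertex:
            raise ValueError("PLY vertex count mismatch")
        return data[:, cols]


# ---------------------------------------------------------------------------
# Seat scan = two point-cloud files + a YAML sidecar with roles and anchor
# ---------------------------------------------------------------------------


def write_seat_scan(scan: SeatScan, directory: str | Path, stem: str = "seat") -> Path:
    """Write a scan as ``<stem>_surface.ply``, ``<stem>_reference.ply`` and a
    ``<stem>.yaml`` sidecar; returns the sidecar path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    surface = f"{stem}_surface.ply"
    reference = f"{stem}_reference.ply"
    write_point_cloud(scan.surface_points, directory / surface)
    write_point_cloud(scan.reference_points, directory / reference)
    sidecar = {
        "seat_type": scan.seat_type,
        "units": "m",
        "surface": surface,
        "reference": reference,
        "anchor_point": [float(v) for v in scan.anchor_point],
    }
    sidecar_path = directory / f"{stem}.yaml"
    with open(sidecar_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
    return sidecar_path


def read_seat_scan(sidecar_path: str | Path) -> SeatScan:
    """Read a scan from its YAML sidecar (which names the patch files)."""
    sidecar_path = Path(sidecar_path)
    with open(sidecar_path, encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    for key in ("surface", "reference", "seat_type"):
        if key not in meta:
            raise ValueError(f"seat sidecar missing {key!r}")
    if "anchor_point" not in meta:
        raise ValueError("seat sidecar missing the annotated anchor_point")
    base = sidecar_path.parent
    return SeatScan(
        surface_points=read_point_cloud(base / meta["surface"]),
        reference_points=read_point_cloud(base / meta["reference"]),
        anchor_point=np.asarray(meta["anchor_point"], dtype=float),
        seat_type=meta["seat_type"],
    )


# ---------------------------------------------------------------------------
# Metadata TSV
# ---------------------------------------------------------------------------

_META_COLUMNS = ["trial_id", "participant_id", "sex", "BI", "MMSE", "product"]


def write_metadata_tsv(metadata: pd.DataFrame, path: str | Path) -> None:
    missing = set(_META_COLUMNS) - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing columns {sorted(missing)}")
    metadata[_META_COLUMNS].to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns {sorted(missing)}")
    if df["trial_id"].duplicated().any():
        raise ValueError("duplicate trial_id in metadata")
    for row in df.itertuples(index=False):
        TrialMetadata(
            trial_id=str(row.trial_id),
            participant_id=str(row.participant_id),
            sex=str(row.sex),
            BI=int(row.BI),
            MMSE=int(row.MMSE),
            product=str(row.product),
        )
    return df


# ---------------------------------------------------------------------------
# Object frame JSON and matrix CSV
# ---------------------------------------------------------------------------


def write_object_frame_json(frame: ObjectFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(frame.to_dict(), fh, indent=1)


def read_object_frame_json(path: str | Path) -> ObjectFrame:
    with open(path, encoding="utf-8") as fh:
        return ObjectFrame.from_dict(json.load(fh))


def write_distance_matrix_csv(
    D: BehaviorDistanceMatrix, path: str | Path, joint: str | None = None
) -> None:
    M = D.total if joint is None else D.joint_matrix(joint)
    pd.DataFrame(M, index=D.trial_ids, columns=D.trial_ids).to_csv(
        path, float_format="%.17g"
    )


def read_distance_matrix_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise ValueError("distance matrix rows and columns disagree")
    return df
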