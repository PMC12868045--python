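"""Skeleton data model, coordinate conventions, and trial file I/O.

A trial is a uniformly sampled time series of 3-D positions (meters) of 12
tracked joints, expressed in an anatomical body frame:

* ``x`` — sagittal axis, pointing forwards;
* ``y`` — vertical axis, pointing upwards;
* ``z`` — transverse axis, pointing to the participant's right.

Raw camera coordinates from a markerless sensor must be brought into this
frame with :func:`to_body_frame` (a rigid rotation + translation, supplied as
a ``calibration`` block in the trial manifest) before any kinematic analysis:
the joint-angle definitions assume anatomical axes.

On disk a trial is a plain CSV (one row per frame, columns
``t, head_x, head_y, head_z, ..., hand_R_z``) plus a small JSON manifest with
the sampling rate, assessed side, movement type and optional clinical score.
Missing joint samples (tracking dropouts) are empty CSV cells and become NaN
positions, to be repaired by :func:`kinassess.preprocessing.interpolate_gaps`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGeometryError,
    FormatError,
    ValidationError,
)

#: The 12 tracked joints, in canonical column order.
JOINTS: tuple[str, ...] = (
    "head",
    "spine_shoulder",
    "spine_mid",
    "spine_base",
    "shoulder_L",
    "shoulder_R",
    "elbow_L",
    "elbow_R",
    "wrist_L",
    "wrist_R",
    "hand_L",
    "hand_R",
)

JOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(JOINTS)}

MOVEMENTS = ("RCH", "HTM")
SIDES = ("left", "right")

#: Fixed body-frame axes.
U_X = np.array([1.0, 0.0, 0.0])
U_Y = np.array([0.0, 1.0, 0.0])
U_Z = np.array([0.0, 0.0, 1.0])

#: Tolerated deviation of the frame spacing from 1/fs, in seconds.
_SPACING_TOL_S = 1e-3


def csv_columns() -> list[str]:
    """Canonical trial CSV header."""
    cols = ["t"]
    for j in JOINTS:
        cols += [f"{j}_x", f"{j}_y", f"{j}_z"]
    return cols


@dataclass
class SkeletonFrame:
    """A single time-stamped skeleton sample.

    ``positions`` maps joint name to a 3-vector in meters; a joint lost by
    the tracker holds NaN coordinates.
    """

    t: float
    positions: dict[str, np.ndarray]

    def is_missing(self, joint: str) -> bool:
        return bool(np.isnan(self.positions[joint]).any())


class SkeletonSequence:
    """An ordered, uniformly sampled sequence of skeleton frames.

    Parameters
    ----------
    t:
        Timestamps in seconds, strictly increasing, spaced 1/fs within 1 ms.
    positions:
        Array of shape ``(n_frames, 12, 3)``, meters, joint order ``JOINTS``.
        NaN marks a missing (dropped) joint sample.
    fs:
        Sampling rate in Hz.
    side:
        Assessed limb, ``"left"`` or ``"right"``.
    movement:
        Movement type, ``"RCH"`` (reaching) or ``"HTM"`` (hand-to-mouth).
    fm_score:
        Optional Fugl-Meyer upper-limb score (integer 0-66) of the subject.
    """

    def __init__(
        self,
        t: np.ndarray,
        positions: np.ndarray,
        fs: float,
        side: str,
        movement: str,
        subject_id: str = "",
        fm_score: Optional[int] = None,
        validate: bool = True,
    ) -> None:
        self.t = np.asarray(t, dtype=float)
        self.positions = np.asarray(positions, dtype=float)
        self.fs = float(fs)
        self.side = side
        self.movement = movement
        self.subject_id = subject_id
        self.fm_score = fm_score
        if validate:
            self._validate()

    def _validate(self) -> None:
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.movement not in MOVEMENTS:
            raise ValidationError(
                f"unknown movement tag {self.movement!r}; expected one of {MOVEMENTS}"
            )
        if self.side not in SIDES:
            raise ValidationError(f"unknown side {self.side!r}; expected one of {SIDES}")
        if self.fm_score is not None and not (0 <= int(self.fm_score) <= 66):
            raise ValidationError(f"FM score must be in 0..66, got {self.fm_score}")
        if self.t.ndim != 1 or self.positions.shape != (len(self.t), len(JOINTS), 3):
            raise ValidationError(
                f"positions must have shape (n, {len(JOINTS)}, 3) matching t; "
                f"got {self.positions.shape} for n={len(self.t)}"
            )
        if len(self.t) == 0:
            raise ValidationError("empty sequence")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValidationError("timestamps must be strictly increasing")
            if np.any(np.abs(dt - 1.0 / self.fs) > _SPACING_TOL_S):
                worst = float(np.max(np.abs(dt - 1.0 / self.fs)))
                raise ValidationError(
                    f"frame spacing deviates from 1/fs by up to {worst:.4g} s "
                    f"(tolerance {_SPACING_TOL_S} s)"
                )
        finite_or_nan = np.isfinite(self.positions) | np.isnan(self.positions)
        if not finite_or_nan.all():
            raise ValidationError("positions contain infinite values")

    # ------------------------------------------------------------------ views
    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Trial duration in seconds (last minus first timestamp)."""
        return float(self.t[-1] - self.t[0]) if self.n_frames > 1 else 0.0

    def joint(self, name: str) -> np.ndarray:
        """``(n_frames, 3)`` trajectory of one joint (a view)."""
        return self.positions[:, JOINT_INDEX[name], :]

    def frame(self, i: int) -> SkeletonFrame:
        return SkeletonFrame(
            t=float(self.t[i]),
            positions={j: self.positions[i, k].copy() for k, j in enumerate(JOINTS)},
        )

    def frames(self) -> Iterator[SkeletonFrame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_frames, 12)`` mask of missing joint samples."""
        return np.isnan(self.positions).any(axis=2)

    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def side_joint(self, base: str) -> str:
        """Name of an assessed-side joint, e.g. ``side_joint('wrist')``."""
        return f"{base}_{'R' if self.side == 'right' else 'L'}"

    def copy(self, positions: Optional[np.ndarray] = None) -> "SkeletonSequence":
        return SkeletonSequence(
            t=self.t.copy(),
            positions=self.positions.copy() if positions is None else positions,
            fs=self.fs,
            side=self.side,
            movement=self.movement,
            subject_id=self.subject_id,
            fm_score=self.fm_score,
            validate=False,
        )

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class SegmentVectors:
    """Per-frame unit vectors of the kinematic chain.

    ``SE`` shoulder→elbow, ``EW`` elbow→wrist, ``WH`` wrist→hand on the
    assessed side; ``SH`` right→left shoulder line (always right→left,
    independent of the assessed side); ``TR`` along the trunk (spine_base →
    spine_shoulder by default). ``u_y`` points up; ``u_z`` points to the
    assessed side (mirrored for a left-side assessment so that laterality
    angles are side-symmetric).
    """

    SE: np.ndarray
    EW: np.ndarray
    WH: np.ndarray
    SH: np.ndarray
    TR: np.ndarray
    u_y: np.ndarray = field(default_factory=lambda: U_Y.copy())
    u_z: np.ndarray = field(default_factory=lambda: U_Z.copy())


def _unit(v: np.ndarray, name: str) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-9:
        raise DegenerateGeometryError(
            f"segment {name}: joints coincide (norm {n:.3g} m before normalization)"
        )
    return v / n


def segment_vectors(
    frame: SkeletonFrame, side: str, trunk_joints: str = "spine_base"
) -> SegmentVectors:
    """Unit vectors of the assessed-side arm chain, shoulder line and trunk.

    Parameters
    ----------
    frame:
        A skeleton frame with the required joints present.
    side:
        Assessed limb, ``"left"`` or ``"right"``.
    trunk_joints:
        Lower anchor of the trunk vector: ``"spine_base"`` (default; longest
        spine segment, least noise-sensitive) or ``"spine_mid"``.
    """
    if side not in SIDES:
        raise ValidationError(f"unknown side {side!r}")
    if trunk_joints not in ("spine_base", "spine_mid"):
        raise ValidationError(f"trunk_joints must be spine_base or spine_mid, got {trunk_joints!r}")
    sfx = "R" if side == "right" else "L"
    p = frame.positions
    needed = [f"shoulder_{sfx}", f"elbow_{sfx}", f"wrist_{sfx}", f"hand_{sfx}",
              "shoulder_L", "shoulder_R", "spine_shoulder", trunk_joints]
    for j in needed:
        if np.isnan(p[j]).any():
            raise ValidationError(f"joint {j} is missing in frame at t={frame.t:.3f} s")
    se = _unit(p[f"elbow_{sfx}"] - p[f"shoulder_{sfx}"], "SE")
    ew = _unit(p[f"wrist_{sfx}"] - p[f"elbow_{sfx}"], "EW")
    wh = _unit(p[f"hand_{sfx}"] - p[f"wrist_{sfx}"], "WH")
    sh = _unit(p["shoulder_L"] - p["shoulder_R"], "SH")
    tr = _unit(p["spine_shoulder"] - p[trunk_joints], "TR")
    u_z = U_Z.copy() if side == "right" else -U_Z
    return SegmentVectors(SE=se, EW=ew, WH=wh, SH=sh, TR=tr, u_y=U_Y.copy(), u_z=u_z)


# --------------------------------------------------------------------- I/O


def _read_manifest(manifest: Path) -> dict:
    try:
        meta = json.loads(Path(manifest).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"manifest {manifest}: invalid JSON ({exc})") from exc
    for key in ("fs_hz", "side", "movement"):
        if key not in meta:
            raise FormatError(f"manifest {manifest}: missing required key {key!r}")
    return meta


def read_skeleton_csv(path: str | Path, manifest: str | Path) -> SkeletonSequence:
    """Read a trial CSV plus its JSON manifest into a :class:`SkeletonSequence`.

    If the manifest carries a ``calibration`` block (``rotation``: 9 numbers
    row-major, ``origin``: 3 numbers) the positions are transformed into the
    body frame on load.

    Raises
    ------
    FormatError
        Malformed header or missing column.
    ValidationError
        Non-monotonic timestamps, unknown movement tag, bad metadata.
    """
    path = Path(path)
    meta = _read_manifest(Path(manifest))
    df = pd.read_csv(path)
    expected = csv_columns()
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise FormatError(
            f"{path}: malformed header, missing column(s) {', '.join(missing_cols)}"
        )
    extra = [c for c in df.columns if c not in expected]
    if extra:
        raise FormatError(f"{path}: unexpected column(s) {', '.join(extra)}")
    t = df["t"].to_numpy(dtype=float)
    n = len(t)
    positions = np.empty((n, len(JOINTS), 3))
    for k, j in enumerate(JOINTS):
        for a, ax in enumerate(("x", "y", "z")):
            positions[:, k, a] = df[f"{j}_{ax}"].to_numpy(dtype=float)
    seq = SkeletonSequence(
        t=t,
        positions=positions,
        fs=float(meta["fs_hz"]),
        side=str(meta["side"]),
        movement=str(meta["movement"]),
        subject_id=str(meta.get("subject_id", "")),
        fm_score=meta.get("fm_score"),
    )
    cal = meta.get("calibration")
    if cal is not None:
        rot = np.asarray(cal["rotation"], dtype=float).reshape(3, 3)
        origin = np.asarray(cal["origin"], dtype=float)
        seq = to_body_frame(seq, rot, origin)
    return seq


def write_skeleton_csv(seq: SkeletonSequence, path: str | Path) -> Path:
    """Write a trial CSV and its sibling ``.json`` manifest; round-trip safe.

    Positions are written with full float precision so that
    ``read_skeleton_csv(write_skeleton_csv(seq))`` reproduces the sequence
    exactly (well within 1e-9 m).
    """
    if seq.n_frames == 0:
        raise ValidationError("refusing to write an empty sequence")
    path = Path(path)
    data: dict[str, np.ndarray] = {"t": seq.t}
    for k, j in enumerate(JOINTS):
        for a, ax in enumerate(("x", "y", "z")):
            data[f"{j}_{ax}"] = seq.positions[:, k, a]
    pd.DataFrame(data).to_csv(path, index=False)
    manifest = {
        "fs_hz": seq.fs,
        "side": seq.side,
        "movement": seq.movement,
        "subject_id": seq.subject_id,
        "fm_score": seq.fm_score,
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def to_body_frame(
    seq: SkeletonSequence, rotation: np.ndarray, origin: np.ndarray
) -> SkeletonSequence:
    """Apply the rigid transform ``p -> R @ (p - origin)`` to every position.

    ``rotation`` must be a proper orthonormal 3x3 matrix (det = +1).
    Metadata is preserved; missing samples stay missing.
    """
    rotation = np.asarray(rotation, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if rotation.shape != (3, 3):
        raise ValidationError(f"rotation must be 3x3, got {rotation.shape}")
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-9):
        raise ValidationError("rotation matrix is not orthonormal")
    if abs(np.linalg.det(rotation) - 1.0) > 1e-9:
        raise ValidationError("rotation matrix must be proper (det = +1)")
    shifted = seq.positions - origin[None, None, :]
    new_pos = np.einsum("ij,nkj->nki", rotation, shifted)
    return seq.copy(positions=new_pos)
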