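"""Joint angles, normalized displacements, range of motion, and smoothness.

Seven angle series are derived per frame from the unit vectors of the
kinematic chain (``SE`` shoulder→elbow, ``EW`` elbow→wrist, ``WH``
wrist→hand, ``SH`` right→left shoulder line, ``TR`` trunk) and the body axes:

* ``SF`` shoulder flexion      = acos(-u_y . SE)
* ``SA`` shoulder adduction    = acos( u_z . SE)
* ``EF`` elbow flexion         = acos( SE  . EW)
* ``WF`` wrist flexion         = acos( EW  . SH)   (``printed`` dialect)
                               = acos( EW  . WH)   (``hand_segment`` dialect)
* ``TT`` trunk torsion         = acos( u_z . TR)
* ``TF`` trunk forward tilt    = acos( u_y . TR)  restricted to the sagittal
  (x-y) plane, i.e. with TR projected onto that plane and renormalized
* ``TL`` trunk lateral tilt    = same, restricted to the frontal (z-y) plane

All dot products are clamped to [-1, 1], so every angle lies in [0°, 180°]
for any finite input. For a left-side assessment ``u_z`` is mirrored so that
the laterality angles SA and TT are side-symmetric.

The ``WF`` definition exists in two dialects because the shoulder-line form,
although it is the conventional printed one, does not involve the hand
segment at all; the ``hand_segment`` form (elbow→wrist vs. wrist→hand) is the
anatomically literal wrist angle. Both are exposed and never substituted
silently; the dialect in force is echoed in result provenance.

Joint displacements are expressed in the body axes, taken relative to the
phase onset, and normalized by limb length (mean |shoulder-elbow| + mean
|elbow-wrist|) so that participants of different stature are comparable.

Smoothness is the dimensionless normalized jerk of the endpoint trajectory

    NJ = sqrt( T^5 / (2 L^2) * integral ||d^3 p / dt^3||^2 dt )

over a movement phase of duration T and path length L. NJ is invariant under
spatial and temporal scaling and attains sqrt(360) ~= 18.97 for an ideal
straight-line minimum-jerk movement; larger values mean a less smooth path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .errors import (
    DegenerateGeometryError,
    DegenerateMovementError,
    ParameterError,
    ValidationError,
)
from .preprocessing import derivative
from .skeleton import JOINT_INDEX, SkeletonSequence

if TYPE_CHECKING:  # pragma: no cover
    from .segmentation import MovementPhase

WF_FORMULAS = ("printed", "hand_segment")

#: Angle-series names in reporting order.
ANGLE_NAMES = ("SF", "SA", "EF", "WF", "TT", "TF", "TL")


@dataclass
class AngleSeries:
    """The seven per-frame angle series, in degrees, aligned to the frames."""

    SF: np.ndarray
    SA: np.ndarray
    EF: np.ndarray
    WF: np.ndarray
    TT: np.ndarray
    TF: np.ndarray
    TL: np.ndarray
    wf_formula: str = "printed"

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in ANGLE_NAMES:
            raise KeyError(name)
        return getattr(self, name)


@dataclass
class DisplacementSeries:
    """Limb-length-normalized displacement of one joint along one body axis.

    Values are dimensionless, relative to the phase onset (the first value is
    exactly 0).
    """

    joint: str
    axis: str
    values: np.ndarray


def _unit_rows(v: np.ndarray, name: str) -> np.ndarray:
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms < 1e-9):
        i = int(np.argmin(norms))
        raise DegenerateGeometryError(
            f"segment {name}: joints coincide at frame {i} (norm {norms[i]:.3g} m)"
        )
    return v / norms[:, None]


def _acosd(dots: np.ndarray) -> np.ndarray:
    return np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))


def _plane_angle(tr: np.ndarray, keep: tuple[int, int]) -> np.ndarray:
    """Angle from vertical of TR projected onto a coordinate plane.

    ``keep`` lists the two axis indices spanning the plane (one of them must
    be the vertical axis 1). The projection is renormalized before the dot
    product with u_y.
    """
    proj = tr[:, keep]
    norms = np.linalg.norm(proj, axis=1)
    if np.any(norms < 1e-9):
        i = int(np.argmin(norms))
        raise DegenerateGeometryError(
            f"trunk vector has no component in the requested plane at frame {i}"
        )
    y_component = proj[:, keep.index(1)]
    return _acosd(y_component / norms)


def joint_angles(
    seq: SkeletonSequence,
    wf_formula: str = "printed",
    trunk_joints: str = "spine_base",
) -> AngleSeries:
    """Compute the seven angle series for a filtered, gap-free sequence."""
    if wf_formula not in WF_FORMULAS:
        raise ValidationError(f"wf_formula must be one of {WF_FORMULAS}, got {wf_formula!r}")
    if trunk_joints not in ("spine_base", "spine_mid"):
        raise ValidationError(f"trunk_joints must be spine_base or spine_mid, got {trunk_joints!r}")
    if seq.has_missing():
        raise ValidationError("sequence has missing joints; interpolate gaps first")
    p = seq.positions
    sfx = "R" if seq.side == "right" else "L"
    sh_j = p[:, JOINT_INDEX[f"shoulder_{sfx}"]]
    el = p[:, JOINT_INDEX[f"elbow_{sfx}"]]
    wr = p[:, JOINT_INDEX[f"wrist_{sfx}"]]
    ha = p[:, JOINT_INDEX[f"hand_{sfx}"]]
    se = _unit_rows(el - sh_j, "SE")
    ew = _unit_rows(wr - el, "EW")
    sh = _unit_rows(p[:, JOINT_INDEX["shoulder_L"]] - p[:, JOINT_INDEX["shoulder_R"]], "SH")
    tr = _unit_rows(p[:, JOINT_INDEX["spine_shoulder"]] - p[:, JOINT_INDEX[trunk_joints]], "TR")
    sz = 1.0 if seq.side == "right" else -1.0

    sf = _acosd(-se[:, 1])
    sa = _acosd(sz * se[:, 2])
    ef = _acosd(np.sum(se * ew, axis=1))
    if wf_formula == "printed":
        wf = _acosd(np.sum(ew * sh, axis=1))
    else:
        wh = _unit_rows(ha - wr, "WH")
        wf = _acosd(np.sum(ew * wh, axis=1))
    tt = _acosd(sz * tr[:, 2])
    tf = _plane_angle(tr, (0, 1))
    tl = _plane_angle(tr, (1, 2))
    return AngleSeries(SF=sf, SA=sa, EF=ef, WF=wf, TT=tt, TF=tf, TL=tl, wf_formula=wf_formula)


def sagittal_shoulder_flexion(seq: SkeletonSequence) -> np.ndarray:
    """Shoulder flexion restricted to the sagittal plane, in degrees.

    The shoulder→elbow vector is projected onto the sagittal (x-y) plane and
    renormalized before the angle with the downward vertical is taken. Used
    as the phase-segmentation reference for reaching movements.
    """
    if seq.has_missing():
        raise ValidationError("sequence has missing joints; interpolate gaps first")
    sfx = "R" if seq.side == "right" else "L"
    se = _unit_rows(
        seq.joint(f"elbow_{sfx}") - seq.joint(f"shoulder_{sfx}"), "SE"
    )
    proj = se[:, :2]
    norms = np.linalg.norm(proj, axis=1)
    if np.any(norms < 1e-9):
        i = int(np.argmin(norms))
        raise DegenerateGeometryError(
            f"upper arm is orthogonal to the sagittal plane at frame {i}"
        )
    return _acosd(-proj[:, 1] / norms)


def shoulder_line_torsion(seq: SkeletonSequence) -> np.ndarray:
    """Alternative torsion measure: shoulder-line angle in the transverse plane.

    Angle (degrees) between the right→left shoulder line projected onto the
    transverse (x-z) plane and the leftward horizontal. Unlike ``TT`` (which
    measures trunk obliquity relative to the lateral axis) this responds to
    axial rotation of the shoulder girdle. Provided under its own name; it is
    never substituted for ``TT``.
    """
    if seq.has_missing():
        raise ValidationError("sequence has missing joints; interpolate gaps first")
    sh = _unit_rows(seq.joint("shoulder_L") - seq.joint("shoulder_R"), "SH")
    proj = sh[:, [0, 2]]
    norms = np.linalg.norm(proj, axis=1)
    if np.any(norms < 1e-9):
        i = int(np.argmin(norms))
        raise DegenerateGeometryError(f"shoulder line is vertical at frame {i}")
    # leftward horizontal is -z
    return _acosd(-proj[:, 1] / norms)


def limb_length(seq: SkeletonSequence) -> float:
    """Upper-limb length: mean |shoulder-elbow| + mean |elbow-wrist|, meters."""
    sfx = "R" if seq.side == "right" else "L"
    upper = np.linalg.norm(seq.joint(f"elbow_{sfx}") - seq.joint(f"shoulder_{sfx}"), axis=1)
    fore = np.linalg.norm(seq.joint(f"wrist_{sfx}") - seq.joint(f"elbow_{sfx}"), axis=1)
    if np.any(np.isnan(upper)) or np.any(np.isnan(fore)):
        raise ValidationError("assessed-side shoulder/elbow/wrist have missing samples")
    if np.mean(upper) < 1e-9 or np.mean(fore) < 1e-9:
        raise DegenerateGeometryError("zero-length arm segment")
    return float(np.mean(upper) + np.mean(fore))


def displacement_series(
    seq: SkeletonSequence,
    joint: str,
    axis: str,
    phase: "MovementPhase",
    L: float,
) -> DisplacementSeries:
    """Normalized displacement of ``joint`` along ``axis`` over a phase.

    ``values[i] = (p(joint, axis, onset + i) - p(joint, axis, onset)) / L``.
    The sign is kept (forward and up are positive); range-of-motion extraction
    removes it later.
    """
    if L <= 0:
        raise ParameterError(f"limb length must be positive, got {L}")
    if axis not in ("x", "y"):
        raise ValidationError(f"axis must be 'x' or 'y', got {axis!r}")
    if joint not in JOINT_INDEX:
        raise ValidationError(f"unknown joint {joint!r}")
    if phase.onset_idx < 0 or phase.offset_idx >= seq.n_frames:
        raise ValidationError("phase lies outside the sequence")
    a = {"x": 0, "y": 1}[axis]
    track = seq.positions[phase.onset_idx : phase.offset_idx + 1, JOINT_INDEX[joint], a]
    values = (track - track[0]) / L
    return DisplacementSeries(joint=joint, axis=axis, values=values)


def rom(series: np.ndarray, phase: "MovementPhase") -> float:
    """Range of motion: max - min of the series over [onset, offset]."""
    series = np.asarray(series, dtype=float)
    if phase.onset_idx < 0 or phase.offset_idx >= len(series) or phase.onset_idx > phase.offset_idx:
        raise ValidationError(
            f"phase [{phase.onset_idx}, {phase.offset_idx}] is empty or outside the series"
        )
    window = series[phase.onset_idx : phase.offset_idx + 1]
    return float(np.max(window) - np.min(window))


def normalized_jerk(trajectory: np.ndarray, phase: "MovementPhase", fs: float) -> float:
    """Dimensionless normalized jerk of a 3-D trajectory over a phase.

    The third derivative is taken by repeated central differences on the full
    trajectory (so that phase-interior samples are unaffected by trajectory
    edges), and the squared jerk magnitude is integrated over the phase with
    the trapezoid rule. ``L`` is the path length of the trajectory within the
    phase.

    Raises
    ------
    DegenerateMovementError
        If the path length within the phase is below 1e-6 m.
    """
    trajectory = np.asarray(trajectory, dtype=float)
    if trajectory.ndim != 2 or trajectory.shape[1] != 3:
        raise ValidationError(f"trajectory must be (n, 3), got {trajectory.shape}")
    if fs <= 0:
        raise ParameterError(f"fs must be positive, got {fs}")
    if phase.onset_idx < 0 or phase.offset_idx >= len(trajectory):
        raise ValidationError("phase lies outside the trajectory")
    sl = slice(phase.onset_idx, phase.offset_idx + 1)
    T = (phase.offset_idx - phase.onset_idx) / fs
    if T <= 0:
        raise ValidationError("phase duration must be positive")
    path = trajectory[sl]
    L = float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))
    if L < 1e-6:
        raise DegenerateMovementError(
            f"path length {L:.3g} m within the phase is too small for a smoothness measure"
        )
    jerk = np.column_stack([derivative(trajectory[:, a], fs, order=3) for a in range(3)])
    jerk_sq = np.sum(jerk[sl] ** 2, axis=1)
    integral = float(np.trapezoid(jerk_sq, dx=1.0 / fs))
    return float(np.sqrt(T**5 / (2.0 * L**2) * integral))
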