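"""Synthetic seated reaching / hand-to-mouth trials with controllable deficits.

No public recordings exist for this assessment, so validation rests on a
forward-kinematics generator that scripts a seated skeleton through RCH
(reaching) and HTM (hand-to-mouth) movements with known ground truth:

* joint-angle excursions (shoulder flexion/adduction, elbow flexion, wrist
  flexion) follow minimum-jerk profiles reaching exact target ranges;
* compensatory degrees of freedom (head forward/vertical displacement, trunk
  forward/lateral tilt, shoulder-girdle torsion) are co-articulated
  minimum-jerk profiles of the requested amplitudes;
* smoothness is degraded by superimposing ``submovement_count`` overlapping
  minimum-jerk sub-movements (1 = ideally smooth), which monotonically
  increases the measured normalized jerk;
* isotropic Gaussian position noise emulates markerless sensor jitter.

Group presets target the published group means of a post-stroke cohort
stratified by Fugl-Meyer severity, for both movements; per-subject sampling
adds between-subject variability using the published SDs (parameters are
drawn independently — real inter-parameter couplings are not recoverable
from group summaries).

Construction notes: arm angles drive the segment *orientations* directly, so
the assessment pipeline recovers the targeted angle ROMs exactly in the
noiseless limit. The head trajectory is driven directly (not through the
neck chain), so head-compensation amplitudes are independent of the trunk
tilt — anatomically a simplification, deliberately accepted to keep every
target independently controllable. The torsion amplitude rotates the
shoulder girdle about the trunk axis; note that the reported ``TT`` angle
(trunk obliquity to the lateral axis) does not respond to it, but tracks the
lateral tilt instead. Wrist targets drive the anatomical (hand-segment)
wrist angle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np

from .errors import ParameterError, ValidationError
from .skeleton import JOINT_INDEX, JOINTS, SkeletonSequence

__all__ = [
    "ChainGeometry",
    "ImpairmentProfile",
    "min_jerk_profile",
    "submovement_profile",
    "simulate_trial",
    "group_preset",
    "sample_subject_profile",
    "simulate_cohort",
    "PRESET_MEANS",
    "PRESET_SDS",
]


@dataclass(frozen=True)
class ChainGeometry:
    """Segment lengths (meters) of the simulated seated skeleton."""

    upper_arm: float = 0.30
    forearm: float = 0.25
    hand: float = 0.08
    trunk: float = 0.50
    shoulder_width: float = 0.36
    neck: float = 0.15

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v <= 0:
                raise ValidationError(f"segment length {name} must be positive, got {v}")


@dataclass(frozen=True)
class ImpairmentProfile:
    """Ground-truth targets of one simulated trial.

    Angle targets (degrees) are the ranges of motion the movement sweeps;
    ``hf``/``hv`` are head-displacement amplitudes in limb-length-normalized
    units; ``tf``/``tl``/``tt`` are trunk forward-tilt / lateral-tilt /
    torsion amplitudes in degrees. ``submovement_count`` >= 1 controls
    smoothness degradation; ``noise_sd`` is the per-coordinate sensor noise
    in meters. ``duration`` is the movement time; ``rest_s`` of quiet sitting
    pads both ends of the trial.
    """

    movement: str
    rom_sf: float
    rom_sa: float
    rom_ef: float
    rom_wf: float = 10.0
    hf: float = 0.0
    hv: float = 0.0
    tf: float = 0.0
    tl: float = 0.0
    tt: float = 0.0
    duration: float = 2.0
    submovement_count: int = 1
    noise_sd: float = 0.0
    fs: float = 30.0
    rest_s: float = 0.5


# --------------------------------------------------------------- profiles


def min_jerk_profile(start: float, end: float, T: float, fs: float) -> np.ndarray:
    """Minimum-jerk point-to-point profile sampled at ``fs`` over [0, T].

    ``x(tau) = start + (end - start) * (10 tau^3 - 15 tau^4 + 6 tau^5)`` with
    ``tau = t / T``; position and velocity match the endpoints exactly.
    """
    if T <= 0:
        raise ParameterError(f"movement time T must be positive, got {T}")
    if fs <= 0:
        raise ParameterError(f"fs must be positive, got {fs}")
    n = int(round(T * fs)) + 1
    tau = np.arange(n) / fs / T
    return start + (end - start) * _mj(tau)


def _mj(tau: np.ndarray) -> np.ndarray:
    """Unit minimum-jerk shape, clamped to 0 before and 1 after the movement."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def submovement_profile(t: np.ndarray, T: float, k: int) -> np.ndarray:
    """Unit 0→1 profile built from ``k`` overlapping minimum-jerk sub-movements.

    Sub-movement i (amplitude 1/k, duration ``2T/(k+1)``) starts at
    ``i * T / (k + 1)``; consecutive velocity bells overlap at half their
    width, so the composite speed never rests between sub-movements and the
    composite remains monotone. ``k = 1`` is a single minimum-jerk movement.
    """
    if k < 1:
        raise ParameterError(f"submovement count must be >= 1, got {k}")
    if T <= 0:
        raise ParameterError(f"movement time T must be positive, got {T}")
    t = np.asarray(t, dtype=float)
    t_sub = 2.0 * T / (k + 1)
    out = np.zeros_like(t)
    for i in range(k):
        onset = i * T / (k + 1)
        out += _mj((t - onset) / t_sub) / k
    return out


# ------------------------------------------------------------ kinematics


def _rodrigues(v: np.ndarray, axis: np.ndarray, theta: float) -> np.ndarray:
    """Rotate ``v`` about unit ``axis`` by ``theta`` radians."""
    c, s = np.cos(theta), np.sin(theta)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


def _validate_profile(p: ImpairmentProfile) -> None:
    if p.movement not in ("RCH", "HTM"):
        raise ValidationError(f"unknown movement tag {p.movement!r}")
    if p.duration <= 0:
        raise ValidationError("duration must be positive")
    if p.noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    if p.submovement_count < 1:
        raise ValidationError("submovement_count must be >= 1")
    for name in ("rom_sf", "rom_sa", "rom_ef", "rom_wf", "tf", "tl", "tt"):
        v = getattr(p, name)
        if not (0.0 <= v <= 180.0):
            raise ValidationError(f"{name}={v} outside [0, 180] degrees")
    if p.hf < 0 or p.hv < 0:
        raise ValidationError("head-displacement amplitudes must be non-negative")
    if p.rom_sf > 160:
        raise ValidationError(f"unreachable configuration: rom_sf={p.rom_sf} > 160 deg")
    if p.rom_sa > min(p.rom_sf, 85.0):
        raise ValidationError(
            "unreachable configuration: shoulder adduction excursion must not exceed "
            f"the flexion excursion (rom_sa={p.rom_sa}, rom_sf={p.rom_sf})"
        )
    ef_cap = _ELBOW_REST - 2.0 if p.movement == "RCH" else 178.0 - _ELBOW_REST
    if p.rom_ef > ef_cap:
        raise ValidationError(
            f"unreachable configuration: rom_ef={p.rom_ef} exceeds {ef_cap:.0f} deg "
            f"for {p.movement}"
        )
    if _WRIST_REST + p.rom_wf > 178.0:
        raise ValidationError(f"unreachable configuration: rom_wf={p.rom_wf} too large")


#: Rest elbow angle between upper-arm and forearm directions (flexed elbow,
#: hand on the thigh) and rest wrist (hand-segment) angle, degrees.
_ELBOW_REST = 80.0
_WRIST_REST = 10.0


def simulate_trial(
    profile: ImpairmentProfile,
    geometry: ChainGeometry = ChainGeometry(),
    seed: int = 0,
    side: str = "right",
    subject_id: str = "",
    fm_score: int | None = None,
) -> SkeletonSequence:
    """Forward-kinematics simulation of one seated trial.

    The trial is ``rest_s + duration + rest_s`` seconds long; all driven
    angles and compensations move during the central window. The output is
    bit-reproducible for a fixed seed.
    """
    _validate_profile(profile)
    if side not in ("left", "right"):
        raise ValidationError(f"unknown side {side!r}")
    geo = geometry
    fs = profile.fs
    n = int(round((profile.duration + 2 * profile.rest_s) * fs)) + 1
    t = np.arange(n) / fs
    t_move = t - profile.rest_s

    # time bases: arm angles use the (possibly fragmented) composite profile,
    # compensations a single smooth minimum-jerk profile on the same window
    s_arm = submovement_profile(t_move, profile.duration, profile.submovement_count)
    s_cmp = submovement_profile(t_move, profile.duration, 1)

    d2r = np.radians
    sf = d2r(profile.rom_sf) * s_arm
    sa_from_lateral = np.pi / 2 - d2r(profile.rom_sa) * s_arm  # angle to +z
    if profile.movement == "RCH":
        elbow = d2r(_ELBOW_REST) - d2r(profile.rom_ef) * s_arm
    else:
        elbow = d2r(_ELBOW_REST) + d2r(profile.rom_ef) * s_arm
    wrist = d2r(_WRIST_REST) + d2r(profile.rom_wf) * s_arm
    alpha_f = d2r(profile.tf) * s_cmp
    alpha_l = d2r(profile.tl) * s_cmp
    theta_t = d2r(profile.tt) * s_cmp

    L = geo.upper_arm + geo.forearm
    base = np.zeros(3)
    u_x, u_y, u_z = np.eye(3)

    positions = np.empty((n, len(JOINTS), 3))
    for i in range(n):
        # trunk orientation: forward tilt about z, then lateral tilt about x
        ca, sa_ = np.cos(alpha_f[i]), np.sin(alpha_f[i])
        cl, sl = np.cos(alpha_l[i]), np.sin(alpha_l[i])
        tr = np.array([sa_, ca * cl, ca * sl])
        spine_shoulder = base + geo.trunk * tr
        spine_mid = base + 0.5 * geo.trunk * tr

        # shoulder line: the body z-axis under the trunk rotation, then the
        # torsion rotation about the trunk axis
        z_t = np.array([0.0, -sl, cl])  # Rx(alpha_l) applied to u_z
        shoulder_dir = _rodrigues(z_t, tr, theta_t[i])
        shoulder_r = spine_shoulder + 0.5 * geo.shoulder_width * shoulder_dir
        shoulder_l = spine_shoulder - 0.5 * geo.shoulder_width * shoulder_dir

        # assessed (right) arm: orientations set directly from the angles
        se_y = -np.cos(sf[i])
        se_z = np.cos(sa_from_lateral[i])
        se_x = np.sqrt(max(0.0, 1.0 - se_y**2 - se_z**2))
        se = np.array([se_x, se_y, se_z])
        m = np.cross(u_z, se)
        m /= np.linalg.norm(m)
        ew = np.cos(elbow[i]) * se + np.sin(elbow[i]) * m
        flex_axis = np.cross(se, ew)
        fa_norm = np.linalg.norm(flex_axis)
        flex_axis = np.cross(se, m) if fa_norm < 1e-9 else flex_axis / fa_norm
        wh_dir = np.cross(flex_axis, ew)
        wh = np.cos(wrist[i]) * ew + np.sin(wrist[i]) * wh_dir

        elbow_r = shoulder_r + geo.upper_arm * se
        wrist_r = elbow_r + geo.forearm * ew
        hand_r = wrist_r + geo.hand * wh

        # contralateral arm: static rest pose relative to its shoulder
        se_o = np.array([np.sin(d2r(5.0)), -np.cos(d2r(5.0)), 0.0])
        ew_o = np.cos(d2r(_ELBOW_REST)) * se_o + np.sin(d2r(_ELBOW_REST)) * np.array(
            [np.cos(d2r(5.0)), np.sin(d2r(5.0)), 0.0]
        )
        elbow_l = shoulder_l + geo.upper_arm * se_o
        wrist_l = elbow_l + geo.forearm * ew_o
        hand_l = wrist_l + geo.hand * ew_o

        # head: rest position plus directly driven compensation offsets
        head = (
            base
            + (geo.trunk + geo.neck) * u_y
            + profile.hf * L * s_cmp[i] * u_x
            + profile.hv * L * s_cmp[i] * u_y
        )

        for name, pos in (
            ("head", head),
            ("spine_shoulder", spine_shoulder),
            ("spine_mid", spine_mid),
            ("spine_base", base),
            ("shoulder_L", shoulder_l),
            ("shoulder_R", shoulder_r),
            ("elbow_L", elbow_l),
            ("elbow_R", elbow_r),
            ("wrist_L", wrist_l),
            ("wrist_R", wrist_r),
            ("hand_L", hand_l),
            ("hand_R", hand_r),
        ):
            positions[i, JOINT_INDEX[name]] = pos

    if side == "left":
        # mirror-image motion: flip z and swap left/right joint columns
        positions[:, :, 2] *= -1.0
        for base_name in ("shoulder", "elbow", "wrist", "hand"):
            li, ri = JOINT_INDEX[f"{base_name}_L"], JOINT_INDEX[f"{base_name}_R"]
            positions[:, [li, ri]] = positions[:, [ri, li]]

    if profile.noise_sd > 0:
        rng = np.random.default_rng(seed)
        positions = positions + rng.normal(0.0, profile.noise_sd, positions.shape)

    return SkeletonSequence(
        t=t,
        positions=positions,
        fs=fs,
        side=side,
        movement=profile.movement,
        subject_id=subject_id,
        fm_score=fm_score,
    )


# ---------------------------------------------------------------- presets

#: Published group means of the 13 parameters (reaching movement), by
#: severity class: angles in degrees, displacements limb-length-normalized.
PRESET_MEANS: dict[str, dict[str, dict[str, float]]] = {
    "RCH": {
        "severe":          {"SF": 32.2, "SA": 16.3, "EF": 13.4, "WF": 16.8, "SV": 0.08, "EV": 0.19, "WV": 0.22, "NJ": 27.6, "HF": 0.12, "HV": 0.06, "TT": 5.14, "TF": 4.35, "TL": 2.87},
        "severe_moderate": {"SF": 55.1, "SA": 38.4, "EF": 22.9, "WF": 15.6, "SV": 0.06, "EV": 0.26, "WV": 0.40, "NJ": 36.9, "HF": 0.06, "HV": 0.05, "TT": 5.09, "TF": 3.60, "TL": 1.59},
        "moderate_mild":   {"SF": 57.3, "SA": 25.3, "EF": 23.8, "WF": 22.7, "SV": 0.06, "EV": 0.26, "WV": 0.44, "NJ": 22.6, "HF": 0.05, "HV": 0.03, "TT": 7.24, "TF": 1.96, "TL": 1.65},
        "mild":            {"SF": 84.5, "SA": 57.2, "EF": 41.0, "WF": 16.6, "SV": 0.04, "EV": 0.43, "WV": 0.67, "NJ": 19.5, "HF": 0.03, "HV": 0.01, "TT": 7.14, "TF": 1.57, "TL": 1.00},
        "healthy":         {"SF": 84.3, "SA": 46.2, "EF": 41.3, "WF": 23.5, "SV": 0.05, "EV": 0.41, "WV": 0.70, "NJ": 15.1, "HF": 0.01, "HV": 0.004, "TT": 5.73, "TF": 0.80, "TL": 0.92},
    },
    "HTM": {
        "severe":          {"SF": 33.7, "SA": 30.6, "EF": 34.8, "WF": 47.1, "SV": 0.07, "EV": 0.25, "WV": 0.39, "NJ": 32.5, "HF": 0.10, "HV": 0.06, "TT": 3.49, "TF": 4.12, "TL": 2.14},
        "severe_moderate": {"SF": 33.9, "SA": 23.0, "EF": 46.8, "WF": 46.5, "SV": 0.09, "EV": 0.23, "WV": 0.59, "NJ": 32.1, "HF": 0.11, "HV": 0.07, "TT": 3.43, "TF": 4.37, "TL": 1.72},
        "moderate_mild":   {"SF": 48.3, "SA": 25.1, "EF": 69.4, "WF": 58.3, "SV": 0.06, "EV": 0.25, "WV": 0.76, "NJ": 33.0, "HF": 0.05, "HV": 0.05, "TT": 3.55, "TF": 3.06, "TL": 1.79},
        "mild":            {"SF": 29.3, "SA": 16.1, "EF": 72.2, "WF": 36.1, "SV": 0.03, "EV": 0.13, "WV": 0.77, "NJ": 20.5, "HF": 0.01, "HV": 0.01, "TT": 3.03, "TF": 1.44, "TL": 1.04},
        "healthy":         {"SF": 17.5, "SA": 6.72, "EF": 82.4, "WF": 36.8, "SV": 0.01, "EV": 0.07, "WV": 0.79, "NJ": 16.6, "HF": 0.005, "HV": 0.005, "TT": 3.44, "TF": 1.35, "TL": 0.75},
    },
}

#: Published between-subject SDs, same layout as :data:`PRESET_MEANS`.
PRESET_SDS: dict[str, dict[str, dict[str, float]]] = {
    "RCH": {
        "severe":          {"SF": 25.2, "SA": 15.7, "EF": 9.8, "WF": 11.1, "SV": 0.09, "EV": 0.18, "WV": 0.18, "NJ": 16.1, "HF": 0.12, "HV": 0.06, "TT": 3.61, "TF": 4.30, "TL": 1.25},
        "severe_moderate": {"SF": 27.6, "SA": 35.5, "EF": 15.9, "WF": 6.5, "SV": 0.04, "EV": 0.16, "WV": 0.24, "NJ": 16.5, "HF": 0.06, "HV": 0.03, "TT": 3.04, "TF": 3.13, "TL": 0.86},
        "moderate_mild":   {"SF": 26.0, "SA": 19.6, "EF": 11.5, "WF": 11.2, "SV": 0.03, "EV": 0.11, "WV": 0.18, "NJ": 12.1, "HF": 0.05, "HV": 0.02, "TT": 3.80, "TF": 1.26, "TL": 0.51},
        "mild":            {"SF": 22.0, "SA": 35.2, "EF": 19.7, "WF": 5.7, "SV": 0.03, "EV": 0.14, "WV": 0.16, "NJ": 9.5, "HF": 0.02, "HV": 0.01, "TT": 2.25, "TF": 1.36, "TL": 0.49},
        "healthy":         {"SF": 14.2, "SA": 23.9, "EF": 10.8, "WF": 10.3, "SV": 0.03, "EV": 0.07, "WV": 0.08, "NJ": 3.7, "HF": 0.004, "HV": 0.003, "TT": 1.53, "TF": 0.54, "TL": 0.47},
    },
    "HTM": {
        "severe":          {"SF": 41.7, "SA": 33.4, "EF": 18.3, "WF": 24.7, "SV": 0.06, "EV": 0.26, "WV": 0.28, "NJ": 11.5, "HF": 0.08, "HV": 0.06, "TT": 3.65, "TF": 2.91, "TL": 1.87},
        "severe_moderate": {"SF": 30.7, "SA": 27.5, "EF": 23.2, "WF": 31.1, "SV": 0.08, "EV": 0.21, "WV": 0.27, "NJ": 10.8, "HF": 0.19, "HV": 0.08, "TT": 3.23, "TF": 5.07, "TL": 1.01},
        "moderate_mild":   {"SF": 46.5, "SA": 29.9, "EF": 23.9, "WF": 39.7, "SV": 0.04, "EV": 0.22, "WV": 0.16, "NJ": 10.7, "HF": 0.04, "HV": 0.03, "TT": 2.42, "TF": 1.12, "TL": 0.61},
        "mild":            {"SF": 21.3, "SA": 20.0, "EF": 12.7, "WF": 16.3, "SV": 0.02, "EV": 0.16, "WV": 0.16, "NJ": 9.19, "HF": 0.006, "HV": 0.01, "TT": 1.88, "TF": 0.66, "TL": 0.68},
        "healthy":         {"SF": 7.4, "SA": 2.9, "EF": 15.9, "WF": 17.1, "SV": 0.01, "EV": 0.03, "WV": 0.07, "NJ": 3.9, "HF": 0.003, "HV": 0.003, "TT": 1.90, "TF": 0.46, "TL": 0.49},
    },
}

#: Measured wrist normalized jerk of a noiseless mid-scale trial as a
#: function of the submovement count (default movement time and frame rate;
#: the exact value varies somewhat with the movement amplitude because the
#: multi-joint wrist path is curved). Used to pick the submovement count
#: whose NJ is closest to a target; NJ targets below the single-movement
#: value map to one submovement, the smoothness floor of this generator.
NJ_BY_SUBMOVEMENTS: dict[int, float] = {1: 14.5, 2: 18.9, 3: 29.4, 4: 38.1, 5: 47.6}


def _submovements_for_nj(nj_target: float) -> int:
    return min(NJ_BY_SUBMOVEMENTS, key=lambda k: abs(NJ_BY_SUBMOVEMENTS[k] - nj_target))


def group_preset(severity: str, movement: str) -> ImpairmentProfile:
    """Profile whose targets equal the published group means for a movement."""
    if movement not in PRESET_MEANS:
        raise ValidationError(f"unknown movement tag {movement!r}")
    if severity not in PRESET_MEANS[movement]:
        raise ValidationError(
            f"unknown severity {severity!r}; expected one of {tuple(PRESET_MEANS[movement])}"
        )
    m = PRESET_MEANS[movement][severity]
    return ImpairmentProfile(
        movement=movement,
        rom_sf=m["SF"],
        rom_sa=m["SA"],
        rom_ef=m["EF"],
        rom_wf=m["WF"],
        hf=m["HF"],
        hv=m["HV"],
        tf=m["TF"],
        tl=m["TL"],
        tt=m["TT"],
        submovement_count=_submovements_for_nj(m["NJ"]),
    )


def sample_subject_profile(
    severity: str, movement: str, rng: np.random.Generator
) -> ImpairmentProfile:
    """Draw one subject's targets around the group preset.

    Each targeted parameter is drawn independently from a normal with the
    published group mean and SD, then clipped to the generator's reachable
    range (notably the adduction excursion may not exceed the flexion
    excursion).
    """
    preset = group_preset(severity, movement)
    mu = PRESET_MEANS[movement][severity]
    sd = PRESET_SDS[movement][severity]

    def draw(name: str, lo: float, hi: float) -> float:
        return float(np.clip(rng.normal(mu[name], sd[name]), lo, hi))

    sf = draw("SF", 2.0, 160.0)
    sa = draw("SA", 0.5, min(0.9 * sf, 85.0))
    ef_cap = _ELBOW_REST - 2.0 if movement == "RCH" else 178.0 - _ELBOW_REST
    return replace(
        preset,
        rom_sf=sf,
        rom_sa=sa,
        rom_ef=draw("EF", 1.0, ef_cap),
        rom_wf=draw("WF", 0.5, 60.0),
        hf=draw("HF", 0.0, 0.6),
        hv=draw("HV", 0.0, 0.6),
        tf=draw("TF", 0.0, 30.0),
        tl=draw("TL", 0.0, 30.0),
        tt=draw("TT", 0.0, 30.0),
    )


def simulate_cohort(
    movement: str,
    n_subjects: int = 10,
    reps: int = 3,
    noise_sd: float = 0.002,
    seed: int = 0,
    severities: Iterable[str] | None = None,
    geometry: ChainGeometry = ChainGeometry(),
) -> dict[str, tuple[str, list[SkeletonSequence]]]:
    """Simulate a stratified cohort: ``n_subjects`` per group, ``reps`` trials each.

    Returns a mapping ``subject_id -> (group_label, trials)``. Subject
    targets are drawn once per subject; repetitions differ only in sensor
    noise. Fully reproducible for a fixed seed.
    """
    if n_subjects < 1 or reps < 1:
        raise ValidationError("n_subjects and reps must be >= 1")
    if severities is None:
        severities = tuple(PRESET_MEANS["RCH"].keys())
    root = np.random.SeedSequence(seed)
    out: dict[str, tuple[str, list[SkeletonSequence]]] = {}
    for severity in severities:
        for i in range(n_subjects):
            ss = root.spawn(1)[0]
            rng = np.random.default_rng(ss)
            profile = replace(
                sample_subject_profile(severity, movement, rng), noise_sd=noise_sd
            )
            subject_id = f"{severity}_{i:02d}"
            trial_seed = int(rng.integers(0, 2**31 - 1))
            trials = [
                simulate_trial(
                    profile, geometry=geometry, seed=trial_seed + r,
                    subject_id=subject_id,
                )
                for r in range(reps)
            ]
            out[subject_id] = (severity, trials)
    return out
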