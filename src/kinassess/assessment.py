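"""Per-trial assessment: the 13-parameter profile, severity classes, cohorts.

Every movement phase is summarized by 13 parameters in three categories:

* typical (required by the task): ``SF``, ``SA``, ``EF``, ``WF`` joint-angle
  ranges of motion, in degrees;
* hybrid (task-related but possibly abnormally recruited): ``SV``, ``EV``,
  ``WV`` vertical displacement ranges of shoulder/elbow/wrist (dimensionless,
  limb-length-normalized) and ``NJ`` normalized jerk of the wrist path;
* compensatory (normally near-absent): ``HF`` sagittal and ``HV`` vertical
  head displacement ranges (dimensionless) and ``TT``/``TF``/``TL`` trunk
  torsion / forward tilt / lateral tilt angle ranges, in degrees.

Each parameter is the range of motion (max - min) of its series over the
phase; a ``start_end`` alternative (absolute start-to-end change) is
available for the displacement parameters.

Patients are stratified by their Fugl-Meyer upper-limb score (0-66) into four
impairment classes — severe (FM <= 15), severe-moderate (15 < FM < 35),
moderate-mild (35 <= FM < 54), mild (FM >= 54) — following the cluster-based
cut-offs in common clinical use; unimpaired controls carry the label
``healthy`` and are never classified through FM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .kinematics import (
    displacement_series,
    joint_angles,
    limb_length,
    normalized_jerk,
    rom,
)
from .segmentation import MovementPhase, segment_sequence
from .preprocessing import FilterSpec, filter_sequence, interpolate_gaps
from .skeleton import SkeletonSequence

#: The 13 assessment parameters, in reporting order.
PARAMETERS: tuple[str, ...] = (
    "SF", "SA", "EF", "WF",          # typical
    "SV", "EV", "WV", "NJ",          # hybrid
    "HF", "HV", "TT", "TF", "TL",    # compensatory
)

CATEGORIES: dict[str, str] = {
    "SF": "typical", "SA": "typical", "EF": "typical", "WF": "typical",
    "SV": "hybrid", "EV": "hybrid", "WV": "hybrid", "NJ": "hybrid",
    "HF": "compensatory", "HV": "compensatory",
    "TT": "compensatory", "TF": "compensatory", "TL": "compensatory",
}

#: Parameters expressed in degrees (the rest are dimensionless).
DEGREE_PARAMS = ("SF", "SA", "EF", "WF", "TT", "TF", "TL")

SEVERITY_LABELS = ("severe", "severe_moderate", "moderate_mild", "mild", "healthy")

#: FM ranges of the four patient classes, as printed inequalities.
FM_RANGES = {
    "severe": "FM <= 15",
    "severe_moderate": "15 < FM < 35",
    "moderate_mild": "35 <= FM < 54",
    "mild": "FM >= 54",
}


@dataclass(frozen=True)
class SeverityGroup:
    label: str
    fm_range: str = ""


@dataclass
class AssessmentResult:
    """The 13-parameter assessment of one movement phase."""

    movement: str
    params: dict[str, float]
    category: dict[str, str] = field(default_factory=lambda: dict(CATEGORIES))
    phase: Optional[MovementPhase] = None
    limb_length: float = float("nan")
    subject_id: str = ""

    def __post_init__(self) -> None:
        missing = set(PARAMETERS) - set(self.params)
        if missing:
            raise ValidationError(f"assessment is missing parameters: {sorted(missing)}")


def classify_fm(score: float) -> SeverityGroup:
    """Map a Fugl-Meyer upper-limb score to its impairment class.

    The four classes partition the score range 0..66 (non-integer inputs,
    e.g. group means, classify by the same inequalities); scores outside
    that range are rejected.
    """
    if not (0 <= score <= 66):
        raise ValidationError(f"FM score must be in 0..66, got {score}")
    if score <= 15:
        label = "severe"
    elif score < 35:
        label = "severe_moderate"
    elif score < 54:
        label = "moderate_mild"
    else:
        label = "mild"
    return SeverityGroup(label=label, fm_range=FM_RANGES[label])


def assess_phase(
    seq: SkeletonSequence,
    phase: MovementPhase,
    wf_formula: str = "printed",
    displacement_mode: str = "rom",
    nj_endpoint: str = "wrist",
    trunk_joints: str = "spine_base",
) -> AssessmentResult:
    """Compute the 13 parameters of one phase of a preprocessed sequence.

    Angle parameters are ranges of motion of the angle series over the phase;
    displacement parameters are ranges (or, with ``displacement_mode=
    'start_end'``, absolute start-to-end changes) of the onset-relative,
    limb-length-normalized displacement series; NJ is the normalized jerk of
    the assessed-side endpoint trajectory (wrist by default — distal hand
    tracking is the noisiest).
    """
    if displacement_mode not in ("rom", "start_end"):
        raise ValidationError(
            f"displacement_mode must be 'rom' or 'start_end', got {displacement_mode!r}"
        )
    if nj_endpoint not in ("wrist", "hand"):
        raise ValidationError(f"nj_endpoint must be 'wrist' or 'hand', got {nj_endpoint!r}")
    if seq.duration < 2.0:
        raise ValidationError(
            f"sequence too short for assessment ({seq.duration:.2f} s < 2 s)"
        )
    angles = joint_angles(seq, wf_formula=wf_formula, trunk_joints=trunk_joints)
    L = limb_length(seq)
    params: dict[str, float] = {}
    for name in ("SF", "SA", "EF", "WF", "TT", "TF", "TL"):
        params[name] = rom(angles[name], phase)

    def disp(joint: str, axis: str) -> float:
        series = displacement_series(seq, joint, axis, phase, L).values
        if displacement_mode == "rom":
            return float(np.max(series) - np.min(series))
        return float(abs(series[-1] - series[0]))

    params["SV"] = disp(seq.side_joint("shoulder"), "y")
    params["EV"] = disp(seq.side_joint("elbow"), "y")
    params["WV"] = disp(seq.side_joint("wrist"), "y")
    params["HF"] = disp("head", "x")
    params["HV"] = disp("head", "y")
    params["NJ"] = normalized_jerk(seq.joint(seq.side_joint(nj_endpoint)), phase, seq.fs)
    return AssessmentResult(
        movement=seq.movement,
        params=params,
        phase=phase,
        limb_length=L,
        subject_id=seq.subject_id,
    )


def analyze_sequence(
    seq: SkeletonSequence,
    filter_spec: FilterSpec = FilterSpec(),
    max_gap: float = 0.2,
    threshold_frac: float = 0.05,
    min_duration: float = 0.2,
    multi_rep: bool = False,
    wf_formula: str = "printed",
    displacement_mode: str = "rom",
    nj_endpoint: str = "wrist",
    trunk_joints: str = "spine_base",
) -> list[AssessmentResult]:
    """Full pipeline on a raw trial: repair gaps, filter, segment, assess."""
    seq = interpolate_gaps(seq, max_gap=max_gap)
    seq = filter_sequence(seq, filter_spec)
    phases = segment_sequence(
        seq, threshold_frac=threshold_frac, min_duration=min_duration,
        multi_rep=multi_rep, trunk_joints=trunk_joints, filter_spec=filter_spec,
    )
    return [
        assess_phase(
            seq, ph, wf_formula=wf_formula, displacement_mode=displacement_mode,
            nj_endpoint=nj_endpoint, trunk_joints=trunk_joints,
        )
        for ph in phases
    ]


def aggregate_subject(results: Iterable[AssessmentResult]) -> dict[str, float]:
    """Arithmetic per-parameter mean across one subject's phases."""
    results = list(results)
    if not results:
        raise ValidationError("no results to aggregate")
    movements = {r.movement for r in results}
    if len(movements) > 1:
        raise ValidationError(f"mixed movement types in aggregation: {sorted(movements)}")
    return {
        name: float(np.mean([r.params[name] for r in results])) for name in PARAMETERS
    }


def _format_cell(mean: float, sd: float) -> str:
    # three significant digits, matching clinical report tables
    return f"{mean:.3g}({sd:.3g})"


def cohort_stats(
    subjects: Mapping[str, tuple[str, Mapping[str, float]]],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Inter-subject mean, SD and count per (parameter, group).

    ``subjects`` maps subject id to ``(group_label, per-parameter means)``.
    Returns three DataFrames (means, sds, counts) indexed by parameter with
    one column per group, groups ordered as in ``SEVERITY_LABELS`` where
    applicable.
    """
    if not subjects:
        raise ValidationError("no subjects given")
    groups_present = {g for g, _ in subjects.values()}
    ordered = [g for g in SEVERITY_LABELS if g in groups_present]
    ordered += sorted(groups_present - set(SEVERITY_LABELS))
    means = pd.DataFrame(index=list(PARAMETERS), columns=ordered, dtype=float)
    sds = pd.DataFrame(index=list(PARAMETERS), columns=ordered, dtype=float)
    counts = pd.DataFrame(index=list(PARAMETERS), columns=ordered, dtype=float)
    for g in ordered:
        members = [vals for grp, vals in subjects.values() if grp == g]
        for name in PARAMETERS:
            x = np.array([m[name] for m in members], dtype=float)
            means.loc[name, g] = float(np.mean(x))
            sds.loc[name, g] = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
            counts.loc[name, g] = len(x)
    return means, sds, counts


def cohort_table(
    subjects: Mapping[str, tuple[str, Mapping[str, float]]],
    movement: str,
) -> pd.DataFrame:
    """Report table: rows = 13 parameters, columns = groups, cells ``mean(SD)``.

    Values are printed to three significant digits, matching the precision of
    clinical report tables.
    """
    if movement not in ("RCH", "HTM"):
        raise ValidationError(f"unknown movement tag {movement!r}")
    means, sds, _ = cohort_stats(subjects)
    table = pd.DataFrame(index=means.index, columns=means.columns, dtype=object)
    for g in means.columns:
        for name in means.index:
            table.loc[name, g] = _format_cell(means.loc[name, g], sds.loc[name, g])
    table.index.name = f"parameter ({movement})"
    return table
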