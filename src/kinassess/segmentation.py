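"""Movement-phase detection from an angular-velocity profile.

A movement phase starts at rest and ends at the target (reaching) or at the
mouth (hand-to-mouth). Phases are found with a velocity-threshold algorithm
on the reference angle's speed profile: for each speed peak, the onset is the
last sample before the peak with speed below 5% of the peak, and the offset
is the first sample after it that falls back below 5%.

The reference angle depends on the movement type: shoulder flexion restricted
to the sagittal plane for reaching (RCH), elbow flexion for hand-to-mouth
(HTM).

By default one phase is extracted per trial — the burst containing the
global speed maximum — matching the protocol in which every recording holds
a single start-to-target movement. Recordings with several repetitions can
opt into iterative burst extraction (largest remaining peak first, then
suppressed) while the remaining peak is at least 20% of the global maximum,
with bursts returned in time order; note that at markerless noise levels the
differentiated angle can produce rest-period noise bursts above that
fraction, so multi-repetition mode should only be used on recordings that
really contain repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ValidationError
from .kinematics import joint_angles, sagittal_shoulder_flexion
from .preprocessing import FilterSpec, derivative, lowpass_filter
from .skeleton import SkeletonSequence

#: A burst is only considered a repetition if its peak reaches this fraction
#: of the global speed maximum.
REP_PEAK_FRAC = 0.2


@dataclass(frozen=True)
class MovementPhase:
    """One detected movement phase, as inclusive sample indices."""

    onset_idx: int
    offset_idx: int
    peak_speed: float = float("nan")
    reference: str = ""

    def __post_init__(self) -> None:
        if self.onset_idx >= self.offset_idx:
            raise ValidationError(
                f"phase onset {self.onset_idx} must precede offset {self.offset_idx}"
            )

    def duration(self, fs: float) -> float:
        return (self.offset_idx - self.onset_idx) / fs

    def n_samples(self) -> int:
        return self.offset_idx - self.onset_idx + 1


def reference_angle_for(movement: str) -> str:
    """Name of the segmentation reference angle for a movement type."""
    if movement == "RCH":
        return "SF_sagittal"
    if movement == "HTM":
        return "EF"
    raise ValidationError(f"unknown movement tag {movement!r}; expected 'RCH' or 'HTM'")


def reference_velocity(
    seq: SkeletonSequence,
    trunk_joints: str = "spine_base",
    filter_spec: FilterSpec | None = FilterSpec(),
) -> np.ndarray:
    """Angular speed series (deg/s) of the movement's reference angle.

    The sequence must already be filtered; the speed is the absolute,
    low-pass-filtered first derivative of the reference angle
    (differentiation re-amplifies band-edge noise, so the derivative is
    smoothed again with the same filter before thresholding; pass
    ``filter_spec=None`` to skip).
    """
    ref = reference_angle_for(seq.movement)
    if ref == "SF_sagittal":
        angle = sagittal_shoulder_flexion(seq)
    else:
        angle = joint_angles(seq, trunk_joints=trunk_joints).EF
    vel = derivative(angle, seq.fs, order=1)
    if filter_spec is not None:
        vel = lowpass_filter(vel, seq.fs, filter_spec)
    return np.abs(vel)


def detect_phases(
    velocity: np.ndarray,
    fs: float,
    threshold_frac: float = 0.05,
    min_duration: float = 0.2,
    multi_rep: bool = False,
) -> list[MovementPhase]:
    """Detect movement phases in an angular-speed profile.

    Parameters
    ----------
    velocity:
        Filtered angular-velocity series (deg/s); the absolute value is used.
    fs:
        Sampling rate in Hz.
    threshold_frac:
        Onset/offset threshold as a fraction of the burst's peak speed.
    min_duration:
        Phases shorter than this (seconds) are discarded as threshold jitter.
    multi_rep:
        If false (default, matching the single-movement trial protocol), only
        the burst containing the global speed maximum is returned.

    Returns
    -------
    list of MovementPhase, time-ordered and pairwise disjoint. An all-zero
    velocity yields an empty list.
    """
    if fs <= 0:
        raise ParameterError(f"fs must be positive, got {fs}")
    if not (0.0 < threshold_frac < 1.0):
        raise ParameterError(f"threshold_frac must be in (0, 1), got {threshold_frac}")
    speed = np.abs(np.asarray(velocity, dtype=float))
    if speed.ndim != 1:
        raise ValidationError("velocity must be a 1-D series")
    global_peak = float(np.max(speed)) if len(speed) else 0.0
    if global_peak <= 0.0:
        return []
    remaining = speed.copy()
    phases: list[MovementPhase] = []
    while True:
        peak_idx = int(np.argmax(remaining))
        peak = float(remaining[peak_idx])
        if peak < REP_PEAK_FRAC * global_peak:
            break
        thr = threshold_frac * peak
        below = remaining < thr
        before = np.flatnonzero(below[: peak_idx + 1])
        onset = int(before[-1]) if len(before) else 0
        after = np.flatnonzero(below[peak_idx:])
        offset = int(peak_idx + after[0]) if len(after) else len(remaining) - 1
        remaining[onset : offset + 1] = 0.0
        if (offset - onset) / fs >= min_duration and onset < offset:
            phases.append(
                MovementPhase(onset_idx=onset, offset_idx=offset, peak_speed=peak)
            )
        if not multi_rep:
            break
    phases.sort(key=lambda ph: ph.onset_idx)
    return phases


def segment_sequence(
    seq: SkeletonSequence,
    threshold_frac: float = 0.05,
    min_duration: float = 0.2,
    multi_rep: bool = False,
    trunk_joints: str = "spine_base",
    filter_spec: FilterSpec | None = FilterSpec(),
) -> list[MovementPhase]:
    """Detect phases of a preprocessed sequence using its reference angle."""
    velocity = reference_velocity(seq, trunk_joints=trunk_joints, filter_spec=filter_spec)
    ref = reference_angle_for(seq.movement)
    phases = detect_phases(
        velocity, seq.fs, threshold_frac=threshold_frac,
        min_duration=min_duration, multi_rep=multi_rep,
    )
    return [
        MovementPhase(p.onset_idx, p.offset_idx, p.peak_speed, reference=ref)
        for p in phases
    ]
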