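"""Noise filtering, dropout repair, and numerical differentiation.

Joint coordinates from markerless tracking carry high-frequency sensor noise;
they are low-pass filtered with a 3rd-order Butterworth at 6 Hz before any
vector or angle computation. Filtering is applied to the raw coordinates, not
to derived angle series; derivatives (velocity, jerk) are then taken on the
derived series.

By default the filter is applied forward and backward (zero phase), so that
phase-segmentation timing is not shifted by the filter's group delay; the
effective magnitude response is then the square of the single-pass response
(-6 dB instead of -3 dB at the cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import LengthError, ParameterError, UnrecoverableDropoutError, ValidationError
from .skeleton import JOINTS, SkeletonSequence


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth filter settings.

    cutoff: -3 dB cutoff frequency in Hz (single pass). Must lie below the
        Nyquist frequency of the series it is applied to.
    order: filter order (>= 1).
    zero_phase: apply forward-backward (no phase lag) if true, single
        forward pass otherwise.
    """

    cutoff: float = 6.0
    order: int = 3
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ParameterError(f"cutoff must be positive, got {self.cutoff}")
        if self.order < 1:
            raise ParameterError(f"order must be >= 1, got {self.order}")


def lowpass_filter(series: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Butterworth low-pass filter a uniformly sampled scalar series.

    The input is extended by reflection at both ends to suppress edge
    transients (trials start and end at rest, so this is benign).

    Raises
    ------
    ParameterError
        If the cutoff is at or above the Nyquist frequency.
    LengthError
        If the series is shorter than ``3 * (order + 1) + 1`` samples.
    """
    series = np.asarray(series, dtype=float)
    if fs <= 0:
        raise ParameterError(f"fs must be positive, got {fs}")
    if spec.cutoff >= fs / 2:
        raise ParameterError(
            f"cutoff {spec.cutoff} Hz is not below the Nyquist frequency {fs / 2} Hz"
        )
    min_len = 3 * (spec.order + 1) + 1
    if series.ndim != 1 or len(series) < min_len:
        raise LengthError(f"series must be 1-D with at least {min_len} samples")
    if np.isnan(series).any():
        raise ValidationError("series contains missing values; interpolate gaps first")
    sos = signal.butter(spec.order, spec.cutoff, btype="low", fs=fs, output="sos")
    if spec.zero_phase:
        padlen = min(3 * (spec.order + 1), len(series) - 1)
        return signal.sosfiltfilt(sos, series, padlen=padlen)
    return signal.sosfilt(sos, series)


def filter_sequence(seq: SkeletonSequence, spec: FilterSpec = FilterSpec()) -> SkeletonSequence:
    """Low-pass filter every joint coordinate of a gap-free sequence."""
    if seq.has_missing():
        raise ValidationError("sequence has missing samples; run interpolate_gaps first")
    out = seq.positions.copy()
    for k in range(len(JOINTS)):
        for a in range(3):
            out[:, k, a] = lowpass_filter(seq.positions[:, k, a], seq.fs, spec)
    return seq.copy(positions=out)


def interpolate_gaps(seq: SkeletonSequence, max_gap: float = 0.2) -> SkeletonSequence:
    """Linearly interpolate per-joint tracking dropouts up to ``max_gap`` seconds.

    A gap of k consecutive missing frames spans ``k / fs`` seconds. Gaps
    longer than ``max_gap``, or gaps touching the start or end of the trial
    (which cannot be interpolated), raise
    :class:`~kinassess.errors.UnrecoverableDropoutError` naming the joint and
    time span. The returned sequence has no missing values.
    """
    if max_gap < 0:
        raise ParameterError(f"max_gap must be non-negative, got {max_gap}")
    if not seq.has_missing():
        return seq.copy()
    out = seq.positions.copy()
    mask = seq.missing_mask  # (n, 12)
    n = seq.n_frames
    for k, joint in enumerate(JOINTS):
        m = mask[:, k]
        if not m.any():
            continue
        # enumerate runs of missing frames
        idx = np.flatnonzero(m)
        runs: list[tuple[int, int]] = []
        start = idx[0]
        prev = idx[0]
        for i in idx[1:]:
            if i != prev + 1:
                runs.append((start, prev))
                start = i
            prev = i
        runs.append((start, prev))
        for a, b in runs:
            span = (b - a + 1) / seq.fs
            if a == 0 or b == n - 1 or span > max_gap:
                raise UnrecoverableDropoutError(
                    f"joint {joint}: dropout of {span:.3f} s over t="
                    f"[{seq.t[a]:.3f}, {seq.t[b]:.3f}] s exceeds max_gap={max_gap} s "
                    "or touches the trial boundary"
                )
        valid = ~m
        for axis in range(3):
            out[m, k, axis] = np.interp(seq.t[m], seq.t[valid], seq.positions[valid, k, axis])
    return seq.copy(positions=out)


#: Second-order-accurate finite-difference stencils per derivative order:
#: (central coefficients, one-sided boundary coefficients).
_CENTRAL = {
    1: np.array([-0.5, 0.0, 0.5]),
    2: np.array([1.0, -2.0, 1.0]),
    3: np.array([-0.5, 1.0, 0.0, -1.0, 0.5]),
}
_ONESIDED = {
    1: np.array([-1.5, 2.0, -0.5]),
    2: np.array([2.0, -5.0, 4.0, -1.0]),
    3: np.array([-2.5, 9.0, -12.0, 7.0, -1.5]),
}


def derivative(series: np.ndarray, fs: float, order: int = 1) -> np.ndarray:
    """n-th time derivative by second-order-accurate finite differences.

    Interior samples use compact central stencils; near the series ends
    one-sided stencils of the same accuracy are used, so the output has the
    same length as the input. Compact stencils (rather than repeated
    two-point differencing) keep the discretization error of the jerk
    integral small at typical sensor frame rates.
    """
    if order not in (1, 2, 3):
        raise ParameterError(f"order must be 1, 2 or 3, got {order}")
    if fs <= 0:
        raise ParameterError(f"fs must be positive, got {fs}")
    series = np.asarray(series, dtype=float)
    central = _CENTRAL[order]
    oneside = _ONESIDED[order]
    half = len(central) // 2
    min_len = max(2 * order + 1, len(oneside))
    if series.ndim != 1 or len(series) < min_len:
        raise LengthError(f"series must be 1-D with at least {min_len} samples")
    h = 1.0 / fs
    out = np.convolve(series, central[::-1], mode="same")
    k = len(oneside)
    for i in range(half):
        out[i] = np.dot(oneside, series[i : i + k])
        out[-1 - i] = ((-1.0) ** order) * np.dot(oneside, series[-1 - i : -1 - i - k : -1])
    return out / h**order
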