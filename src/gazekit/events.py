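"""Offline saccade and fixation detection by velocity threshold.

The detector has three parameters: a velocity threshold (deg/s), a minimum
saccade duration and a minimum fixation duration (ms). Maximal runs of samples
whose speed strictly exceeds the threshold become saccade candidates if they
last at least the minimum saccade duration; consecutive candidates separated
by less than the minimum fixation duration are merged (a brief dip below
threshold mid-flight is not a fixation); surviving candidates are saccades and
the intervals between them are fixations.

Convention: a run's onset is the timestamp of its first supra-threshold
sample and its offset the timestamp of its last; run duration is their
difference. A merged saccade spans from the first candidate's onset to the
last's offset, and its amplitude is measured between the positions at those
two samples. Events that overlap tracking-loss samples are kept but flagged
unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_data import Trial
from .filtering import FilterSpec, filter_trial, velocity

__all__ = [
    "DetectionParams",
    "SaccadeEvent",
    "FixationEvent",
    "EventList",
    "merge_candidates",
    "saccade_intervals",
    "detect_events",
]


@dataclass(frozen=True)
class DetectionParams:
    """Three-parameter velocity-threshold detector configuration."""

    velocity_threshold: float = 22.0  # deg/s
    min_saccade_ms: float = 12.0
    min_fixation_ms: float = 12.0

    def __post_init__(self) -> None:
        if not (
            self.velocity_threshold > 0
            and self.min_saccade_ms > 0
            and self.min_fixation_ms > 0
        ):
            raise ValueError("detection parameters must all be positive")


@dataclass
class SaccadeEvent:
    onset_ms: float
    offset_ms: float
    duration_ms: float
    start: tuple[float, float]
    end: tuple[float, float]
    amplitude_deg: float
    peak_velocity: float
    unreliable: bool = False


@dataclass
class FixationEvent:
    onset_ms: float
    offset_ms: float
    duration_ms: float
    centroid: tuple[float, float]
    unreliable: bool = False


@dataclass
class EventList:
    """Ordered saccades and fixations tiling the analysed span."""

    saccades: list[SaccadeEvent] = field(default_factory=list)
    fixations: list[FixationEvent] = field(default_factory=list)


def merge_candidates(
    candidates: Sequence[tuple[float, float]], min_fixation_ms: float
) -> list[tuple[float, float]]:
    """Merge sorted, disjoint (onset, offset) intervals across short gaps.

    A single left-to-right pass: whenever the gap to the next interval is
    strictly less than ``min_fixation_ms``, the two intervals fuse into one
    spanning the first onset to the last offset. Idempotent. Raises ValueError
    on unsorted or overlapping input.
    """
    cands = list(candidates)
    for (a0, a1), (b0, b1) in zip(cands, cands[1:]):
        if b0 < a1 or a0 > a1 or b0 > b1:
            raise ValueError("candidate intervals must be sorted and disjoint")
    if not cands:
        return []
    merged = [cands[0]]
    for on, off in cands[1:]:
        if on - merged[-1][1] < min_fixation_ms:
            merged[-1] = (merged[-1][0], off)
        else:
            merged.append((on, off))
    return merged


def saccade_intervals(
    t: np.ndarray, speed: np.ndarray, params: DetectionParams
) -> list[tuple[int, int]]:
    """Detect saccade spans as (first, last) sample index pairs.

    Runs the full candidate pipeline on a precomputed speed series: strict
    supra-threshold runs (NaN speed is never supra-threshold), the minimum
    duration gate, then gap merging.
    """
    t = np.asarray(t, dtype=float)
    speed = np.asarray(speed, dtype=float)
    with np.errstate(invalid="ignore"):
        supra = speed > params.velocity_threshold

    # maximal supra-threshold runs as index pairs
    padded = np.concatenate(([False], supra, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0] - 1  # inclusive last index

    candidates = [
        (int(i0), int(i1))
        for i0, i1 in zip(starts, ends)
        if t[i1] - t[i0] >= params.min_saccade_ms
    ]

    # merge on time gaps, carrying sample indices along
    merged: list[tuple[int, int]] = []
    for i0, i1 in candidates:
        if merged and t[i0] - t[merged[-1][1]] < params.min_fixation_ms:
            merged[-1] = (merged[-1][0], i1)
        else:
            merged.append((i0, i1))
    return merged


def detect_events(
    trial: Trial,
    params: DetectionParams = DetectionParams(),
    filter_spec: Optional[FilterSpec] = None,
    fs: Optional[float] = None,
) -> EventList:
    """Detect saccades and fixations in one trial.

    When ``filter_spec`` is given, speed (and event start/end positions) are
    taken from the zero-phase-filtered trace; otherwise from the raw trace.
    Requires at least 3 valid samples.
    """
    if int(np.count_nonzero(trial.valid)) < 3:
        raise ValueError("detection requires at least 3 valid samples")

    trace = trial
    if filter_spec is not None:
        trace, _ = filter_trial(trial, filter_spec, fs=fs)

    speed = velocity(trace.t, trace.x, trace.y, trace.valid)
    spans = saccade_intervals(trace.t, speed, params)

    t = trace.t

    def _touches_invalid(t0: float, t1: float) -> bool:
        # unreliable if the event contains an invalid sample, or directly
        # abuts one (a gap can truncate a run and hide its true boundary)
        i0 = int(np.searchsorted(t, t0))
        i1 = int(np.searchsorted(t, t1, side="right")) - 1
        lo = max(0, i0 - 1)
        hi = min(len(t), i1 + 2)
        return bool(np.any(~trace.valid[lo:hi]))

    saccades: list[SaccadeEvent] = []
    for i0, i1 in spans:
        on, off = float(t[i0]), float(t[i1])
        seg = slice(i0, i1 + 1)
        pv = float(np.nanmax(speed[seg]))
        saccades.append(
            SaccadeEvent(
                onset_ms=on,
                offset_ms=off,
                duration_ms=off - on,
                start=(float(trace.x[i0]), float(trace.y[i0])),
                end=(float(trace.x[i1]), float(trace.y[i1])),
                amplitude_deg=float(
                    np.hypot(trace.x[i1] - trace.x[i0], trace.y[i1] - trace.y[i0])
                ),
                peak_velocity=pv,
                unreliable=_touches_invalid(on, off),
            )
        )

    # complementary intervals are fixations
    fixations: list[FixationEvent] = []
    bounds = [float(t[0])]
    for s in saccades:
        bounds.extend([s.onset_ms, s.offset_ms])
    bounds.append(float(t[-1]))
    for f0, f1 in zip(bounds[0::2], bounds[1::2]):
        if f1 <= f0:
            continue
        in_fix = (t >= f0) & (t <= f1) & trace.valid
        if np.any(in_fix):
            cx = float(np.mean(trace.x[in_fix]))
            cy = float(np.mean(trace.y[in_fix]))
        else:
            cx = cy = float("nan")
        fixations.append(
            FixationEvent(
                onset_ms=f0,
                offset_ms=f1,
                duration_ms=f1 - f0,
                centroid=(cx, cy),
                unreliable=_touches_invalid(f0, f1),
            )
        )

    return EventList(saccades=saccades, fixations=fixations)
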