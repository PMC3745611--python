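"""Trial-level analysis: first-saccade extraction, latency, validity, summaries.

A saccade-task trial is scored by the first saccade after target onset: its
latency must fall inside an acceptance window (default 100–600 ms), it must
land within a radius of the expected position (default 2.0°; for an
antisaccade the expected position is the mirror of the target about the
fixation point), and its detection must not be compromised by a tracking-loss
gap. Trials failing any check are rejected with a reason and excluded from
task summaries.

Fixation accuracy is measured as the mean distance between gaze and target in
a window after each target jump (default 250–750 ms), when the correcting
saccade has landed and gaze is steady.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_data import MessageEvent, Trial
from .events import EventList, SaccadeEvent

__all__ = [
    "RejectionReason",
    "ClassifyOptions",
    "TrialOutcome",
    "TaskSummary",
    "ConditionSummary",
    "first_saccade_after",
    "latency",
    "mirror_position",
    "classify_trial",
    "spatial_error",
    "summarize_task",
]


class RejectionReason(enum.Enum):
    NO_SACCADE = "no_saccade"
    LATENCY_OUT_OF_RANGE = "latency_out_of_range"
    LANDING_TOO_FAR = "landing_too_far"
    DETECTION_GAP = "detection_gap"


@dataclass(frozen=True)
class ClassifyOptions:
    """Trial acceptance rules: latency window (ms, closed) and landing radius."""

    latency_window_ms: tuple[float, float] = (100.0, 600.0)
    landing_radius_deg: float = 2.0


@dataclass
class TrialOutcome:
    index: int
    condition: str
    latency_ms: Optional[float]
    amplitude_deg: Optional[float]
    landing: Optional[tuple[float, float]]
    valid: bool
    rejection_reason: Optional[RejectionReason] = None

    def __post_init__(self) -> None:
        assert self.valid == (self.rejection_reason is None)


def first_saccade_after(events: EventList, t0: float) -> Optional[SaccadeEvent]:
    """Earliest saccade with onset at or after ``t0`` (closed boundary)."""
    for s in events.saccades:
        if s.onset_ms >= t0:
            return s
    return None


def latency(sac: SaccadeEvent, msg: MessageEvent) -> float:
    """Saccade onset time relative to a message (ms)."""
    return sac.onset_ms - msg.t


def mirror_position(
    target: tuple[float, float], fixation: tuple[float, float] = (0.0, 0.0)
) -> tuple[float, float]:
    """Point-reflect a target about the fixation point (antisaccade goal)."""
    return (2 * fixation[0] - target[0], 2 * fixation[1] - target[1])


def classify_trial(
    events: EventList,
    target_onset_msg: MessageEvent,
    expected_pos: tuple[float, float],
    opts: ClassifyOptions = ClassifyOptions(),
    index: int = 0,
    condition: str = "",
) -> TrialOutcome:
    """Score one trial by its first saccade after target onset.

    ``expected_pos`` is where a correct saccade should land (the target for a
    prosaccade, its mirror for an antisaccade). Checks run in order:
    saccade present → detection not gap-compromised → latency within the
    closed window → landing within the radius.
    """
    sac = first_saccade_after(events, target_onset_msg.t)
    if sac is None:
        return TrialOutcome(
            index, condition, None, None, None, False, RejectionReason.NO_SACCADE
        )
    lat = latency(sac, target_onset_msg)
    land = sac.end
    if sac.unreliable:
        return TrialOutcome(
            index, condition, lat, sac.amplitude_deg, land, False,
            RejectionReason.DETECTION_GAP,
        )
    lo, hi = opts.latency_window_ms
    if not (lo <= lat <= hi):
        return TrialOutcome(
            index, condition, lat, sac.amplitude_deg, land, False,
            RejectionReason.LATENCY_OUT_OF_RANGE,
        )
    dist = float(np.hypot(land[0] - expected_pos[0], land[1] - expected_pos[1]))
    if dist > opts.landing_radius_deg:
        return TrialOutcome(
            index, condition, lat, sac.amplitude_deg, land, False,
            RejectionReason.LANDING_TOO_FAR,
        )
    return TrialOutcome(index, condition, lat, sac.amplitude_deg, land, True, None)


def spatial_error(
    trial: Trial,
    target_jumps: Sequence[tuple[float, tuple[float, float]]],
    window_ms: tuple[float, float] = (250.0, 750.0),
) -> tuple[list[Optional[float]], Optional[float]]:
    """Mean gaze-to-target distance in a post-jump window, per jump.

    For each (t_jump, position), valid samples with
    t_jump + window[0] ≤ t < t_jump + window[1] are compared with the target;
    a jump with no valid sample in its window yields None and is skipped in
    the trial average. Returns (per-jump means, overall mean or None).
    """
    per_jump: list[Optional[float]] = []
    for t_jump, (tx, ty) in target_jumps:
        lo, hi = t_jump + window_ms[0], t_jump + window_ms[1]
        m = (trial.t >= lo) & (trial.t < hi) & trial.valid
        if not np.any(m):
            per_jump.append(None)
            continue
        d = np.hypot(trial.x[m] - tx, trial.y[m] - ty)
        per_jump.append(float(np.mean(d)))
    usable = [v for v in per_jump if v is not None]
    overall = float(np.mean(usable)) if usable else None
    return per_jump, overall


@dataclass
class ConditionSummary:
    n: int
    mean_latency_ms: float
    sd_latency_ms: float
    mean_amplitude_deg: float
    sd_amplitude_deg: float


@dataclass
class TaskSummary:
    """Per-condition latency/amplitude statistics over valid trials only."""

    conditions: dict[str, ConditionSummary] = field(default_factory=dict)
    n_trials: int = 0
    n_valid: int = 0
    removal_fraction: float = 0.0


def summarize_task(outcomes: Sequence[TrialOutcome]) -> TaskSummary:
    """Aggregate trial outcomes into per-condition means and SDs.

    Invalid trials contribute only to the removal fraction, exactly
    1 − n_valid/n_trials.
    """
    n = len(outcomes)
    valid = [o for o in outcomes if o.valid]
    by_cond: dict[str, list[TrialOutcome]] = {}
    for o in valid:
        by_cond.setdefault(o.condition, []).append(o)
    conditions = {}
    for cond, os_ in sorted(by_cond.items()):
        lats = np.array([o.latency_ms for o in os_], dtype=float)
        amps = np.array([o.amplitude_deg for o in os_], dtype=float)
        conditions[cond] = ConditionSummary(
            n=len(os_),
            mean_latency_ms=float(np.mean(lats)),
            sd_latency_ms=float(np.std(lats, ddof=1)) if len(os_) > 1 else 0.0,
            mean_amplitude_deg=float(np.mean(amps)),
            sd_amplitude_deg=float(np.std(amps, ddof=1)) if len(os_) > 1 else 0.0,
        )
    return TaskSummary(
        conditions=conditions,
        n_trials=n,
        n_valid=len(valid),
        removal_fraction=(1.0 - len(valid) / n) if n else 0.0,
    )
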