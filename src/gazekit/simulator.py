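"""Synthetic eye-tracking sessions with known ground truth.

This module stands in for the camera, recorder and presentation hardware: it
generates task schedules (antisaccade, gap/overlap, fixation grid), gaze
traces with realistic saccade kinematics and measurement noise, camera-space
feature streams, and ocular image sequences — each with the generative ground
truth attached, so every downstream stage (imaging, calibration, filtering,
detection, analysis) can be tested against what was actually injected.

Kinematic model: saccades follow a raised-cosine velocity profile
v(t) = (A/D)·(1 − cos 2πt/D), whose peak velocity is 2A/D, with a linear
main-sequence duration rule D = d0 + d1·A (defaults 20 ms + 2 ms/deg).
Fixations are the current gaze goal plus isotropic Gaussian noise. Latencies
are drawn per condition from a truncated normal (ex-Gaussian available).
Sampling imperfections are modeled explicitly: i.i.d. Gaussian jitter on each
intersample interval, i.i.d. frame drops, and two-state Markov tracking loss
producing contiguous ``valid=False`` gaps.

All randomness flows from the mandatory seed; identical config + seed gives
bit-identical output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .calibration import CalibrationModel, CalibrationSample, CalibrationSchedule
from .core_data import GazeRecording, MessageEvent, ScreenGeometry, Trial
from .imaging import RenderConfig, render_eye_image

logger = logging.getLogger(__name__)

__all__ = [
    "Kinematics",
    "LatencyModel",
    "SimConfig",
    "ScheduledTrial",
    "TrialTruth",
    "make_schedule",
    "synth_trace",
    "simulate_session",
    "synth_feature_stream",
    "synth_calibration_stream",
    "synth_image_sequence",
    "grid_positions",
    "DEFAULT_SCREEN",
]

DEFAULT_SCREEN = ScreenGeometry(
    viewing_distance_cm=57.0, pixels_per_cm=28.0, resolution=(1920, 1080)
)


@dataclass(frozen=True)
class Kinematics:
    """Raised-cosine saccade kinematics with a linear main-sequence rule."""

    d0_ms: float = 20.0
    d1_ms_per_deg: float = 2.0

    def duration_ms(self, amplitude_deg: float) -> float:
        return self.d0_ms + self.d1_ms_per_deg * amplitude_deg

    def peak_velocity(self, amplitude_deg: float) -> float:
        """Analytic peak speed, deg/s: 2·A/D for the raised-cosine profile."""
        return 2.0 * amplitude_deg / (self.duration_ms(amplitude_deg) / 1000.0)

    def displacement(self, amplitude_deg: float, tau: np.ndarray) -> np.ndarray:
        """Distance travelled at normalised time tau ∈ [0, 1]."""
        tau = np.clip(tau, 0.0, 1.0)
        return amplitude_deg * (tau - np.sin(2 * np.pi * tau) / (2 * np.pi))


@dataclass
class LatencyModel:
    """Per-condition saccade latency distribution (ms)."""

    means: dict[str, float]
    sd: float = 30.0
    dist: str = "truncnorm"  # or "exgauss"
    bounds: tuple[float, float] = (80.0, 700.0)
    tau_ms: float = 60.0  # exponential component of the ex-Gaussian

    def draw(self, condition: str, rng: np.random.Generator) -> float:
        mu = self.means[condition]
        lo, hi = self.bounds
        for _ in range(1000):
            if self.dist == "truncnorm":
                v = rng.normal(mu, self.sd)
            elif self.dist == "exgauss":
                v = rng.normal(mu - self.tau_ms, self.sd) + rng.exponential(self.tau_ms)
            else:
                raise ValueError(f"unknown latency distribution {self.dist!r}")
            if lo <= v <= hi:
                return float(v)
        return float(np.clip(mu, lo, hi))  # pragma: no cover - degenerate config


_GAP_OFFSETS = (-200.0, -100.0, 0.0, 100.0, 200.0)
_FIX_DURATIONS = (1000.0, 1100.0, 1200.0, 1300.0, 1400.0, 1500.0)


def _default_latency(task: str) -> LatencyModel:
    if task == "gapoverlap":
        # latency grows monotonically from gap to overlap
        return LatencyModel(
            means={f"gap{int(g):+d}": m for g, m in zip(_GAP_OFFSETS, (160.0, 175.0, 195.0, 220.0, 240.0))}
        )
    if task == "antisaccade":
        return LatencyModel(means={"pro": 200.0, "anti": 260.0})
    if task == "grid":
        return LatencyModel(means={"grid": 200.0})
    raise ValueError(f"unknown task {task!r}")


@dataclass
class SimConfig:
    """Full generative configuration of a synthetic session.

    The defaults mirror the study conditions the tasks come from: target
    eccentricity 4.2°, fixation durations 1000–1500 ms, gap offsets −200 to
    +200 ms, 20 trials per block, a 6×6 grid with 2.7° spacing for the
    fixation-accuracy task, and a 3×3 calibration grid spaced 9.3° × 6.6°.
    """

    seed: int
    task: str = "gapoverlap"
    nominal_rate: float = 250.0
    trials_per_block: int = 20
    n_blocks: int = 4
    fixation_noise_sd: float = 0.1  # deg
    timestamp_jitter_sd: float = 0.0  # ms, i.i.d. per interval
    frame_drop_prob: float = 0.0
    gap_prob: float = 0.0  # per-sample probability of entering tracking loss
    gap_dur_ms: float = 100.0  # mean tracking-loss duration
    target_distance_deg: float = 4.2
    landing_noise_sd: float = 0.0  # deg, endpoint scatter
    trial_length_ms: float = 3000.0
    fix_durations_ms: tuple[float, ...] = _FIX_DURATIONS
    gap_offsets_ms: tuple[float, ...] = _GAP_OFFSETS
    grid_size: int = 6
    grid_spacing_deg: float = 2.7
    grid_jumps: int = 10
    grid_dwell_ms: float = 1000.0
    kinematics: Kinematics = field(default_factory=Kinematics)
    latency: Optional[LatencyModel] = None
    screen: ScreenGeometry = field(default_factory=lambda: replace(DEFAULT_SCREEN))

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for any stochastic output")
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be positive")
        if not (0.0 <= self.frame_drop_prob < 1.0 and 0.0 <= self.gap_prob < 1.0):
            raise ValueError("probabilities must lie in [0, 1)")
        if self.latency is None:
            self.latency = _default_latency(self.task)


@dataclass
class ScheduledTrial:
    """One planned trial: condition, stimulus timing and geometry."""

    index: int
    condition: str
    fix_duration_ms: float
    target_on_ms: float
    fix_off_ms: float
    end_ms: float
    target_pos: tuple[float, float]
    goal_pos: tuple[float, float]  # where the correct saccade should land
    # grid task: (jump time, new target position); saccades chase each jump
    jumps: list[tuple[float, tuple[float, float]]] = field(default_factory=list)


@dataclass
class TrialTruth:
    """Generative ground truth of one emitted trial."""

    index: int
    condition: str
    target_pos: tuple[float, float]
    goal_pos: tuple[float, float]
    target_onset_ms: float
    latency_ms: Optional[float] = None
    saccade_onset_ms: Optional[float] = None
    saccade_offset_ms: Optional[float] = None
    amplitude_deg: Optional[float] = None
    peak_velocity: Optional[float] = None
    # grid task: one entry per target jump
    jumps: list[tuple[float, tuple[float, float]]] = field(default_factory=list)
    jump_saccades: list[tuple[float, float, float]] = field(default_factory=list)


def grid_positions(n: int, spacing: float) -> list[tuple[float, float]]:
    """Nodes of an n×n grid centered on the screen center, row-major."""
    offs = (np.arange(n) - (n - 1) / 2.0) * spacing
    return [(float(x), float(y)) for y in offs[::-1] for x in offs]


_DIRECTIONS = {
    "right": (1.0, 0.0),
    "left": (-1.0, 0.0),
    "up": (0.0, 1.0),
    "down": (0.0, -1.0),
}


def make_schedule(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> list[ScheduledTrial]:
    """Build the session's trial schedule with balanced conditions per block.

    Antisaccade task: blocks alternate anti/pro instruction; the 4 target
    directions appear equally often within a block, in seeded random order.
    Gap/overlap task: the 5 gap offsets (and 2 directions) are balanced within
    each block. Grid task: each trial visits ``grid_jumps + 1`` distinct nodes
    of the fixation grid.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    trials: list[ScheduledTrial] = []
    idx = 1
    dist = cfg.target_distance_deg

    if cfg.task in ("antisaccade", "gapoverlap"):
        for b in range(cfg.n_blocks):
            if cfg.task == "antisaccade":
                block_cond = "anti" if b % 2 == 0 else "pro"
                dirs = list(_DIRECTIONS)
                reps = -(-cfg.trials_per_block // len(dirs))
                combos = (dirs * reps)[: cfg.trials_per_block]
                rng.shuffle(combos)
                plan = [(block_cond, d, None) for d in combos]
            else:
                dirs = ["left", "right"]
                combos = [
                    (g, d) for g in cfg.gap_offsets_ms for d in dirs
                ]
                reps = -(-cfg.trials_per_block // len(combos))
                full = (combos * reps)[: cfg.trials_per_block]
                rng.shuffle(full)
                plan = [(f"gap{int(g):+d}", d, g) for g, d in full]

            for cond, dname, g in plan:
                fdur = float(rng.choice(cfg.fix_durations_ms))
                dx, dy = _DIRECTIONS[dname]
                target = (dx * dist, dy * dist)
                goal = (
                    (-target[0], -target[1])
                    if cond == "anti"
                    else target
                )
                t_on = fdur
                fix_off = fdur + (g if g is not None else 0.0)
                trials.append(
                    ScheduledTrial(
                        index=idx,
                        condition=cond,
                        fix_duration_ms=fdur,
                        target_on_ms=t_on,
                        fix_off_ms=fix_off,
                        end_ms=fdur + cfg.trial_length_ms,
                        target_pos=target,
                        goal_pos=goal,
                    )
                )
                idx += 1
    elif cfg.task == "grid":
        nodes = grid_positions(cfg.grid_size, cfg.grid_spacing_deg)
        n_total = cfg.trials_per_block * cfg.n_blocks
        for _ in range(n_total):
            order = rng.permutation(len(nodes))[: cfg.grid_jumps + 1]
            path = [nodes[i] for i in order]
            jumps = [
                (float((k + 1) * cfg.grid_dwell_ms), path[k + 1])
                for k in range(cfg.grid_jumps)
            ]
            end = (cfg.grid_jumps + 1) * cfg.grid_dwell_ms
            trials.append(
                ScheduledTrial(
                    index=idx,
                    condition="grid",
                    fix_duration_ms=cfg.grid_dwell_ms,
                    target_on_ms=0.0,
                    fix_off_ms=0.0,
                    end_ms=end,
                    target_pos=path[0],
                    goal_pos=path[-1],
                    jumps=jumps,
                )
            )
            idx += 1
    else:
        raise ValueError(f"unknown task {cfg.task!r}")
    return trials


def _sample_times(cfg: SimConfig, end_ms: float, rng: np.random.Generator) -> np.ndarray:
    dt = 1000.0 / cfg.nominal_rate
    n = int(math.floor(end_ms / dt)) + 1
    intervals = np.full(n - 1, dt)
    if cfg.timestamp_jitter_sd > 0:
        intervals = intervals + rng.normal(0.0, cfg.timestamp_jitter_sd, n - 1)
        intervals = np.maximum(intervals, 0.05)  # keep time strictly increasing
    return np.concatenate(([0.0], np.cumsum(intervals)))


def _tracking_loss(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Two-state Markov valid/lost chain producing contiguous gaps."""
    valid = np.ones(n, dtype=bool)
    if cfg.gap_prob <= 0:
        return valid
    dt = 1000.0 / cfg.nominal_rate
    p_exit = min(1.0, dt / cfg.gap_dur_ms)
    lost = False
    u = rng.random(n)
    for i in range(n):
        if lost:
            if u[i] < p_exit:
                lost = False
        else:
            if u[i] < cfg.gap_prob:
                lost = True
        valid[i] = not lost
    return valid


def _saccade_segment(
    kin: Kinematics,
    t: np.ndarray,
    onset: float,
    start: np.ndarray,
    end: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Positions for all samples given one saccade; returns (pos, duration)."""
    amp = float(np.hypot(*(end - start)))
    if amp == 0.0:
        return np.tile(start, (len(t), 1)), 0.0
    D = kin.duration_ms(amp)
    tau = (t - onset) / D
    s = kin.displacement(amp, tau)
    u = (end - start) / amp
    return start[None, :] + s[:, None] * u[None, :], D


def synth_trace(
    sched: ScheduledTrial, cfg: SimConfig, rng: np.random.Generator
) -> tuple[Trial, TrialTruth]:
    """Generate one trial's sample stream and its ground truth.

    Gaze rests at the fixation point, launches a raised-cosine saccade toward
    the goal after a condition-drawn latency, then fixates the landing point;
    isotropic Gaussian measurement noise rides on every sample. A drawn
    latency whose saccade would overrun the trial is resampled (and logged).
    """
    assert cfg.latency is not None
    t = _sample_times(cfg, sched.end_ms, rng)
    n = len(t)

    if sched.jumps:  # grid task: a chase of target jumps
        pos = np.zeros((n, 2))
        cur = np.asarray(sched.target_pos, dtype=float)
        pos[:] = cur
        truth = TrialTruth(
            index=sched.index,
            condition=sched.condition,
            target_pos=sched.target_pos,
            goal_pos=sched.goal_pos,
            target_onset_ms=0.0,
            jumps=[(0.0, sched.target_pos)] + list(sched.jumps),
        )
        for t_jump, target in sched.jumps:
            target_a = np.asarray(target, dtype=float)
            lat = cfg.latency.draw(sched.condition, rng)
            onset = t_jump + lat
            land = target_a + (
                rng.normal(0.0, cfg.landing_noise_sd, 2)
                if cfg.landing_noise_sd > 0
                else 0.0
            )
            seg, D = _saccade_segment(cfg.kinematics, t, onset, cur, land)
            after = t >= onset
            pos[after] = seg[after]
            truth.jump_saccades.append((onset, onset + D, float(np.hypot(*(land - cur)))))
            cur = land
    else:
        start = np.zeros(2)
        goal = np.asarray(sched.goal_pos, dtype=float)
        for attempt in range(100):
            lat = cfg.latency.draw(sched.condition, rng)
            amp_nominal = float(np.hypot(*(goal - start)))
            D = cfg.kinematics.duration_ms(amp_nominal)
            if sched.target_on_ms + lat + D <= sched.end_ms - 50.0:
                break
            logger.info(
                "trial %d: latency %.0f ms overruns the trial; resampling",
                sched.index,
                lat,
            )
        land = goal + (
            rng.normal(0.0, cfg.landing_noise_sd, 2)
            if cfg.landing_noise_sd > 0
            else 0.0
        )
        onset = sched.target_on_ms + lat
        seg, D = _saccade_segment(cfg.kinematics, t, onset, start, land)
        pos = np.where((t >= onset)[:, None], seg, start[None, :])
        amp = float(np.hypot(*(land - start)))
        truth = TrialTruth(
            index=sched.index,
            condition=sched.condition,
            target_pos=sched.target_pos,
            goal_pos=sched.goal_pos,
            target_onset_ms=sched.target_on_ms,
            latency_ms=lat,
            saccade_onset_ms=onset,
            saccade_offset_ms=onset + D,
            amplitude_deg=amp,
            peak_velocity=cfg.kinematics.peak_velocity(amp),
        )

    if cfg.fixation_noise_sd > 0:
        pos = pos + rng.normal(0.0, cfg.fixation_noise_sd, pos.shape)

    keep = np.ones(n, dtype=bool)
    if cfg.frame_drop_prob > 0:
        keep = rng.random(n) >= cfg.frame_drop_prob
        keep[0] = True  # the recording's first frame defines t=0
    valid = _tracking_loss(cfg, n, rng)

    t_k, pos_k, valid_k = t[keep], pos[keep], valid[keep]
    # invalid samples carry no position information
    x = np.where(valid_k, pos_k[:, 0], np.nan)
    y = np.where(valid_k, pos_k[:, 1], np.nan)

    messages = [MessageEvent(0.0, f"TRIAL {sched.index} COND {sched.condition}")]
    if sched.jumps:
        for t_jump, (tx, ty) in sched.jumps:
            messages.append(MessageEvent(t_jump, f"TARGET_JUMP {tx:.4f} {ty:.4f}"))
    else:
        messages.append(MessageEvent(sched.fix_off_ms, "FIX_OFF"))
        tx, ty = sched.target_pos
        messages.append(
            MessageEvent(sched.target_on_ms, f"TARGET_ON {tx:.4f} {ty:.4f}")
        )
        messages.sort(key=lambda m: m.t)

    trial = Trial(
        t=t_k, x=x, y=y, valid=valid_k, messages=messages, index=sched.index
    )
    return trial, truth


def simulate_session(cfg: SimConfig) -> tuple[GazeRecording, list[TrialTruth]]:
    """Generate a complete session: schedule, traces, recording, truth."""
    rng = np.random.default_rng(cfg.seed)
    schedule = make_schedule(cfg, rng)
    trials: list[Trial] = []
    truths: list[TrialTruth] = []
    for sched in schedule:
        trial, truth = synth_trace(sched, cfg, rng)
        trials.append(trial)
        truths.append(truth)
    rec = GazeRecording(
        trials=trials, nominal_rate=cfg.nominal_rate, screen=cfg.screen
    )
    return rec, truths


# ---------------------------------------------------------------------------
# Feature-space and image-space synthesis


def synth_feature_stream(
    trial: Trial,
    true_model: CalibrationModel,
    pixel_noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the calibration map: gaze (deg) → camera features (U, V) px.

    Solves the true model's linear system for each valid sample, optionally
    adding camera-pixel noise. Raises on a singular model. Invalid samples
    yield NaN features.
    """
    m = true_model.matrix
    if abs(np.linalg.det(m)) < 1e-12:
        raise ValueError("true calibration model is singular")
    P = np.column_stack([trial.x, trial.y]) - true_model.offset[None, :]
    UV = np.full_like(P, np.nan)
    v = trial.valid
    UV[v] = np.linalg.solve(m, P[v].T).T
    if pixel_noise_sd > 0:
        if rng is None:
            raise ValueError("pixel noise requires an rng")
        UV[v] += rng.normal(0.0, pixel_noise_sd, UV[v].shape)
    return UV[:, 0], UV[:, 1]


CALIBRATION_3X3 = CalibrationSchedule(
    positions=[
        (x * 9.3, y * 6.6) for y in (1, 0, -1) for x in (-1, 0, 1)
    ],
    dwell_ms=1000.0,
    move_ms=0.0,
)


def synth_calibration_stream(
    schedule: CalibrationSchedule,
    true_model: CalibrationModel,
    rate_hz: float,
    fixation_noise_sd: float = 0.1,
    pixel_noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> list[CalibrationSample]:
    """Generate the raw calibration sample stream for a target schedule.

    While the target dwells at each position the simulated eye fixates it
    (with Gaussian positional noise); gaze is pushed backward through the true
    model to camera features, optionally with pixel noise. The stream covers
    the whole timeline, so window selection can be exercised realistically.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    dt = 1000.0 / rate_hz
    arrivals = schedule.arrival_times()
    out: list[CalibrationSample] = []
    m = true_model.matrix
    if abs(np.linalg.det(m)) < 1e-12:
        raise ValueError("true calibration model is singular")
    minv = np.linalg.inv(m)
    for pos, a in zip(schedule.positions, arrivals):
        n = int(schedule.dwell_ms / dt)
        ts = a + np.arange(n) * dt
        gaze = np.tile(np.asarray(pos, dtype=float), (n, 1))
        if fixation_noise_sd > 0:
            gaze = gaze + rng.normal(0.0, fixation_noise_sd, (n, 2))
        UV = (minv @ (gaze - true_model.offset[None, :]).T).T
        if pixel_noise_sd > 0:
            UV = UV + rng.normal(0.0, pixel_noise_sd, UV.shape)
        for t_i, (u, v) in zip(ts, UV):
            out.append(CalibrationSample(t=float(t_i), U=float(u), V=float(v), target=tuple(pos)))
    return out


def synth_image_sequence(
    U: np.ndarray,
    V: np.ndarray,
    render_cfg: Optional[RenderConfig] = None,
    pupil_center: tuple[float, float] = (160.0, 120.0),
    glint_off: Optional[Sequence[bool]] = None,
) -> list[np.ndarray]:
    """Render an ocular frame per feature sample.

    The pupil stays at a fixed frame position while the glint is displaced by
    (U, V); ``glint_off`` suppresses the glint on chosen frames to emulate
    unstable corneal reflection. Raises if any glint would leave the frame.
    """
    if render_cfg is None:
        render_cfg = RenderConfig()
    frames = []
    for i, (u, v) in enumerate(zip(U, V)):
        off = glint_off is not None and glint_off[i]
        cfg_i = replace(render_cfg, render_glint=not off)
        if render_cfg.seed is not None:
            cfg_i = replace(cfg_i, seed=render_cfg.seed + i)
        glint = (pupil_center[0] + float(u), pupil_center[1] + float(v))
        frames.append(render_eye_image(pupil_center, glint, cfg_i))
    return frames
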