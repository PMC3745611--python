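"""Linear gaze calibration: map camera features (U, V) to screen gaze (X, Y).

The model is the affine pair

    X = a_X·U + b_X·V + c_X
    Y = a_Y·U + b_Y·V + c_Y

fit by minimising the sum of squared distances between predicted gaze and the
fixated target over the calibration samples. That joint objective separates
into two independent linear regressions sharing one design matrix [U V 1], so
the optimum is computed in closed form by ordinary least squares.

Sample selection reproduces the two windows used in practice: dropping samples
within a guard interval around each target move (the eye is in flight), or
keeping only a window after the target arrives at a new position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "CalibrationModel",
    "CalibrationSample",
    "CalibrationSchedule",
    "FitReport",
    "select_valid_samples",
    "fit_calibration",
    "apply_calibration",
    "calibration_error",
]


@dataclass
class CalibrationModel:
    """Six coefficients of the affine (U,V) → (X,Y) map, degrees per pixel."""

    a_x: float
    b_x: float
    c_x: float
    a_y: float
    b_y: float
    c_y: float

    @property
    def matrix(self) -> np.ndarray:
        """The 2×2 linear part [[a_x, b_x], [a_y, b_y]]."""
        return np.array([[self.a_x, self.b_x], [self.a_y, self.b_y]])

    @property
    def offset(self) -> np.ndarray:
        return np.array([self.c_x, self.c_y])

    def is_usable(self, tol: float = 1e-12) -> bool:
        m = self.matrix
        return bool(
            np.all(np.isfinite([self.a_x, self.b_x, self.c_x, self.a_y, self.b_y, self.c_y]))
            and abs(np.linalg.det(m)) > tol
        )


@dataclass(frozen=True)
class CalibrationSample:
    """One calibration observation: time, camera features, fixated target."""

    t: float
    U: float
    V: float
    target: tuple[float, float]


@dataclass
class CalibrationSchedule:
    """Target presentation schedule.

    The target moves to ``positions[k]`` during ``move_ms`` (0 for a jump) and
    then dwells for ``dwell_ms``; position k's move starts at
    k·(move_ms + dwell_ms) and the target arrives move_ms later. At least
    three non-collinear positions are needed for an identifiable model.
    """

    positions: list[tuple[float, float]]
    dwell_ms: float = 1000.0
    move_ms: float = 0.0

    def arrival_times(self) -> np.ndarray:
        k = np.arange(len(self.positions))
        return k * (self.move_ms + self.dwell_ms) + self.move_ms

    def move_starts(self) -> np.ndarray:
        k = np.arange(len(self.positions))
        return k * (self.move_ms + self.dwell_ms)


def select_valid_samples(
    samples: Sequence[CalibrationSample],
    schedule: CalibrationSchedule,
    mode: Literal["exclusion_window", "arrival_window"] = "exclusion_window",
    exclude_ms: float = 200.0,
    window: tuple[float, float] = (200.0, 800.0),
) -> list[CalibrationSample]:
    """Select the calibration samples that fall in steady fixation.

    ``exclusion_window`` drops every sample within ``exclude_ms`` of any
    target motion (from move start to arrival, padded on both sides);
    ``arrival_window`` keeps only samples between ``window[0]`` and
    ``window[1]`` ms after each arrival. All interval comparisons are strict,
    so a sample lying exactly on a window edge is excluded.

    Raises ValueError if nothing survives.
    """
    arrivals = schedule.arrival_times()
    moves = schedule.move_starts()
    dwell_ends = arrivals + schedule.dwell_ms

    kept: list[CalibrationSample] = []
    if mode == "exclusion_window":
        # the end of the last dwell acts as a final target move (the target
        # disappears), so its guard interval applies there too
        guards = list(zip(moves, arrivals)) + [(dwell_ends[-1], dwell_ends[-1])]
        for s in samples:
            excluded = False
            for m0, a in guards:
                if m0 - exclude_ms <= s.t <= a + exclude_ms:
                    excluded = True
                    break
            in_session = moves[0] < s.t < dwell_ends[-1]
            if not excluded and in_session:
                kept.append(s)
    elif mode == "arrival_window":
        for s in samples:
            for a in arrivals:
                if a + window[0] < s.t < a + window[1]:
                    kept.append(s)
                    break
    else:
        raise ValueError(f"unknown selection mode {mode!r}")

    if not kept:
        raise ValueError("insufficient calibration data: no samples selected")
    return kept


@dataclass
class FitReport:
    """Goodness-of-fit of a calibration: SSE and per-target mean error (deg)."""

    sse: float
    per_target_error: dict[tuple[float, float], float] = field(default_factory=dict)
    overall_error: float = 0.0
    n_samples: int = 0


def _design(samples: Sequence[CalibrationSample]) -> tuple[np.ndarray, np.ndarray]:
    A = np.array([[s.U, s.V, 1.0] for s in samples])
    T = np.array([list(s.target) for s in samples])
    return A, T


def fit_calibration(
    samples: Sequence[CalibrationSample],
) -> tuple[CalibrationModel, FitReport]:
    """Closed-form least-squares fit of the calibration model.

    Requires at least three samples with non-collinear (U, V); a rank-deficient
    design raises ValueError.
    """
    if len(samples) < 3:
        raise ValueError("calibration requires at least 3 samples")
    A, T = _design(samples)
    if np.linalg.matrix_rank(A) < 3:
        raise ValueError("calibration design is rank-deficient (collinear U,V)")
    coef, _, _, _ = np.linalg.lstsq(A, T, rcond=None)
    model = CalibrationModel(
        a_x=float(coef[0, 0]),
        b_x=float(coef[1, 0]),
        c_x=float(coef[2, 0]),
        a_y=float(coef[0, 1]),
        b_y=float(coef[1, 1]),
        c_y=float(coef[2, 1]),
    )
    pred = A @ coef
    resid = pred - T
    sse = float(np.sum(resid**2))
    per_target, overall = calibration_error(model, samples)
    report = FitReport(
        sse=sse,
        per_target_error=per_target,
        overall_error=overall,
        n_samples=len(samples),
    )
    return model, report


def apply_calibration(model: CalibrationModel, U, V) -> tuple:
    """Map features to screen gaze: exactly (a_x·U + b_x·V + c_x, ·)."""
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    x = model.a_x * U + model.b_x * V + model.c_x
    y = model.a_y * U + model.b_y * V + model.c_y
    if x.ndim == 0:
        return (float(x), float(y))
    return (x, y)


def calibration_error(
    model: CalibrationModel, samples: Sequence[CalibrationSample]
) -> tuple[dict[tuple[float, float], float], float]:
    """Mean Euclidean distance (deg) between predicted gaze and target.

    Returns per-target means and their unweighted average across targets
    (the "average of the nine locations" criterion used to accept a
    calibration in practice).
    """
    groups: dict[tuple[float, float], list[float]] = {}
    for s in samples:
        px, py = apply_calibration(model, s.U, s.V)
        d = float(np.hypot(px - s.target[0], py - s.target[1]))
        groups.setdefault(tuple(s.target), []).append(d)
    per_target = {k: float(np.mean(v)) for k, v in groups.items()}
    overall = float(np.mean(list(per_target.values()))) if per_target else float("nan")
    return per_target, overall
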