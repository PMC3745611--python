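"""Shared fixtures: small synthetic trials and recordings."""

import numpy as np
import pytest

from gazekit import (
    GazeRecording,
    MessageEvent,
    ScreenGeometry,
    Trial,
)


@pytest.fixture
def screen() -> ScreenGeometry:
    return ScreenGeometry(
        viewing_distance_cm=57.0, pixels_per_cm=28.0, resolution=(1920, 1080)
    )


def make_uniform_trial(
    duration_ms: float,
    rate_hz: float,
    x=0.0,
    y=0.0,
    valid=None,
    messages=(),
    index: int = 1,
) -> Trial:
    """A trial on an exact uniform time grid with given positions."""
    dt = 1000.0 / rate_hz
    n = int(duration_ms / dt) + 1
    t = np.arange(n) * dt
    x = np.broadcast_to(np.asarray(x, dtype=float), (n,)).copy()
    y = np.broadcast_to(np.asarray(y, dtype=float), (n,)).copy()
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return Trial(t=t, x=x, y=y, valid=valid, messages=list(messages), index=index)


@pytest.fixture
def tiny_recording(screen) -> GazeRecording:
    """One trial, three samples, one message."""
    trial = Trial(
        t=np.array([0.0, 8.33, 16.66]),
        x=np.array([0.1, 0.2, 0.3]),
        y=np.array([-0.1, 0.0, 0.1]),
        valid=np.array([True, True, False]),
        messages=[MessageEvent(5.0, "target on, left")],
        index=1,
    )
    return GazeRecording(trials=[trial], nominal_rate=120.0, screen=screen)


def random_recording(rng: np.random.Generator, n_trials: int, screen: ScreenGeometry) -> GazeRecording:
    trials = []
    for i in range(1, n_trials + 1):
        n = int(rng.integers(2, 40))
        t = np.cumsum(rng.uniform(0.5, 10.0, n))
        messages = sorted(
            (
                MessageEvent(float(rng.uniform(0, t[-1])), f"msg {i},{j}\\esc")
                for j in range(int(rng.integers(0, 3)))
            ),
            key=lambda m: m.t,
        )
        trials.append(
            Trial(
                t=t,
                x=rng.normal(0, 5, n),
                y=rng.normal(0, 5, n),
                valid=rng.random(n) > 0.1,
                messages=messages,
                index=i,
            )
        )
    return GazeRecording(trials=trials, nominal_rate=250.0, screen=screen)
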