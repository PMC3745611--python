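"""Data model for gaze recordings: trials, samples, messages, CSV persistence.

All gaze positions are held in degrees of visual angle with the origin at the
screen center, +x rightward and +y upward. Pixels appear only at the I/O edge,
through :func:`pixels_to_degrees` / :func:`degrees_to_pixels`. Tracking loss is
kept in-band as ``valid=False`` samples; no interpolation is ever performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GazeSample",
    "MessageEvent",
    "Trial",
    "ScreenGeometry",
    "GazeRecording",
    "IntersampleStats",
    "ParseError",
    "ValidationError",
    "pixels_to_degrees",
    "degrees_to_pixels",
    "intersample_stats",
    "read_recording",
    "write_recording",
]


class ParseError(ValueError):
    """Raised when a recording file cannot be parsed; names the line number."""


class ValidationError(ValueError):
    """Raised when a recording violates a structural invariant."""


@dataclass(frozen=True)
class GazeSample:
    """A single gaze sample.

    ``t`` is milliseconds from recording start; ``x``/``y`` are degrees of
    visual angle. When ``valid`` is False the eye could not be located in the
    camera image and ``x``/``y`` carry no information (stored as NaN).
    """

    t: float
    x: float
    y: float
    valid: bool = True


@dataclass(frozen=True)
class MessageEvent:
    """A timestamped text message (stimulus onset, keypress, ...)."""

    t: float
    text: str


@dataclass
class Trial:
    """One recording trial: sample arrays plus its messages.

    Samples are stored as parallel numpy arrays (``t``, ``x``, ``y``,
    ``valid``) for vectorised downstream processing; :meth:`samples` yields
    them as :class:`GazeSample` objects.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    messages: list[MessageEvent] = field(default_factory=list)
    index: int = 1

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValidationError("sample arrays must have equal length")
        if n and (not np.all(np.isfinite(self.t)) or np.any(self.t < 0)):
            raise ValidationError("timestamps must be finite and non-negative")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValidationError(
                f"trial {self.index}: sample timestamps must be strictly increasing"
            )
        ts = [m.t for m in self.messages]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValidationError(
                f"trial {self.index}: messages must be in nondecreasing time order"
            )

    @classmethod
    def from_samples(
        cls,
        samples: Iterable[GazeSample],
        messages: Sequence[MessageEvent] = (),
        index: int = 1,
    ) -> "Trial":
        ss = list(samples)
        return cls(
            t=np.array([s.t for s in ss], dtype=float),
            x=np.array([s.x for s in ss], dtype=float),
            y=np.array([s.y for s in ss], dtype=float),
            valid=np.array([s.valid for s in ss], dtype=bool),
            messages=list(messages),
            index=index,
        )

    def samples(self) -> Iterator[GazeSample]:
        for t, x, y, v in zip(self.t, self.x, self.y, self.valid):
            yield GazeSample(float(t), float(x), float(y), bool(v))

    def __len__(self) -> int:
        return len(self.t)

    @property
    def is_empty(self) -> bool:
        """True when the trial holds fewer than two valid samples."""
        return int(np.count_nonzero(self.valid)) < 2


@dataclass
class ScreenGeometry:
    """Display geometry: viewing distance (cm), pixel pitch and resolution.

    The origin of the degree coordinate system is the screen center; +x points
    right and +y points up (screen pixel rows increase downward).
    """

    viewing_distance_cm: float
    pixels_per_cm: float
    resolution: tuple[int, int]  # (width px, height px)

    def __post_init__(self) -> None:
        w, h = self.resolution
        if not (
            self.viewing_distance_cm > 0
            and self.pixels_per_cm > 0
            and w > 0
            and h > 0
        ):
            raise ValidationError("screen geometry values must be strictly positive")


@dataclass
class GazeRecording:
    """A full session: ordered trials sharing one geometry and sampling rate."""

    trials: list[Trial]
    nominal_rate: float
    screen: ScreenGeometry
    units: str = "deg"

    def __post_init__(self) -> None:
        if self.nominal_rate <= 0:
            raise ValidationError("nominal_rate must be positive")


# ---------------------------------------------------------------------------
# Unit conversion


def pixels_to_degrees(
    p: tuple[float, float], geom: ScreenGeometry
) -> tuple[float, float]:
    """Convert a screen-pixel position to degrees of visual angle.

    Uses the exact arctangent mapping ``deg = atan(offset_cm / distance_cm)``
    per axis, with the screen center as the angular origin and +y up.
    """
    w, h = geom.resolution
    dx_cm = (p[0] - w / 2.0) / geom.pixels_per_cm
    dy_cm = (h / 2.0 - p[1]) / geom.pixels_per_cm  # pixel rows grow downward
    d = geom.viewing_distance_cm
    return (
        math.degrees(math.atan(dx_cm / d)),
        math.degrees(math.atan(dy_cm / d)),
    )


def degrees_to_pixels(
    deg: tuple[float, float], geom: ScreenGeometry
) -> tuple[float, float]:
    """Inverse of :func:`pixels_to_degrees`."""
    w, h = geom.resolution
    d = geom.viewing_distance_cm
    dx_cm = d * math.tan(math.radians(deg[0]))
    dy_cm = d * math.tan(math.radians(deg[1]))
    return (
        w / 2.0 + dx_cm * geom.pixels_per_cm,
        h / 2.0 - dy_cm * geom.pixels_per_cm,
    )


# ---------------------------------------------------------------------------
# Timestamp diagnostics


@dataclass(frozen=True)
class IntersampleStats:
    """Summary of consecutive timestamp differences (ms) within a trial."""

    mean: float
    sd: float
    p0_5: float
    p99_5: float
    min: float
    max: float
    n_intervals: int


def intersample_stats(trial: Trial) -> IntersampleStats:
    """Summarise the intersample-interval distribution of one trial.

    Intervals are taken over *all* consecutive samples, valid and invalid
    alike: a tracking-loss sample still carries a camera timestamp, so it
    still constrains timing. Percentiles use linear interpolation between
    order statistics. Requires at least two samples.
    """
    if len(trial) < 2:
        raise ValidationError("intersample_stats requires at least 2 samples")
    dt = np.diff(trial.t)
    lo, hi = np.percentile(dt, [0.5, 99.5])
    return IntersampleStats(
        mean=float(np.mean(dt)),
        sd=float(np.std(dt, ddof=1)) if len(dt) > 1 else 0.0,
        p0_5=float(lo),
        p99_5=float(hi),
        min=float(np.min(dt)),
        max=float(np.max(dt)),
        n_intervals=len(dt),
    )


# ---------------------------------------------------------------------------
# CSV persistence
#
# Dialect (UTF-8, comma separated, one record per line):
#   #META,key,value           header; keys: nominal_rate, viewing_distance_cm,
#                             pixels_per_cm, resolution (WxH)
#   #TRIAL_START,<index> / #TRIAL_END,<index>
#   S,<t_ms>,<x_deg>,<y_deg>,<valid 0|1>
#   M,<t_ms>,<text>           commas in text escaped as '\,'
# Floats are written with repr() (shortest round-trip form), so
# read(write(rec)) is bit-exact for finite values. Invalid samples write NaN
# coordinates as 'nan'.


def _fmt(v: float) -> str:
    return repr(float(v))


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace(",", "\\,")


def _unescape(text: str) -> str:
    out: list[str] = []
    it = iter(text)
    for ch in it:
        if ch == "\\":
            nxt = next(it, "")
            out.append(nxt)
        else:
            out.append(ch)
    return "".join(out)


def _split_escaped(line: str) -> list[str]:
    """Split on commas not preceded by a backslash escape."""
    fields: list[str] = []
    cur: list[str] = []
    escaped = False
    for ch in line:
        if escaped:
            cur.append(ch)
            escaped = False
        elif ch == "\\":
            cur.append(ch)
            escaped = True
        elif ch == ",":
            fields.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    fields.append("".join(cur))
    return fields


def write_recording(rec: GazeRecording, path) -> None:
    """Serialise a recording to the package's CSV dialect."""
    w, h = rec.screen.resolution
    lines = [
        f"#META,nominal_rate,{_fmt(rec.nominal_rate)}",
        f"#META,viewing_distance_cm,{_fmt(rec.screen.viewing_distance_cm)}",
        f"#META,pixels_per_cm,{_fmt(rec.screen.pixels_per_cm)}",
        f"#META,resolution,{w}x{h}",
    ]
    for trial in rec.trials:
        lines.append(f"#TRIAL_START,{trial.index}")
        # samples and messages interleaved by timestamp (messages after
        # samples at equal t) so the file reads chronologically
        rows: list[tuple[float, int, str]] = []
        for t, x, y, v in zip(trial.t, trial.x, trial.y, trial.valid):
            rows.append(
                (float(t), 0, f"S,{_fmt(t)},{_fmt(x)},{_fmt(y)},{1 if v else 0}")
            )
        for m in trial.messages:
            rows.append((float(m.t), 1, f"M,{_fmt(m.t)},{_escape(m.text)}"))
        rows.sort(key=lambda r: (r[0], r[1]))
        lines.extend(r[2] for r in rows)
        lines.append(f"#TRIAL_END,{trial.index}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_recording(path) -> GazeRecording:
    """Parse a recording from the package's CSV dialect.

    Raises :class:`ParseError` (naming the offending line) on malformed rows
    and :class:`ValidationError` on nonmonotonic timestamps within a trial.
    """
    meta: dict[str, str] = {}
    trials: list[Trial] = []
    cur: dict | None = None

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = _split_escaped(line)
            tag = fields[0]
            try:
                if tag == "#META":
                    if len(fields) != 3:
                        raise ValueError("META needs key,value")
                    meta[fields[1]] = fields[2]
                elif tag == "#TRIAL_START":
                    if cur is not None:
                        raise ValueError("nested TRIAL_START")
                    cur = {
                        "index": int(fields[1]),
                        "t": [],
                        "x": [],
                        "y": [],
                        "valid": [],
                        "messages": [],
                    }
                elif tag == "#TRIAL_END":
                    if cur is None or int(fields[1]) != cur["index"]:
                        raise ValueError("TRIAL_END without matching TRIAL_START")
                    trials.append(
                        Trial(
                            t=np.array(cur["t"], dtype=float),
                            x=np.array(cur["x"], dtype=float),
                            y=np.array(cur["y"], dtype=float),
                            valid=np.array(cur["valid"], dtype=bool),
                            messages=cur["messages"],
                            index=cur["index"],
                        )
                    )
                    cur = None
                elif tag == "S":
                    if cur is None:
                        raise ValueError("sample row outside a trial")
                    if len(fields) != 5 or fields[4] not in ("0", "1"):
                        raise ValueError("sample row needs S,t,x,y,valid")
                    cur["t"].append(float(fields[1]))
                    cur["x"].append(float(fields[2]))
                    cur["y"].append(float(fields[3]))
                    cur["valid"].append(fields[4] == "1")
                elif tag == "M":
                    if cur is None:
                        raise ValueError("message row outside a trial")
                    if len(fields) != 3:
                        raise ValueError("message row needs M,t,text")
                    cur["messages"].append(
                        MessageEvent(float(fields[1]), _unescape(fields[2]))
                    )
                else:
                    raise ValueError(f"unknown record tag {tag!r}")
            except ValidationError:
                raise
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc

    if cur is not None:
        raise ParseError(f"unterminated trial {cur['index']} at end of file")

    required = ("nominal_rate", "viewing_distance_cm", "pixels_per_cm", "resolution")
    missing = [k for k in required if k not in meta]
    if missing:
        raise ParseError(f"missing #META keys: {', '.join(missing)}")
    try:
        rw, rh = meta["resolution"].lower().split("x")
        screen = ScreenGeometry(
            viewing_distance_cm=float(meta["viewing_distance_cm"]),
            pixels_per_cm=float(meta["pixels_per_cm"]),
            resolution=(int(rw), int(rh)),
        )
    except (ValueError, ValidationError) as exc:
        raise ParseError(f"bad #META values: {exc}") from exc

    return GazeRecording(
        trials=trials, nominal_rate=float(meta["nominal_rate"]), screen=screen
    )
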