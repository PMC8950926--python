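"""Sensor-session data model and on-disk log dialect.

A session holds one walking trial recorded by the rollator's three sensor
streams: 360-degree planar laser scans (~5.5 Hz), cumulative rear-wheel
encoder displacements (600 Hz, 0.1 mm ticks) and handlebar load readings
(2.5 Hz, 5.5 g resolution), plus the static frame graph and user metadata.

On disk a session is a directory of human-inspectable text files:

* ``meta.json``     -- session id, user weight, duration, seed
* ``frames.json``   -- static frame poses relative to ``base_footprint``
* ``laser.jsonl``   -- one JSON object per scan; invalid returns as ``"inf"``
* ``encoders.csv``  -- header ``t,left_disp,right_disp``
* ``loads.csv``     -- header ``t,left_load,right_load``

All numeric text is written with ``repr`` (shortest round-tripping decimal),
so ``read_session(write_session(s))`` is bit-exact.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .frames import BASE_FRAME, FrameGraph, default_frame_graph

__all__ = [
    "ENCODER_TICK",
    "LOAD_RESOLUTION",
    "GRAVITY",
    "SessionFormatError",
    "ValidationError",
    "LaserScan",
    "EncoderStream",
    "LoadStream",
    "SensorSession",
    "read_session",
    "write_session",
    "resample_to_timeline",
]

#: Encoder tick size: 0.1 mm of rim displacement.
ENCODER_TICK = 1e-4
#: Handlebar load resolution: 5.5 g.
LOAD_RESOLUTION = 0.0055
#: Standard gravity, used to convert kg-force to newtons.
GRAVITY = 9.80665


class SessionFormatError(RuntimeError):
    """A session directory is missing a stream file or is malformed."""


class ValidationError(ValueError):
    """Stream contents violate an invariant (ordering, ranges, units)."""


def _require_strictly_increasing(t: np.ndarray, name: str) -> None:
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"{name}: timestamps not strictly increasing at index {bad[0] + 1}"
        )


@dataclass
class LaserScan:
    """One 360-degree planar scan.

    ``ranges[i]`` is the range along ``angle_start + i * angle_increment``
    (radians, counter-clockwise, in the ``frame`` coordinate system);
    invalid/absent returns are ``+inf``.
    """

    t: float
    angle_start: float
    angle_increment: float
    ranges: np.ndarray
    frame: str = "laser"

    def __post_init__(self):
        self.ranges = np.asarray(self.ranges, dtype=float)
        if self.ranges.size < 1:
            raise ValidationError("laser scan with empty ranges")
        coverage = self.ranges.size * self.angle_increment
        if abs(coverage - 2 * math.pi) > self.angle_increment:
            raise ValidationError(
                "laser scan does not cover 2*pi within one increment"
            )

    @property
    def angles(self) -> np.ndarray:
        return self.angle_start + self.angle_increment * np.arange(self.ranges.size)

    def equals(self, other: "LaserScan") -> bool:
        return (
            self.t == other.t
            and self.angle_start == other.angle_start
            and self.angle_increment == other.angle_increment
            and self.frame == other.frame
            and np.array_equal(self.ranges, other.ranges)
        )


@dataclass
class EncoderStream:
    """Cumulative rim displacement of each rear wheel, in meters."""

    t: np.ndarray
    left_disp: np.ndarray
    right_disp: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.left_disp = np.asarray(self.left_disp, dtype=float)
        self.right_disp = np.asarray(self.right_disp, dtype=float)

    def validate(self) -> None:
        if self.t.size == 0:
            raise ValidationError("encoder stream is empty")
        _require_strictly_increasing(self.t, "encoders")
        for name, d in (("left_disp", self.left_disp), ("right_disp", self.right_disp)):
            frac = np.abs(d / ENCODER_TICK - np.round(d / ENCODER_TICK))
            if np.any(frac > 1e-6):
                raise ValidationError(
                    f"encoders.{name}: values are not multiples of the "
                    f"{ENCODER_TICK} m tick"
                )

    def equals(self, other: "EncoderStream") -> bool:
        return (
            np.array_equal(self.t, other.t)
            and np.array_equal(self.left_disp, other.left_disp)
            and np.array_equal(self.right_disp, other.right_disp)
        )


@dataclass
class LoadStream:
    """Handlebar loads in kg-force, one column per handle."""

    t: np.ndarray
    left_load: np.ndarray
    right_load: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.left_load = np.asarray(self.left_load, dtype=float)
        self.right_load = np.asarray(self.right_load, dtype=float)

    @property
    def total(self) -> np.ndarray:
        return self.left_load + self.right_load

    def validate(self) -> None:
        if self.t.size == 0:
            raise ValidationError("load stream is empty")
        _require_strictly_increasing(self.t, "loads")
        if np.any(self.left_load < 0) or np.any(self.right_load < 0):
            raise ValidationError("loads: negative handle load")
        for name, v in (("left_load", self.left_load), ("right_load", self.right_load)):
            frac = np.abs(v / LOAD_RESOLUTION - np.round(v / LOAD_RESOLUTION))
            if np.any(frac > 1e-6):
                raise ValidationError(
                    f"loads.{name}: values are not multiples of the "
                    f"{LOAD_RESOLUTION} kg resolution"
                )

    def equals(self, other: "LoadStream") -> bool:
        return (
            np.array_equal(self.t, other.t)
            and np.array_equal(self.left_load, other.left_load)
            and np.array_equal(self.right_load, other.right_load)
        )


@dataclass
class SensorSession:
    """One walking trial: three sensor streams plus frames and metadata."""

    laser: list[LaserScan]
    encoders: EncoderStream
    loads: LoadStream
    frames: FrameGraph = field(default_factory=default_frame_graph)
    user_weight: float = 70.0
    duration: float = 60.0
    session_id: str = "session"
    seed: int | None = None

    def validate(self) -> None:
        if not self.laser:
            raise ValidationError("laser stream is empty")
        laser_t = np.array([s.t for s in self.laser])
        _require_strictly_increasing(laser_t, "laser")
        self.encoders.validate()
        self.loads.validate()
        for name, t in (
            ("laser", laser_t),
            ("encoders", self.encoders.t),
            ("loads", self.loads.t),
        ):
            if t[0] < -1e-12 or t[-1] > self.duration + 1e-9:
                raise ValidationError(
                    f"{name}: timestamps outside [0, {self.duration}]"
                )
        if self.user_weight <= 0:
            raise ValidationError("user_weight must be positive")

    def equals(self, other: "SensorSession") -> bool:
        return (
            len(self.laser) == len(other.laser)
            and all(a.equals(b) for a, b in zip(self.laser, other.laser))
            and self.encoders.equals(other.encoders)
            and self.loads.equals(other.loads)
            and self.frames == other.frames
            and self.user_weight == other.user_weight
            and self.duration == other.duration
            and self.session_id == other.session_id
            and self.seed == other.seed
        )


# ---------------------------------------------------------------------------
# on-disk dialect


def _encode_range(r: float):
    return "inf" if math.isinf(r) else r


def _decode_range(r) -> float:
    return math.inf if r == "inf" else float(r)


def write_session(session: SensorSession, path: str | Path) -> None:
    """Write a session directory (see module docstring for the layout)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    meta = {
        "session_id": session.session_id,
        "user_weight": session.user_weight,
        "duration": session.duration,
        "seed": session.seed,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1) + "\n")
    (path / "frames.json").write_text(
        json.dumps(session.frames.to_dict(), indent=1) + "\n"
    )

    with open(path / "laser.jsonl", "w") as fh:
        for scan in session.laser:
            rec = {
                "t": scan.t,
                "angle_start": scan.angle_start,
                "angle_increment": scan.angle_increment,
                "frame": scan.frame,
                "ranges": [_encode_range(r) for r in scan.ranges],
            }
            fh.write(json.dumps(rec) + "\n")

    _write_csv(
        path / "encoders.csv",
        ("t", "left_disp", "right_disp"),
        (session.encoders.t, session.encoders.left_disp, session.encoders.right_disp),
    )
    _write_csv(
        path / "loads.csv",
        ("t", "left_load", "right_load"),
        (session.loads.t, session.loads.left_load, session.loads.right_load),
    )


def _write_csv(path: Path, header: tuple[str, ...], cols) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for row in zip(*cols):
            w.writerow([repr(float(v)) for v in row])


def _read_csv(path: Path, header: tuple[str, ...]) -> tuple[np.ndarray, ...]:
    if not path.exists():
        raise SessionFormatError(f"missing stream file {path.name}")
    with open(path, newline="") as fh:
        r = csv.reader(fh)
        got = tuple(next(r, []))
        if got != header:
            raise SessionFormatError(
                f"{path.name}: expected header {','.join(header)}"
            )
        rows = [[float(v) for v in row] for row in r if row]
    if not rows:
        return tuple(np.empty(0) for _ in header)
    arr = np.array(rows, dtype=float)
    return tuple(arr[:, i] for i in range(len(header)))


def read_session(path: str | Path) -> SensorSession:
    """Read and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise SessionFormatError("missing metadata file meta.json")
    meta = json.loads(meta_path.read_text())

    frames_path = path / "frames.json"
    if not frames_path.exists():
        raise SessionFormatError("missing stream file frames.json")
    frames = FrameGraph.from_dict(json.loads(frames_path.read_text()))

    laser_path = path / "laser.jsonl"
    if not laser_path.exists():
        raise SessionFormatError("missing stream file laser.jsonl")
    scans = []
    with open(laser_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            scans.append(
                LaserScan(
                    t=rec["t"],
                    angle_start=rec["angle_start"],
                    angle_increment=rec["angle_increment"],
                    ranges=np.array([_decode_range(r) for r in rec["ranges"]]),
                    frame=rec.get("frame", "laser"),
                )
            )

    et, eld, erd = _read_csv(path / "encoders.csv", ("t", "left_disp", "right_disp"))
    lt, lll, lrl = _read_csv(path / "loads.csv", ("t", "left_load", "right_load"))

    session = SensorSession(
        laser=scans,
        encoders=EncoderStream(et, eld, erd),
        loads=LoadStream(lt, lll, lrl),
        frames=frames,
        user_weight=float(meta["user_weight"]),
        duration=float(meta["duration"]),
        session_id=str(meta.get("session_id", "session")),
        seed=meta.get("seed"),
    )
    session.validate()
    return session


# ---------------------------------------------------------------------------
# resampling


def resample_to_timeline(
    t: np.ndarray,
    values: np.ndarray,
    rate: float,
    method: str = "hold",
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a timestamped stream onto a uniform timeline.

    The output timeline starts at ``t[0]`` with spacing ``1/rate`` and never
    extends beyond ``t[-1]`` (no extrapolation).  ``hold`` carries the last
    observation forward; ``linear`` interpolates.  ``values`` may be 1-D or
    (n, k); columns are resampled independently.
    """
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValidationError("resampling needs at least 2 samples")
    if rate <= 0:
        raise ValidationError("rate must be positive")
    if method not in ("hold", "linear"):
        raise ValidationError(f"unknown resampling method {method!r}")

    n_out = int(np.floor((t[-1] - t[0]) * rate)) + 1
    t_out = t[0] + np.arange(n_out) / rate

    def _one(col: np.ndarray) -> np.ndarray:
        if method == "linear":
            return np.interp(t_out, t, col)
        idx = np.searchsorted(t, t_out, side="right") - 1
        return col[np.clip(idx, 0, t.size - 1)]

    if values.ndim == 1:
        return t_out, _one(values)
    out = np.column_stack([_one(values[:, j]) for j in range(values.shape[1])])
    return t_out, out
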