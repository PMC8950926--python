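"""Synthetic walking trials with ground truth.

Generates :class:`~rollagait.session.SensorSession` objects that emulate a
user walking behind the rollator: the gait cycle alternates double-support
transitions with single-support phases (one leg planted, the other
swinging), the body and rollator advance one step length per step, and the
three sensor streams are rendered with their hardware rates and
quantization (600 Hz encoders at 0.1 mm ticks, 2.5 Hz handle loads at
5.5 g, ~5.5 Hz laser with Gaussian range noise).

Gait model
----------
Heel strikes alternate sides; the step ending with a side-``s`` strike lasts
that side's step time (60/cadence scaled by the per-side asymmetry
multiplier).  Each step begins with a double-support interval occupying
``1 - single_support_fraction`` of the step, after which the contralateral
foot swings until its own strike.  The stance foot is fixed in world
coordinates; the swinging foot travels between consecutive same-side
footprints (one stride length) with a raised-cosine longitudinal velocity
profile, so velocity and acceleration vanish at lift-off and contact.

Handlebar loads oscillate around ``handle_support_mean``: when a heel
contacts, the load difference swings toward that side, peaking a quarter
step after contact, with amplitude ``handle_modulation``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .frames import FrameGraph, RigidTransform2D, default_frame_graph
from .session import (
    ENCODER_TICK,
    LOAD_RESOLUTION,
    EncoderStream,
    LaserScan,
    LoadStream,
    SensorSession,
    ValidationError,
)

__all__ = [
    "PathSegment",
    "SideFactors",
    "SimulationConfig",
    "GroundTruth",
    "GaitTimeline",
    "simulate_session",
    "leg_trajectory",
    "render_laser_scan",
    "synth_handle_loads",
]

#: Longitudinal foot position in the body/base frame at heel contact (m).
#: Negative: the user walks behind the rear axle, inside the detection area.
FOOT_CONTACT_X = -0.30
#: Lateral foot placement in the body frame (m), left positive.
FOOT_LATERAL_Y = 0.12


@dataclass(frozen=True)
class PathSegment:
    """A constant-curvature piece of the walked path."""

    duration: float  # s
    omega: float = 0.0  # rad/s, positive = left turn


@dataclass(frozen=True)
class SideFactors:
    """Per-side multipliers; 1.0 on both sides means symmetric gait."""

    left: float = 1.0
    right: float = 1.0

    def get(self, side: str) -> float:
        return self.left if side == "left" else self.right


@dataclass
class SimulationConfig:
    """Parameters of one synthetic trial.

    Defaults emulate a mildly impaired rollator user on a straight 60 s
    walk: cadence 95 steps/min, 0.35 m steps, 62% of the cycle in single
    support, 10 kg-force mean handle support with a 1.5 kg side-to-side
    modulation synchronized to heel contacts.
    """

    user_weight: float = 70.0  # kg
    cadence: float = 95.0  # steps/min
    step_length: float = 0.35  # m
    single_support_fraction: float = 0.62
    handle_support_mean: float = 10.0  # kg-force, both handles combined
    handle_modulation: float = 1.5  # kg-force oscillation amplitude
    step_time_asymmetry: SideFactors = field(default_factory=SideFactors)
    step_length_asymmetry: SideFactors = field(default_factory=SideFactors)
    load_asymmetry: SideFactors = field(default_factory=SideFactors)
    #: total-load multiplier during each side's single-support phase;
    #: >1 on a side emulates a user unloading that (affected) support leg
    #: onto the handlebars.
    stance_load_factor: SideFactors = field(default_factory=SideFactors)
    path: tuple[PathSegment, ...] = (PathSegment(60.0, 0.0),)
    encoder_rate: float = 600.0  # Hz
    load_rate: float = 2.5  # Hz
    laser_rate: float = 5.5  # Hz
    laser_angular_increment: float = math.radians(1.0)
    laser_range_max: float = 6.0  # m
    laser_noise_sd: float = 0.01  # m
    leg_radius: float = 0.06  # m
    dropout_prob: float = 0.02  # P(one leg occluded in a scan)
    wheelbase: float = 0.55  # m, rear-wheel separation
    seed: int = 0

    @property
    def duration(self) -> float:
        return sum(seg.duration for seg in self.path)

    @property
    def base_speed(self) -> float:
        """Nominal body speed: one step length per step."""
        return self.step_length * self.cadence / 60.0

    def validate(self) -> None:
        if self.cadence <= 0:
            raise ValidationError("cadence must be positive")
        if not 0 < self.single_support_fraction < 1:
            raise ValidationError("single_support_fraction must be in (0, 1)")
        if self.handle_support_mean >= self.user_weight:
            raise ValidationError("handle support exceeds user weight")
        for name in ("encoder_rate", "load_rate", "laser_rate"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.duration <= 0:
            raise ValidationError("path must have positive total duration")
        # peak swing speed of a raised-cosine profile is 2 * stride / swing time
        step_t = 60.0 / self.cadence
        worst_stride = 2 * self.step_length * max(
            self.step_length_asymmetry.left, self.step_length_asymmetry.right
        )
        worst_swing = self.single_support_fraction * step_t * min(
            self.step_time_asymmetry.left, self.step_time_asymmetry.right
        )
        if 2 * worst_stride / worst_swing > 10.0:
            raise ValidationError(
                "infeasible gait: implied leg swing speed exceeds 10 m/s"
            )

    def to_dict(self) -> dict:
        return {
            "user_weight": self.user_weight,
            "cadence": self.cadence,
            "step_length": self.step_length,
            "single_support_fraction": self.single_support_fraction,
            "handle_support_mean": self.handle_support_mean,
            "handle_modulation": self.handle_modulation,
            "step_time_asymmetry": [self.step_time_asymmetry.left,
                                    self.step_time_asymmetry.right],
            "step_length_asymmetry": [self.step_length_asymmetry.left,
                                      self.step_length_asymmetry.right],
            "load_asymmetry": [self.load_asymmetry.left, self.load_asymmetry.right],
            "stance_load_factor": [self.stance_load_factor.left,
                                   self.stance_load_factor.right],
            "path": [[seg.duration, seg.omega] for seg in self.path],
            "encoder_rate": self.encoder_rate,
            "load_rate": self.load_rate,
            "laser_rate": self.laser_rate,
            "laser_angular_increment": self.laser_angular_increment,
            "laser_range_max": self.laser_range_max,
            "laser_noise_sd": self.laser_noise_sd,
            "leg_radius": self.leg_radius,
            "dropout_prob": self.dropout_prob,
            "wheelbase": self.wheelbase,
            "seed": self.seed,
        }

    @staticmethod
    def from_dict(d: dict) -> "SimulationConfig":
        kw = dict(d)
        for name in (
            "step_time_asymmetry",
            "step_length_asymmetry",
            "load_asymmetry",
            "stance_load_factor",
        ):
            if name in kw and not isinstance(kw[name], SideFactors):
                kw[name] = SideFactors(*kw[name])
        if "path" in kw:
            kw["path"] = tuple(
                seg if isinstance(seg, PathSegment) else PathSegment(*seg)
                for seg in kw["path"]
            )
        return SimulationConfig(**kw)


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    #: (t, side) heel contacts inside [0, duration].
    heel_strikes: list[tuple[float, str]]
    #: (t_start, t_end, label) partition of [0, duration];
    #: labels: single_left / single_right / double.
    support_phases: list[tuple[float, float, str]]
    #: Gait parameters implied by the configuration (NoS, CAD, SpT, ...).
    true_params: dict
    #: Per laser timestamp, true foot centers in the base frame.
    leg_positions: dict

    def single_support_fraction(self) -> float:
        single = sum(
            t1 - t0 for t0, t1, lab in self.support_phases if lab.startswith("single")
        )
        total = sum(t1 - t0 for t0, t1, _ in self.support_phases)
        return single / total

    def to_json(self) -> str:
        return json.dumps(
            {
                "heel_strikes": [[t, s] for t, s in self.heel_strikes],
                "support_phases": [[a, b, lab] for a, b, lab in self.support_phases],
                "true_params": self.true_params,
                "leg_positions": {
                    "t": list(self.leg_positions["t"]),
                    "left": [list(p) for p in self.leg_positions["left"]],
                    "right": [list(p) for p in self.leg_positions["right"]],
                },
            }
        )

    @staticmethod
    def from_json(text: str) -> "GroundTruth":
        d = json.loads(text)
        return GroundTruth(
            heel_strikes=[(t, s) for t, s in d["heel_strikes"]],
            support_phases=[(a, b, lab) for a, b, lab in d["support_phases"]],
            true_params=d["true_params"],
            leg_positions={
                "t": np.array(d["leg_positions"]["t"]),
                "left": np.array(d["leg_positions"]["left"]),
                "right": np.array(d["leg_positions"]["right"]),
            },
        )


def _raised_cosine_progress(phi: np.ndarray) -> np.ndarray:
    """Fraction of the swing displacement completed at swing phase ``phi``.

    Integral of the raised-cosine velocity profile v(phi) ~ 1 - cos(2*pi*phi);
    starts and ends with zero velocity and acceleration.
    """
    return phi - np.sin(2 * np.pi * phi) / (2 * np.pi)


class GaitTimeline:
    """Deterministic kinematic skeleton of a trial.

    Precomputes the heel-strike sequence (extended a few strides beyond
    [0, duration] so boundary queries are well defined), the piecewise
    constant body speed / turning speed, the body pose as a closed-form
    unicycle trajectory, and the world-frame footprint of every strike.
    """

    def __init__(self, config: SimulationConfig):
        config.validate()
        self.config = config
        f = config.single_support_fraction
        tr = config.duration
        base_step_t = 60.0 / config.cadence

        def step_time(side: str) -> float:
            return base_step_t * config.step_time_asymmetry.get(side)

        def step_len(side: str) -> float:
            return config.step_length * config.step_length_asymmetry.get(side)

        # --- strike sequence, left strike anchored at t = 0
        times = [0.0]
        sides = ["left"]
        while times[-1] <= tr + 3 * base_step_t:
            nxt = "right" if sides[-1] == "left" else "left"
            times.append(times[-1] + step_time(nxt))
            sides.append(nxt)
        # extend backwards so feet/phases are defined slightly before t = 0
        for _ in range(4):
            first = sides[0]  # interval ending at `first` has its step time
            times.insert(0, times[0] - step_time(first))
            sides.insert(0, "right" if first == "left" else "left")
        self.strike_t = np.array(times)
        self.strike_side = sides

        # --- piecewise body speed: one step length per step
        self.interval_v = np.array(
            [
                step_len(sides[k + 1]) / (times[k + 1] - times[k])
                for k in range(len(times) - 1)
            ]
        )

        # --- turning speed from path segments
        seg_bounds = np.concatenate(
            [[0.0], np.cumsum([seg.duration for seg in config.path])]
        )
        self._seg_bounds = seg_bounds
        self._seg_omega = np.array([seg.omega for seg in config.path])

        # --- pose breakpoints: strikes cross path-segment boundaries
        bps = np.unique(
            np.concatenate([self.strike_t, seg_bounds, [0.0]])
        )
        self._bps = bps
        self._bp_v = self._speed_at(0.5 * (bps[:-1] + bps[1:]))
        self._bp_w = self._omega_at(0.5 * (bps[:-1] + bps[1:]))
        self._bp_pose = self._integrate_breakpoints()
        self._bp_arc = np.concatenate(
            [[0.0], np.cumsum(self._bp_v * np.diff(bps))]
        )
        i0 = int(np.searchsorted(bps, 0.0))
        self._bp_arc -= self._bp_arc[i0]

        # --- world footprints at each strike
        self._footprints = np.array(
            [
                self._foot_world(self.pose(t), side)
                for t, side in zip(self.strike_t, self.strike_side)
            ]
        )
        # per-side strike indexing
        self._side_idx = {
            s: np.array([k for k, ss in enumerate(self.strike_side) if ss == s])
            for s in ("left", "right")
        }
        # swing of the foot striking at k starts f*step into the interval
        dt = np.diff(self.strike_t)
        self._swing_start = np.concatenate(
            [[self.strike_t[0]], self.strike_t[1:] - f * dt]
        )

    # -- piecewise profiles -------------------------------------------------

    def _speed_at(self, t: np.ndarray) -> np.ndarray:
        idx = np.clip(
            np.searchsorted(self.strike_t, t, side="right") - 1,
            0,
            self.interval_v.size - 1,
        )
        return self.interval_v[idx]

    def _omega_at(self, t: np.ndarray) -> np.ndarray:
        idx = np.clip(
            np.searchsorted(self._seg_bounds, t, side="right") - 1,
            0,
            self._seg_omega.size - 1,
        )
        return self._seg_omega[idx]

    def speed(self, t) -> np.ndarray:
        """Body/rollator translational speed (m/s), piecewise constant."""
        return self._speed_at(np.asarray(t, dtype=float))

    def omega(self, t) -> np.ndarray:
        """Turning speed (rad/s, positive = left), piecewise constant."""
        return self._omega_at(np.asarray(t, dtype=float))

    # -- pose ---------------------------------------------------------------

    def _integrate_breakpoints(self) -> np.ndarray:
        bps = self._bps
        n = bps.size
        pose = np.zeros((n, 3))
        i0 = int(np.searchsorted(bps, 0.0))
        for i in range(i0, n - 1):
            pose[i + 1] = _unicycle_step(
                pose[i], self._bp_v[i], self._bp_w[i], bps[i + 1] - bps[i]
            )
        for i in range(i0, 0, -1):
            pose[i - 1] = _unicycle_step(
                pose[i], self._bp_v[i - 1], self._bp_w[i - 1], bps[i - 1] - bps[i]
            )
        return pose

    def pose(self, t) -> np.ndarray:
        """Body pose(s) (x, y, theta) at time(s) ``t``."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.clip(
            np.searchsorted(self._bps, t_arr, side="right") - 1, 0, self._bps.size - 2
        )
        out = np.empty((t_arr.size, 3))
        for j, (ti, i) in enumerate(zip(t_arr, idx)):
            out[j] = _unicycle_step(
                self._bp_pose[i], self._bp_v[i], self._bp_w[i], ti - self._bps[i]
            )
        return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out

    def arc_length(self, t) -> np.ndarray:
        """Signed arc length along the path, zero at t = 0."""
        return np.interp(np.asarray(t, dtype=float), self._bps, self._bp_arc)

    def _foot_world(self, pose: np.ndarray, side: str) -> np.ndarray:
        y = FOOT_LATERAL_Y if side == "left" else -FOOT_LATERAL_Y
        tf = RigidTransform2D(pose[0], pose[1], pose[2])
        return tf.apply(np.array([FOOT_CONTACT_X, y]))

    # -- feet ---------------------------------------------------------------

    def foot_positions(self, t, side: str) -> np.ndarray:
        """World position(s) of one foot at time(s) ``t``.

        The foot rests on its last footprint until the swing toward the next
        same-side footprint begins, then follows a raised-cosine progress
        along the straight segment between the two footprints.
        """
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        s_idx = self._side_idx[side]
        s_times = self.strike_t[s_idx]
        pos_in_side = np.clip(
            np.searchsorted(s_times, t_arr, side="right") - 1, 0, s_idx.size - 2
        )
        cur = s_idx[pos_in_side]  # global index of last same-side strike
        nxt = s_idx[np.clip(pos_in_side + 1, 0, s_idx.size - 1)]
        p0 = self._footprints[cur]
        p1 = self._footprints[nxt]
        sw_start = self._swing_start[nxt]
        sw_end = self.strike_t[nxt]
        phi = np.clip((t_arr - sw_start) / (sw_end - sw_start), 0.0, 1.0)
        prog = _raised_cosine_progress(phi)[:, None]
        out = p0 + prog * (p1 - p0)
        return out[0] if np.ndim(t) == 0 else out

    def phase_label(self, t) -> np.ndarray:
        """Support-phase label(s) at time(s) ``t``."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.clip(
            np.searchsorted(self.strike_t, t_arr, side="right") - 1,
            0,
            self.strike_t.size - 2,
        )
        labels = np.empty(t_arr.size, dtype=object)
        for j, (ti, k) in enumerate(zip(t_arr, idx)):
            if ti < self._swing_start[k + 1]:
                labels[j] = "double"
            else:
                labels[j] = f"single_{self.strike_side[k]}"
        return labels[0] if np.ndim(t) == 0 else labels

    def support_phases(self) -> list[tuple[float, float, str]]:
        """Ground-truth phase partition of [0, duration]."""
        tr = self.config.duration
        edges: list[tuple[float, str]] = []
        for k in range(self.strike_t.size - 1):
            edges.append((self.strike_t[k], "double"))
            edges.append((self._swing_start[k + 1], f"single_{self.strike_side[k]}"))
        phases = []
        for (t0, lab), (t1, _) in zip(edges, edges[1:]):
            a, b = max(t0, 0.0), min(t1, tr)
            if b - a > 1e-9:  # drop zero-length slivers at the session edges
                phases.append((float(a), float(b), lab))
        return phases

    def heel_strikes(self) -> list[tuple[float, str]]:
        tr = self.config.duration
        return [
            (float(t), s)
            for t, s in zip(self.strike_t, self.strike_side)
            if -1e-12 <= t <= tr + 1e-12
        ]


def _unicycle_step(pose: np.ndarray, v: float, w: float, dt: float) -> np.ndarray:
    """Exact constant-(v, w) unicycle update (works for negative dt)."""
    x, y, th = pose
    if abs(w) < 1e-9:
        return np.array([x + v * dt * math.cos(th), y + v * dt * math.sin(th), th])
    th1 = th + w * dt
    r = v / w
    return np.array(
        [x + r * (math.sin(th1) - math.sin(th)), y - r * (math.cos(th1) - math.cos(th)), th1]
    )


# ---------------------------------------------------------------------------
# public operations


def leg_trajectory(
    t: float, config: SimulationConfig, timeline: GaitTimeline | None = None
) -> tuple[np.ndarray, np.ndarray, str]:
    """True world foot positions and phase label at time ``t``.

    Building the timeline is the expensive part; pass one in when querying
    many times.
    """
    tl = timeline or GaitTimeline(config)
    return (
        tl.foot_positions(t, "left"),
        tl.foot_positions(t, "right"),
        str(tl.phase_label(t)),
    )


def render_laser_scan(
    feet_world: list[np.ndarray] | np.ndarray,
    laser_pose: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    t: float = 0.0,
) -> LaserScan:
    """Ray-cast one 360-degree scan against the leg discs.

    ``feet_world`` lists world-frame leg centers (possibly empty when a leg
    is occluded); ``laser_pose`` is (x, y, theta) of the laser in world.
    Beam i points along ``angle_start + i * increment`` in the laser frame;
    each beam returns the nearest ray/disc intersection within
    ``laser_range_max`` plus Gaussian noise, else +inf.
    """
    inc = config.laser_angular_increment
    n = int(round(2 * math.pi / inc))
    angle_start = -math.pi
    angles = angle_start + inc * np.arange(n) + laser_pose[2]
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    origin = np.asarray(laser_pose[:2], dtype=float)

    ranges = np.full(n, np.inf)
    for center in feet_world:
        rel = np.asarray(center, dtype=float) - origin
        proj = dirs @ rel  # distance of closest approach along each beam
        d2 = float(rel @ rel) - proj**2
        hit = (proj > 0) & (d2 <= config.leg_radius**2)
        r = np.where(hit, proj - np.sqrt(np.maximum(config.leg_radius**2 - d2, 0.0)), np.inf)
        ranges = np.minimum(ranges, r)

    noise = rng.normal(0.0, config.laser_noise_sd, n)
    finite = np.isfinite(ranges)
    ranges[finite] = np.maximum(ranges[finite] + noise[finite], 0.0)
    ranges[~finite | (ranges > config.laser_range_max)] = np.inf
    return LaserScan(t=t, angle_start=angle_start, angle_increment=inc, ranges=ranges)


def synth_handle_loads(
    t: np.ndarray, timeline: GaitTimeline, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Handlebar loads (kg-force, pre-quantization) at times ``t``.

    The left-minus-right difference is a smooth oscillation at step
    frequency that peaks ``handle_modulation`` kg toward the side whose heel
    just struck, a quarter step after contact; the total stays at
    ``handle_support_mean``, scaled by ``stance_load_factor`` of the current
    support side during single-support phases.
    """
    t = np.asarray(t, dtype=float)
    st = timeline.strike_t
    # control points: a quarter step after each strike the difference peaks
    u = st[:-1] + 0.25 * np.diff(st)
    peak = np.array(
        [1.0 if s == "left" else -1.0 for s in timeline.strike_side[:-1]]
    )
    idx = np.clip(np.searchsorted(u, t, side="right") - 1, 0, u.size - 2)
    frac = (t - u[idx]) / (u[idx + 1] - u[idx])
    diff = config.handle_modulation * peak[idx] * np.cos(np.pi * frac)
    factor = np.array(
        [
            config.stance_load_factor.get(lab.removeprefix("single_"))
            if lab.startswith("single")
            else 1.0
            for lab in np.atleast_1d(timeline.phase_label(t))
        ]
    )
    total = config.handle_support_mean * factor
    left = (total + diff) / 2.0 * config.load_asymmetry.left
    right = (total - diff) / 2.0 * config.load_asymmetry.right
    return np.maximum(left, 0.0), np.maximum(right, 0.0)


def _quantize(values: np.ndarray, step: float) -> np.ndarray:
    return np.round(values / step) * step


def simulate_session(
    config: SimulationConfig | None = None,
) -> tuple[SensorSession, GroundTruth]:
    """Generate one synthetic trial and its ground truth.

    Deterministic given ``config.seed``; random draws occur in a fixed
    order (per laser scan: dropout coin, occluded-side choice, beam noise).
    """
    config = config or SimulationConfig()
    config.validate()
    tl = GaitTimeline(config)
    tr = config.duration
    rng = np.random.default_rng(config.seed)
    frames = _frames_for(config)

    # --- encoders: piecewise-linear cumulative wheel displacement
    et = np.arange(int(np.floor(tr * config.encoder_rate)) + 1) / config.encoder_rate
    bps = np.unique(np.concatenate([tl._bps, [0.0, tr]]))
    bps = bps[(bps >= 0.0) & (bps <= tr)]
    mid = 0.5 * (bps[:-1] + bps[1:])
    v_mid, w_mid = tl.speed(mid), tl.omega(mid)
    half_l = config.wheelbase / 2.0
    cum_left = np.concatenate([[0.0], np.cumsum((v_mid - w_mid * half_l) * np.diff(bps))])
    cum_right = np.concatenate([[0.0], np.cumsum((v_mid + w_mid * half_l) * np.diff(bps))])
    encoders = EncoderStream(
        t=et,
        left_disp=_quantize(np.interp(et, bps, cum_left), ENCODER_TICK),
        right_disp=_quantize(np.interp(et, bps, cum_right), ENCODER_TICK),
    )

    # --- handle loads
    lt = np.arange(int(np.floor(tr * config.load_rate)) + 1) / config.load_rate
    left_raw, right_raw = synth_handle_loads(lt, tl, config)
    loads = LoadStream(
        t=lt,
        left_load=_quantize(left_raw, LOAD_RESOLUTION),
        right_load=_quantize(right_raw, LOAD_RESOLUTION),
    )

    # --- laser scans
    laser_tf = frames.pose("laser")
    scan_t = np.arange(int(np.floor(tr * config.laser_rate)) + 1) / config.laser_rate
    poses = tl.pose(scan_t)
    feet_left = tl.foot_positions(scan_t, "left")
    feet_right = tl.foot_positions(scan_t, "right")
    scans = []
    for i, t in enumerate(scan_t):
        body = RigidTransform2D(poses[i, 0], poses[i, 1], poses[i, 2])
        lp = body.compose(laser_tf)
        laser_pose = np.array([lp.x, lp.y, lp.theta])
        feet = [feet_left[i], feet_right[i]]
        if rng.uniform() < config.dropout_prob:
            drop = int(rng.integers(0, 2))
            feet = [feet[1 - drop]]
        scans.append(render_laser_scan(feet, laser_pose, config, rng, t=float(t)))

    session = SensorSession(
        laser=scans,
        encoders=encoders,
        loads=loads,
        frames=frames,
        user_weight=config.user_weight,
        duration=tr,
        session_id=f"sim-{config.seed}",
        seed=config.seed,
    )
    session.validate()

    # --- ground truth
    base_inv = [RigidTransform2D(*p).inverse() for p in poses]
    leg_positions = {
        "t": scan_t,
        "left": np.array([tf.apply(p) for tf, p in zip(base_inv, feet_left)]),
        "right": np.array([tf.apply(p) for tf, p in zip(base_inv, feet_right)]),
    }
    gt = GroundTruth(
        heel_strikes=tl.heel_strikes(),
        support_phases=tl.support_phases(),
        true_params=_true_params(tl),
        leg_positions=leg_positions,
    )
    return session, gt


def _frames_for(config: SimulationConfig) -> FrameGraph:
    g = default_frame_graph()
    half = config.wheelbase / 2.0
    poses = {name: g.pose(name) for name in g.frames}
    poses["left_wheel"] = RigidTransform2D(0.0, half, 0.0)
    poses["right_wheel"] = RigidTransform2D(0.0, -half, 0.0)
    return FrameGraph(poses)


def _true_params(tl: GaitTimeline) -> dict:
    tr = tl.config.duration
    st, sides = tl.strike_t, tl.strike_side
    inside = [
        k for k in range(st.size) if 1e-12 < st[k] <= tr + 1e-12
    ]  # events after the session starts
    nos = len(inside)
    spt = {"left": [], "right": []}
    spl = {"left": [], "right": []}
    for k in inside:
        spt[sides[k]].append(st[k] - st[k - 1])
        spl[sides[k]].append(float(tl.arc_length(st[k]) - tl.arc_length(st[k - 1])))
    sdt_all, sdl_all = [], []
    for side in ("left", "right"):
        ks = [k for k in inside if sides[k] == side]
        sdt_all += [st[b] - st[a] for a, b in zip(ks, ks[1:])]
        sdl_all += [
            float(tl.arc_length(st[b]) - tl.arc_length(st[a]))
            for a, b in zip(ks, ks[1:])
        ]
    d = float(tl.arc_length(tr) - tl.arc_length(0.0))
    phases = tl.support_phases()
    single = sum(b - a for a, b, lab in phases if lab.startswith("single"))
    return {
        "NoS": nos,
        "Tr": tr,
        "CAD": 60.0 * nos / tr,
        "SpT_left": float(np.mean(spt["left"])),
        "SpT_right": float(np.mean(spt["right"])),
        "SdT": float(np.mean(sdt_all)),
        "SpL_left": float(np.mean(spl["left"])),
        "SpL_right": float(np.mean(spl["right"])),
        "SdL": float(np.mean(sdl_all)),
        "d": d,
        "WV": d / tr,
        "single_support_fraction": single / tr,
    }


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(gt.to_json() + "\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())
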