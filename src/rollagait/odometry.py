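"""Differential-drive odometry from the wheel-encoder streams.

The rollator's front wheels are casters, so the rear axle fully determines
the pose: with wheel speeds ``vl``, ``vr`` and wheelbase ``L``,

    v     = (vl + vr) / 2
    omega = (vr - vl) / L      (positive = counter-clockwise = left turn)

Wheel speeds come from centered finite differences of the cumulative
displacement over a short smoothing window (0.1 mm ticks at 600 Hz are too
jittery for sample-to-sample differences), and the pose integrates the
exact constant-(v, omega) unicycle arc per interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .session import EncoderStream, SensorSession, ValidationError

__all__ = [
    "OdometryConfig",
    "PoseSeries",
    "wheel_speeds",
    "diff_drive",
    "integrate_pose",
    "total_distance",
    "cumulative_distance",
    "compute_odometry",
]


@dataclass
class OdometryConfig:
    """``wheelbase``: rear-wheel separation (m); ``speed_window``:
    finite-difference smoothing window (s)."""

    wheelbase: float = 0.55
    speed_window: float = 0.05

    def validate(self) -> None:
        if self.wheelbase <= 0:
            raise ValidationError("wheelbase must be positive")
        if self.speed_window <= 0:
            raise ValidationError("speed_window must be positive")


@dataclass
class PoseSeries:
    """Odometric trajectory: pose plus body speeds on the encoder timeline.

    ``theta`` is wrapped to (-pi, pi]; ``omega`` > 0 means a left turn.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    v: np.ndarray
    omega: np.ndarray

    def __len__(self) -> int:
        return self.t.size


def _wrap_angle(theta: np.ndarray) -> np.ndarray:
    wrapped = np.mod(theta + np.pi, 2 * np.pi) - np.pi
    return np.where(wrapped == -np.pi, np.pi, wrapped)


def wheel_speeds(
    encoders: EncoderStream, config: OdometryConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-wheel speeds (m/s) on the encoder timeline.

    Speed at ``t_i`` is the displacement slope between the samples nearest
    ``t_i - w/2`` and ``t_i + w/2`` (clamped at the stream ends), i.e. a
    centered finite difference averaged over the smoothing window.
    """
    config = config or OdometryConfig()
    config.validate()
    t = encoders.t
    if t.size < 2:
        raise ValidationError("wheel speeds need at least 2 encoder samples")
    half = config.speed_window / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right") - 1
    hi = np.clip(hi, 0, t.size - 1)
    # guarantee a nonzero span even at the stream edges
    same = lo >= hi
    lo = np.where(same & (hi > 0), hi - 1, lo)
    hi = np.where(same & (hi == 0), 1, hi)
    dt = t[hi] - t[lo]
    vl = (encoders.left_disp[hi] - encoders.left_disp[lo]) / dt
    vr = (encoders.right_disp[hi] - encoders.right_disp[lo]) / dt
    return t, vl, vr


def diff_drive(
    vl: np.ndarray, vr: np.ndarray, config: OdometryConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Translational and rotational speed from wheel speeds."""
    config = config or OdometryConfig()
    vl = np.asarray(vl, dtype=float)
    vr = np.asarray(vr, dtype=float)
    return (vl + vr) / 2.0, (vr - vl) / config.wheelbase


def integrate_pose(
    t: np.ndarray, v: np.ndarray, omega: np.ndarray
) -> PoseSeries:
    """Integrate (v, omega) into a pose trajectory starting at (0, 0, 0).

    Each interval uses the exact constant-speed arc (straight-line update
    when |omega| < 1e-9 rad/s).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    omega = np.asarray(omega, dtype=float)
    n = t.size
    x = np.zeros(n)
    y = np.zeros(n)
    th = np.zeros(n)
    dt = np.diff(t)
    for i in range(n - 1):
        vi, wi, dti = v[i], omega[i], dt[i]
        if abs(wi) < 1e-9:
            x[i + 1] = x[i] + vi * dti * math.cos(th[i])
            y[i + 1] = y[i] + vi * dti * math.sin(th[i])
            th[i + 1] = th[i] + wi * dti
        else:
            th1 = th[i] + wi * dti
            r = vi / wi
            x[i + 1] = x[i] + r * (math.sin(th1) - math.sin(th[i]))
            y[i + 1] = y[i] - r * (math.cos(th1) - math.cos(th[i]))
            th[i + 1] = th1
    return PoseSeries(t=t, x=x, y=y, theta=_wrap_angle(th), v=v, omega=omega)


def cumulative_distance(poses: PoseSeries) -> np.ndarray:
    """Odometric path distance walked up to each sample (trapezoid of |v|)."""
    if len(poses) == 0:
        raise ValidationError("empty pose series")
    av = np.abs(poses.v)
    mid = 0.5 * (av[:-1] + av[1:])
    return np.concatenate([[0.0], np.cumsum(mid * np.diff(poses.t))])


def total_distance(poses: PoseSeries) -> float:
    """Total path distance ``d`` (m) over the session."""
    return float(cumulative_distance(poses)[-1])


def compute_odometry(
    session: SensorSession, config: OdometryConfig | None = None
) -> PoseSeries:
    """Full odometry pipeline for a session's encoder stream."""
    config = config or OdometryConfig()
    t, vl, vr = wheel_speeds(session.encoders, config)
    v, omega = diff_drive(vl, vr, config)
    return integrate_pose(t, v, omega)
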