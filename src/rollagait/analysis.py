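"""Spatiotemporal gait parameters, support metrics and weight bearing.

From a cleaned, alternating heel-strike sequence and the odometric
trajectory this module derives the standard rollator gait summary:

* NoS, number of steps; CAD = 60 * NoS / Tr (steps/min)
* SpT, step time: interval ending at a left/right event (per-side mean, sd)
* SdT, stride time: interval between same-side events
* SpL / SdL: odometric path distance traversed over those intervals (m)
* d, distance walked; WV = d / Tr (m/s)
* UrS, user support: mean per-step total handle load (kg-force, also N);
  WB reported literally as 1 / UrS in newtons
* pwb, partial weight bearing: percent body weight on the support leg
  during its single-support phases, overall and binned by steering speed

Steering-speed bins use the clinical reporting convention (negative =
steering left), which is the negative of the odometric omega.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .odometry import (
    OdometryConfig,
    PoseSeries,
    compute_odometry,
    cumulative_distance,
    total_distance,
)
from .session import GRAVITY, LoadStream, SensorSession, ValidationError
from .tracking import (
    DetectionArea,
    DetectorConfig,
    HeelStrikeEvent,
    LegTrack,
    SupportPhase,
    VdiffSignal,
    clean_alternating,
    detect_events,
    detect_heel_strikes_force,
    label_support_phases,
)

__all__ = [
    "MeanSd",
    "SteeringBins",
    "GaitReport",
    "PwbSummary",
    "AnalysisError",
    "AnalysisResult",
    "clean_alternating",
    "spatiotemporal",
    "support_metrics",
    "partial_weight_bearing",
    "phases_from_events",
    "aggregate_reports",
    "report_to_row",
    "analyze_session",
]

#: UrS values below this (kg-force) are reported as "<1" and contribute
#: zero to the aggregate column mean.
URS_DETECTION_FLOOR = 1.0


@dataclass(frozen=True)
class MeanSd:
    mean: float
    sd: float

    def as_tuple(self) -> tuple[float, float]:
        return (self.mean, self.sd)


def _mean_sd(values) -> MeanSd:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return MeanSd(math.nan, math.nan)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return MeanSd(float(np.mean(arr)), sd)


@dataclass
class SteeringBins:
    """Bin edges (rad/s) on the reporting turning-speed axis (negative =
    left turn)."""

    edges: tuple[float, ...] = (-math.inf, -0.3, -0.1, 0.1, 0.3, math.inf)

    def __post_init__(self):
        if np.any(np.diff(self.edges) <= 0):
            raise ValidationError("steering bin edges must be strictly increasing")

    @property
    def labels(self) -> list[str]:
        return [
            f"[{lo:+.2f}, {hi:+.2f})"
            for lo, hi in zip(self.edges[:-1], self.edges[1:])
        ]

    def assign(self, omega_report: np.ndarray) -> np.ndarray:
        inner = np.asarray(self.edges[1:-1])
        return np.digitize(omega_report, inner)


@dataclass
class PwbSummary:
    """Partial weight bearing (% body weight on the support leg)."""

    left: float
    right: float
    by_steering: dict = field(default_factory=dict)


@dataclass
class GaitReport:
    """Full per-session gait summary."""

    nos: int
    tr: float
    cad: float
    spt_left: MeanSd
    spt_right: MeanSd
    sdt: MeanSd
    sdt_left: MeanSd
    sdt_right: MeanSd
    spl_left: MeanSd
    spl_right: MeanSd
    sdl: MeanSd
    d: float
    wv: float
    urs_kg: float | None = None
    urs_n: float | None = None
    wb_inv: float | None = None
    urs_sum_n: float | None = None
    pwb: PwbSummary | None = None
    user_weight: float | None = None
    source: str = "laser"

    def to_dict(self) -> dict:
        def ms(v):
            return None if v is None else {"mean": v.mean, "sd": v.sd}

        return {
            "NoS": self.nos,
            "Tr": self.tr,
            "CAD": self.cad,
            "SpT_left": ms(self.spt_left),
            "SpT_right": ms(self.spt_right),
            "SdT": ms(self.sdt),
            "SdT_left": ms(self.sdt_left),
            "SdT_right": ms(self.sdt_right),
            "SpL_left": ms(self.spl_left),
            "SpL_right": ms(self.spl_right),
            "SdL": ms(self.sdl),
            "d": self.d,
            "WV": self.wv,
            "UrS_kg": self.urs_kg,
            "UrS_N": self.urs_n,
            "WB_inv": self.wb_inv,
            "UrS_sum_N": self.urs_sum_n,
            "pwb_left": None if self.pwb is None else self.pwb.left,
            "pwb_right": None if self.pwb is None else self.pwb.right,
            "pwb_by_steering": None if self.pwb is None else self.pwb.by_steering,
            "user_weight": self.user_weight,
            "source": self.source,
        }


class AnalysisError(RuntimeError):
    """Pipeline failure, prefixed with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"{stage}: {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# spatiotemporal parameters


def spatiotemporal(
    events: list[HeelStrikeEvent], poses: PoseSeries, tr: float
) -> dict:
    """Temporal and spatial step/stride parameters from events + odometry.

    Lengths interpolate the cumulative odometric path distance at the event
    timestamps.  Raises on fewer than 4 alternating events.
    """
    events = clean_alternating(events)
    if len(events) < 4:
        raise ValidationError("insufficient steps: fewer than 4 alternating events")
    times = np.array([e.t for e in events])
    sides = [e.side for e in events]
    cum = cumulative_distance(poses)
    dist_at = np.interp(times, poses.t, cum)

    spt = {"left": [], "right": []}
    spl = {"left": [], "right": []}
    for i in range(1, len(events)):
        spt[sides[i]].append(times[i] - times[i - 1])
        spl[sides[i]].append(dist_at[i] - dist_at[i - 1])
    sdt = {"left": [], "right": []}
    sdl = {"left": [], "right": []}
    for side in ("left", "right"):
        ks = [i for i, s in enumerate(sides) if s == side]
        sdt[side] = [times[b] - times[a] for a, b in zip(ks, ks[1:])]
        sdl[side] = [dist_at[b] - dist_at[a] for a, b in zip(ks, ks[1:])]

    d = total_distance(poses)
    nos = len(events)
    return {
        "nos": nos,
        "tr": tr,
        "cad": 60.0 * nos / tr,
        "spt_left": _mean_sd(spt["left"]),
        "spt_right": _mean_sd(spt["right"]),
        "sdt": _mean_sd(sdt["left"] + sdt["right"]),
        "sdt_left": _mean_sd(sdt["left"]),
        "sdt_right": _mean_sd(sdt["right"]),
        "spl_left": _mean_sd(spl["left"]),
        "spl_right": _mean_sd(spl["right"]),
        "sdl": _mean_sd(sdl["left"] + sdl["right"]),
        "d": d,
        "wv": d / tr,
    }


# ---------------------------------------------------------------------------
# support and weight bearing


def support_metrics(
    loads: LoadStream, events: list[HeelStrikeEvent]
) -> tuple[float, float, float | None, float]:
    """User support over steps.

    Returns ``(UrS_kg, UrS_N, WB_inv, sum_N)``: the mean per-step total
    handle load in kg-force and newtons, weight bearing as 1/UrS (None when
    UrS is zero), and the raw sum of per-step forces.
    """
    if len(events) < 2:
        raise ValidationError("support metrics need at least 2 events")
    times = np.array([e.t for e in events])
    total = loads.total
    per_step = []
    for a, b in zip(times, times[1:]):
        sel = (loads.t >= a) & (loads.t < b)
        if np.any(sel):
            per_step.append(float(np.mean(total[sel])))
    if not per_step:
        raise ValidationError("no load samples overlap the event span")
    urs_kg = float(np.mean(per_step))
    urs_n = urs_kg * GRAVITY
    wb_inv = (1.0 / urs_n) if urs_n > 0 else None
    return urs_kg, urs_n, wb_inv, float(np.sum(per_step) * GRAVITY)


def phases_from_events(
    events: list[HeelStrikeEvent], swing_fraction: float, tr: float
) -> list[SupportPhase]:
    """Nominal support phases implied by an event sequence alone.

    Used when leg velocities are unavailable (force-only sessions): after a
    side's contact the first ``1 - swing_fraction`` of the step is double
    support, the remainder single support on that side.
    """
    events = clean_alternating(events)
    phases: list[SupportPhase] = []
    for a, b in zip(events, events[1:]):
        split = a.t + (1.0 - swing_fraction) * (b.t - a.t)
        phases.append(SupportPhase(a.t, split, "double"))
        phases.append(SupportPhase(split, b.t, f"single_{a.side}"))
    return [p for p in phases if p.t_end > 0 and p.t_start < tr]


def partial_weight_bearing(
    loads: LoadStream,
    phases: list[SupportPhase],
    user_weight: float,
    poses: PoseSeries | None = None,
    bins: SteeringBins | None = None,
) -> PwbSummary:
    """Percent body weight on the support leg during single support.

    pwb(t) = 100 * (W - total_handle_load(t)) / W, attributed to the
    support leg of the phase containing the sample.  Per-bin means use the
    reporting-convention turning speed (negative = left turn).
    """
    if user_weight <= 0:
        raise ValidationError("user_weight must be positive")
    bins = bins or SteeringBins()
    t = loads.t
    pwb = 100.0 * (user_weight - loads.total) / user_weight

    side = np.empty(t.size, dtype=object)
    side[:] = None
    for ph in phases:
        if not ph.label.startswith("single"):
            continue
        sel = (t >= ph.t_start) & (t < ph.t_end)
        side[sel] = ph.label.removeprefix("single_")

    def _mean(mask) -> float:
        return float(np.mean(pwb[mask])) if np.any(mask) else math.nan

    is_left = side == "left"
    is_right = side == "right"
    summary = PwbSummary(left=_mean(is_left), right=_mean(is_right))

    if poses is not None:
        omega_report = -np.interp(t, poses.t, poses.omega)
        which = bins.assign(omega_report)
        for b, label in enumerate(bins.labels):
            in_bin = which == b
            summary.by_steering[label] = {
                "left": _mean(is_left & in_bin),
                "right": _mean(is_right & in_bin),
                "n_left": int(np.sum(is_left & in_bin)),
                "n_right": int(np.sum(is_right & in_bin)),
            }
    return summary


# ---------------------------------------------------------------------------
# aggregation (multi-session summary table)

_TABLE_COLUMNS = ["User", "CAD", "SdT", "SdL", "rSpT", "lSpT", "rSpL", "lSpL", "WV", "UrS"]
_MEAN_SD_COLS = ["SdT", "SdL", "rSpT", "lSpT", "rSpL", "lSpL"]
_SCALAR_COLS = ["CAD", "WV"]


def report_to_row(report: GaitReport, user: str) -> dict:
    """Convert a :class:`GaitReport` into a summary-table row."""
    urs = report.urs_kg
    return {
        "User": user,
        "CAD": report.cad,
        "SdT": report.sdt.as_tuple(),
        "SdL": report.sdl.as_tuple(),
        "rSpT": report.spt_right.as_tuple(),
        "lSpT": report.spt_left.as_tuple(),
        "rSpL": report.spl_right.as_tuple(),
        "lSpL": report.spl_left.as_tuple(),
        "WV": report.wv,
        "UrS": urs,
    }


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def aggregate_reports(rows: list[dict]) -> tuple[pd.DataFrame, dict]:
    """Build the per-user summary table with a final averages row.

    Each row is a dict as produced by :func:`report_to_row` (mean/sd columns
    may be a bare float or a ``(mean, sd)`` tuple).  UrS below the 1 kg
    detection floor is rendered ``"<1"`` and contributes zero to the column
    mean.  Returns the formatted table and the numeric column means.
    """
    if not rows:
        raise ValidationError("aggregate_reports needs at least one row")

    def split(v) -> tuple[float, float | None]:
        if isinstance(v, (tuple, list)):
            return float(v[0]), float(v[1])
        return float(v), None

    means: dict[str, float] = {}
    for col in _SCALAR_COLS:
        means[col] = float(np.mean([float(r[col]) for r in rows]))
    for col in _MEAN_SD_COLS:
        means[col] = float(np.mean([split(r[col])[0] for r in rows]))
    means["UrS"] = float(
        np.mean(
            [
                0.0
                if r["UrS"] is None or r["UrS"] < URS_DETECTION_FLOOR
                else float(r["UrS"])
                for r in rows
            ]
        )
    )

    table = []
    for r in rows:
        rec = {"User": r["User"]}
        for col in _SCALAR_COLS:
            rec[col] = _fmt(float(r[col]))
        for col in _MEAN_SD_COLS:
            m, s = split(r[col])
            rec[col] = _fmt(m) if s is None else f"{_fmt(m)} ({_fmt(s)})"
        urs = r["UrS"]
        rec["UrS"] = "<1" if urs is None or urs < URS_DETECTION_FLOOR else _fmt(urs)
        table.append(rec)
    av = {"User": "Av."}
    for col in _SCALAR_COLS + _MEAN_SD_COLS + ["UrS"]:
        av[col] = _fmt(means[col])
    table.append(av)
    return pd.DataFrame(table, columns=_TABLE_COLUMNS), means


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class AnalysisResult:
    report: GaitReport
    events: list[HeelStrikeEvent]
    phases: list[SupportPhase]
    poses: PoseSeries
    track: LegTrack | None = None
    vdiff: list[VdiffSignal] = field(default_factory=list)


def analyze_session(
    session: SensorSession,
    odometry_config: OdometryConfig | None = None,
    detector_config: DetectorConfig | None = None,
    area: DetectionArea | None = None,
    bins: SteeringBins | None = None,
    source: str = "auto",
) -> AnalysisResult:
    """Run the full pipeline on one session.

    ``source`` selects the event detector: ``laser`` (default path),
    ``force`` (legacy handlebar detector) or ``auto`` (laser when scans are
    present, otherwise force if its validity gate passes).
    """
    odometry_config = odometry_config or OdometryConfig()
    detector_config = detector_config or DetectorConfig()
    bins = bins or SteeringBins()

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, AnalysisError):
                    raise AnalysisError(name, str(exc)) from exc
                return False

        return _Ctx()

    with stage("odometry"):
        poses = compute_odometry(session, odometry_config)

    track = None
    vdiff: list[VdiffSignal] = []
    use_laser = source == "laser" or (source == "auto" and len(session.laser) > 0)
    if use_laser:
        with stage("leg_tracking"):
            events, track, vels, vdiff = detect_events(session, area, detector_config)
            phases = label_support_phases(
                track.t, vels[0], vels[1], detector_config, events=events
            )
        used = "laser"
    else:
        with stage("force_detection"):
            events, valid, _ = detect_heel_strikes_force(session.loads, detector_config)
            if not valid and source == "auto":
                raise ValidationError(
                    "force-difference detector below the 7 N validity gate"
                )
            phases = phases_from_events(
                events, detector_config.swing_fraction, session.duration
            )
        used = "force"

    with stage("spatiotemporal"):
        params = spatiotemporal(events, poses, session.duration)

    urs_kg = urs_n = wb_inv = urs_sum = None
    pwb = None
    if session.loads.t.size:
        with stage("support_metrics"):
            urs_kg, urs_n, wb_inv, urs_sum = support_metrics(session.loads, events)
        with stage("partial_weight_bearing"):
            pwb = partial_weight_bearing(
                session.loads, phases, session.user_weight, poses, bins
            )

    report = GaitReport(
        **params,
        urs_kg=urs_kg,
        urs_n=urs_n,
        wb_inv=wb_inv,
        urs_sum_n=urs_sum,
        pwb=pwb,
        user_weight=session.user_weight,
        source=used,
    )
    return AnalysisResult(
        report=report, events=events, phases=phases, poses=poses, track=track, vdiff=vdiff
    )
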