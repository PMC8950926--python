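"""Leg tracking and heel-contact detection from planar laser scans.

Pipeline: keep laser returns inside a rectangular detection area behind the
rollator, split them into two clusters (one per leg) with a 2-means
iteration warm-started from the previous scan, track the cluster centroids
to get each leg's longitudinal velocity relative to the rollator, bandpass
the velocity difference ``vdiff = v_left - v_right`` with a zero-phase
Butterworth filter, and read heel contacts off its thresholded peaks:
positive peaks mark left-leg events, negative peaks right-leg events.

Support phases follow from the relative velocities directly: the support
leg is the slower (more negative) one, and double support is declared when
both legs move backwards relative to the frame at nearly equal speed.

A legacy force-based detector is also provided: extrema of the low-passed
left-minus-right handlebar force difference (``fdiff``) mark contacts, but
the method is only trustworthy when the peak-to-peak difference exceeds
7 N, so its output carries a validity flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .frames import BASE_FRAME, FrameGraph
from .session import GRAVITY, LaserScan, LoadStream, SensorSession, ValidationError

__all__ = [
    "DetectionArea",
    "DetectorConfig",
    "LegTrack",
    "VdiffSignal",
    "FdiffSignal",
    "HeelStrikeEvent",
    "SupportPhase",
    "filter_detection_area",
    "cluster_legs",
    "track_legs",
    "leg_velocities",
    "bandpass",
    "compute_vdiff",
    "detect_heel_strikes",
    "detect_events",
    "label_support_phases",
    "detect_heel_strikes_force",
]


@dataclass
class DetectionArea:
    """Closed rectangle behind the rollator (base frame, meters)."""

    x_min: float = -1.0
    x_max: float = -0.1
    y_min: float = -0.45
    y_max: float = 0.45

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValidationError("detection area must have positive extent")

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        return (
            (pts[:, 0] >= self.x_min)
            & (pts[:, 0] <= self.x_max)
            & (pts[:, 1] >= self.y_min)
            & (pts[:, 1] <= self.y_max)
        )


@dataclass
class DetectorConfig:
    """Tunables of the event detectors.

    ``passband`` covers stride frequencies for cadences from roughly 18 to
    180 steps/min; ``swing_fraction`` is the assumed share of a step spent
    in swing, used to shift the mid-swing vdiff peak forward to the contact
    instant (0 disables the shift).  Signals are linearly resampled to
    ``internal_rate`` before filtering so the passband sits safely below
    the Nyquist frequency regardless of the (slow) sensor rates.
    """

    butterworth_order: int = 2
    passband: tuple[float, float] = (0.3, 3.0)
    peak_threshold: float = 0.1  # m/s on filtered vdiff
    max_cadence: float = 180.0  # steps/min; sets the refractory gap
    force_validity_threshold: float = 7.0  # N, peak-to-peak fdiff gate
    force_cutoff: float = 3.0  # Hz low-pass for fdiff
    min_cluster_points: int = 3
    min_leg_separation: float = 0.10  # m; closer centroids = one occluded leg
    internal_rate: float = 50.0  # Hz
    swing_fraction: float = 0.62
    double_support_band: float = 0.15  # m/s
    min_phase_duration: float = 0.1  # s
    max_gap_frames: int = 2  # invalid frames bridged by interpolation
    min_stretch: float = 2.0  # s, shortest vdiff stretch worth filtering

    @property
    def min_event_gap(self) -> float:
        return 60.0 / self.max_cadence


@dataclass
class LegTrack:
    """Per-scan leg centroids in the base frame, with validity flags."""

    t: np.ndarray
    left: np.ndarray  # (n, 2), NaN when invalid
    right: np.ndarray
    valid_left: np.ndarray
    valid_right: np.ndarray

    def side(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        if name == "left":
            return self.left, self.valid_left
        return self.right, self.valid_right


@dataclass
class VdiffSignal:
    """Leg-velocity difference on a uniform internal timeline."""

    t: np.ndarray
    raw: np.ndarray
    filtered: np.ndarray


@dataclass
class FdiffSignal:
    """Left-minus-right handlebar force difference (newtons)."""

    t: np.ndarray
    raw: np.ndarray
    filtered: np.ndarray
    peak_to_peak: float


@dataclass(frozen=True)
class HeelStrikeEvent:
    t: float
    side: str  # left | right
    source: str  # laser | force
    peak_value: float  # m/s (laser) or N (force), signed


@dataclass(frozen=True)
class SupportPhase:
    t_start: float
    t_end: float
    label: str  # single_left | single_right | double


# ---------------------------------------------------------------------------
# geometry


def filter_detection_area(
    scan: LaserScan,
    area: DetectionArea | None = None,
    graph: FrameGraph | None = None,
) -> np.ndarray:
    """Finite laser returns inside the detection area, as base-frame points.

    The rectangle is closed: boundary points are retained.  May be empty.
    """
    area = area or DetectionArea()
    finite = np.isfinite(scan.ranges)
    r = scan.ranges[finite]
    a = scan.angles[finite]
    pts = np.column_stack([r * np.cos(a), r * np.sin(a)])
    if graph is not None and scan.frame != BASE_FRAME:
        pts = graph.transform(scan.frame, BASE_FRAME).apply(pts)
    if pts.size == 0:
        return pts.reshape(0, 2)
    return pts[area.contains(pts)]


def cluster_legs(
    cloud: np.ndarray,
    previous: np.ndarray | None = None,
    config: DetectorConfig | None = None,
) -> tuple[np.ndarray | None, np.ndarray | None, bool, bool]:
    """Split a leg point cloud into (left, right) centroids.

    2-means (Lloyd), run from two seedings -- the previous scan's centroids
    (tracking prior) and a median split on the lateral coordinate -- keeping
    the partition with the lower within-cluster sum of squares (the prior
    alone mistracks when a fast swing moves a leg by more than the leg
    separation between scans).  Sides are assigned by lateral position
    (greater y = left).  When the two centroids collapse within
    ``min_leg_separation`` the cloud is treated as a single (occluded) leg
    assigned to the nearer side; a side is invalid when its cluster has
    fewer than ``min_cluster_points`` points.
    """
    config = config or DetectorConfig()
    cloud = np.atleast_2d(np.asarray(cloud, dtype=float))
    n = cloud.shape[0] if cloud.size else 0
    if n == 0:
        return None, None, False, False

    med = np.median(cloud[:, 1])
    upper = cloud[:, 1] >= med
    if upper.all() or (~upper).all():  # degenerate: split top/bottom point
        order = np.argsort(cloud[:, 1])
        upper = np.zeros(n, dtype=bool)
        upper[order[n // 2:]] = True
    seeds = [np.array([cloud[upper].mean(axis=0), cloud[~upper].mean(axis=0)])]
    if previous is not None and np.all(np.isfinite(previous)):
        seeds.insert(0, np.array(previous, dtype=float))

    best = None
    for centers in seeds:
        assign, centers, cost = _lloyd2(cloud, centers)
        if best is None or cost < best[2] - 1e-12:
            best = (assign, centers, cost)
    assign, centers, _ = best

    counts = np.array([np.sum(assign == 0), np.sum(assign == 1)])
    if np.linalg.norm(centers[0] - centers[1]) < config.min_leg_separation:
        # one visible leg: both centroids sit on the same blob
        centroid = cloud.mean(axis=0)
        side = _nearest_side(centroid, previous)
        ok = n >= config.min_cluster_points
        if side == "left":
            return centroid, None, ok, False
        return None, centroid, False, ok

    # larger y = left; exact tie resolved toward the previous assignment
    if centers[0][1] > centers[1][1]:
        li, ri = 0, 1
    elif centers[0][1] < centers[1][1]:
        li, ri = 1, 0
    elif previous is not None and np.all(np.isfinite(previous)):
        d_prev = np.linalg.norm(centers - previous[0], axis=1)
        li = int(np.argmin(d_prev))
        ri = 1 - li
    else:
        li, ri = 0, 1
    valid_l = counts[li] >= config.min_cluster_points
    valid_r = counts[ri] >= config.min_cluster_points
    return (
        centers[li] if counts[li] else None,
        centers[ri] if counts[ri] else None,
        bool(valid_l),
        bool(valid_r),
    )


def _lloyd2(
    cloud: np.ndarray, centers: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd iteration for k=2; returns (assignment, centers, cost)."""
    centers = centers.copy()
    assign = np.full(cloud.shape[0], -1)
    for _ in range(50):
        d = np.linalg.norm(cloud[:, None, :] - centers[None, :, :], axis=2)
        new_assign = np.argmin(d, axis=1)
        for k in (0, 1):
            if np.any(new_assign == k):
                centers[k] = cloud[new_assign == k].mean(axis=0)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    cost = 0.0
    for k in (0, 1):
        sel = assign == k
        if np.any(sel):
            cost += float(np.sum((cloud[sel] - centers[k]) ** 2))
    return assign, centers, cost


def _nearest_side(centroid: np.ndarray, previous: np.ndarray | None) -> str:
    if previous is not None and np.all(np.isfinite(previous)):
        d = np.linalg.norm(previous - centroid, axis=1)
        return "left" if d[0] <= d[1] else "right"
    return "left" if centroid[1] >= 0 else "right"


def track_legs(
    session: SensorSession,
    area: DetectionArea | None = None,
    config: DetectorConfig | None = None,
) -> LegTrack:
    """Cluster every scan, carrying centroids forward as the 2-means seed."""
    area = area or DetectionArea()
    config = config or DetectorConfig()
    n = len(session.laser)
    t = np.array([s.t for s in session.laser])
    left = np.full((n, 2), np.nan)
    right = np.full((n, 2), np.nan)
    valid_l = np.zeros(n, dtype=bool)
    valid_r = np.zeros(n, dtype=bool)
    prev: np.ndarray | None = None
    for i, scan in enumerate(session.laser):
        cloud = filter_detection_area(scan, area, session.frames)
        lc, rc, vl, vr = cluster_legs(cloud, prev, config)
        if lc is not None:
            left[i] = lc
        if rc is not None:
            right[i] = rc
        valid_l[i], valid_r[i] = vl, vr
        last_l = left[i] if vl else (prev[0] if prev is not None else None)
        last_r = right[i] if vr else (prev[1] if prev is not None else None)
        if last_l is not None and last_r is not None:
            prev = np.array([last_l, last_r])
    return LegTrack(t=t, left=left, right=right, valid_left=valid_l, valid_right=valid_r)


# ---------------------------------------------------------------------------
# velocities and vdiff


def leg_velocities(
    track: LegTrack, config: DetectorConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Rollator-frame longitudinal leg velocities on the laser timeline.

    Centered finite differences of the centroid x-coordinate; gaps of up to
    ``max_gap_frames`` invalid scans are bridged by linear interpolation,
    longer gaps leave the velocity undefined (NaN).
    """
    config = config or DetectorConfig()
    out = []
    for side in ("left", "right"):
        pos, valid = track.side(side)
        x = pos[:, 0].copy()
        ok = valid & np.isfinite(x)
        if ok.sum() < 3:
            raise ValidationError(f"fewer than 3 valid frames for {side} leg")
        filled = _bridge_gaps(track.t, x, ok, config.max_gap_frames)
        v = np.full_like(x, np.nan)
        for start, stop in _runs(np.isfinite(filled)):
            if stop - start >= 2:
                v[start:stop] = np.gradient(filled[start:stop], track.t[start:stop])
        out.append(v)
    return out[0], out[1]


def _bridge_gaps(
    t: np.ndarray, x: np.ndarray, ok: np.ndarray, max_gap: int
) -> np.ndarray:
    filled = np.where(ok, x, np.nan)
    idx_ok = np.nonzero(ok)[0]
    for a, b in zip(idx_ok, idx_ok[1:]):
        gap = b - a - 1
        if 0 < gap <= max_gap:
            filled[a + 1 : b] = np.interp(t[a + 1 : b], [t[a], t[b]], [x[a], x[b]])
    return filled


def _runs(mask: np.ndarray):
    """Yield (start, stop) of contiguous True runs."""
    diff = np.diff(mask.astype(int), prepend=0, append=0)
    starts = np.nonzero(diff == 1)[0]
    stops = np.nonzero(diff == -1)[0]
    yield from zip(starts, stops)


def bandpass(
    x: np.ndarray, fs: float, config: DetectorConfig | None = None
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward), same length out."""
    config = config or DetectorConfig()
    low, high = config.passband
    if not 0 < low < high < fs / 2:
        raise ValidationError(
            f"passband {config.passband} must lie inside (0, Nyquist={fs / 2})"
        )
    sos = sp_signal.butter(
        config.butterworth_order, [low, high], btype="bandpass", fs=fs, output="sos"
    )
    return sp_signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def compute_vdiff(
    track: LegTrack,
    config: DetectorConfig | None = None,
    velocities: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[VdiffSignal]:
    """Filtered vdiff stretches on a uniform internal timeline.

    vdiff is defined where both leg velocities are; each contiguous defined
    stretch of at least ``min_stretch`` seconds is linearly resampled to
    ``internal_rate`` and bandpassed independently.
    """
    config = config or DetectorConfig()
    v_l, v_r = velocities if velocities is not None else leg_velocities(track, config)
    raw = v_l - v_r
    defined = np.isfinite(raw)
    stretches = []
    for start, stop in _runs(defined):
        t0, t1 = track.t[start], track.t[stop - 1]
        if t1 - t0 < config.min_stretch:
            continue
        n_out = int(math.floor((t1 - t0) * config.internal_rate)) + 1
        tu = t0 + np.arange(n_out) / config.internal_rate
        raw_u = np.interp(tu, track.t[start:stop], raw[start:stop])
        stretches.append(
            VdiffSignal(t=tu, raw=raw_u, filtered=bandpass(raw_u, config.internal_rate, config))
        )
    return stretches


# ---------------------------------------------------------------------------
# event detection


def detect_heel_strikes(
    vdiff: VdiffSignal, config: DetectorConfig | None = None
) -> list[HeelStrikeEvent]:
    """Heel contacts from the peaks of filtered vdiff.

    Local maxima above ``+peak_threshold`` are left events, minima below
    ``-peak_threshold`` right events; peaks closer than ``min_event_gap`` to
    a larger same-sign peak are suppressed.  When ``swing_fraction`` > 0
    each peak (mid-swing by kinematics) is shifted forward by half the
    swing duration, estimated as ``swing_fraction`` times the local
    inter-event interval.
    """
    config = config or DetectorConfig()
    t = vdiff.t
    if t.size < 3:
        return []
    fs = 1.0 / float(np.median(np.diff(t)))
    dist = max(1, int(round(config.min_event_gap * fs)))
    pk_l, _ = sp_signal.find_peaks(vdiff.filtered, height=config.peak_threshold, distance=dist)
    pk_r, _ = sp_signal.find_peaks(-vdiff.filtered, height=config.peak_threshold, distance=dist)
    idx = np.concatenate([pk_l, pk_r])
    sides = ["left"] * pk_l.size + ["right"] * pk_r.size
    order = np.argsort(idx)
    times = t[idx[order]]
    sides = [sides[i] for i in order]
    values = vdiff.filtered[idx[order]]

    if config.swing_fraction > 0 and times.size >= 2:
        gaps = np.diff(times)
        gap_for = np.append(gaps, gaps[-1])
        times = times + 0.5 * config.swing_fraction * gap_for

    events = [
        HeelStrikeEvent(t=float(ti), side=s, source="laser", peak_value=float(v))
        for ti, s, v in zip(times, sides, values)
    ]
    events.sort(key=lambda e: e.t)
    return events


def detect_events(
    session: SensorSession,
    area: DetectionArea | None = None,
    config: DetectorConfig | None = None,
) -> tuple[list[HeelStrikeEvent], LegTrack, tuple[np.ndarray, np.ndarray], list[VdiffSignal]]:
    """Laser pipeline: track legs, estimate velocities, detect contacts.

    Events are stitched across vdiff stretches.  Returns intermediates for
    audit (track, velocities, vdiff stretches).
    """
    config = config or DetectorConfig()
    track = track_legs(session, area, config)
    vels = leg_velocities(track, config)
    stretches = compute_vdiff(track, config, vels)
    events: list[HeelStrikeEvent] = []
    for s in stretches:
        events.extend(detect_heel_strikes(s, config))
    events.sort(key=lambda e: e.t)
    return events, track, vels, stretches


# ---------------------------------------------------------------------------
# support phases


def label_support_phases(
    t: np.ndarray,
    v_left: np.ndarray,
    v_right: np.ndarray,
    config: DetectorConfig | None = None,
    rollator_speed: np.ndarray | None = None,
    events: list[HeelStrikeEvent] | None = None,
) -> list[SupportPhase]:
    """Per-sample support labels merged into maximal intervals.

    Double support: both relative velocities negative and within
    ``double_support_band`` of each other; otherwise single support on the
    slower (more negative) leg.  Samples with undefined velocity inherit
    the previous label; intervals shorter than ``min_phase_duration`` are
    absorbed by their longer neighbor.

    When a detected event sequence is supplied, phase boundaries are
    anchored on it instead: each contact starts a double-support interval
    lasting ``1 - swing_fraction`` of the step, followed by single support
    on the contact side.  At slow scan rates the brief double-support
    windows span barely one scan, so the instantaneous rule blurs them;
    contact times are localized far more precisely than per-sample
    velocities, making the anchored labeling the accurate choice whenever
    events are available.
    """
    config = config or DetectorConfig()
    if events is not None and len(events) >= 2:
        return _phases_from_event_anchor(t, events, config)
    t = np.asarray(t, dtype=float)
    n = t.size
    labels = np.empty(n, dtype=object)
    labels[:] = None
    defined = np.isfinite(v_left) & np.isfinite(v_right)
    both_neg = (v_left < 0) & (v_right < 0)
    close = np.abs(v_left - v_right) < config.double_support_band
    for i in range(n):
        if not defined[i]:
            continue
        if both_neg[i] and close[i]:
            labels[i] = "double"
        elif v_left[i] < v_right[i]:
            labels[i] = "single_left"
        elif v_right[i] < v_left[i]:
            labels[i] = "single_right"
        else:
            labels[i] = "double"
    # forward/backward fill undefined samples
    last = None
    for i in range(n):
        if labels[i] is None:
            labels[i] = last
        else:
            last = labels[i]
    nxt = None
    for i in range(n - 1, -1, -1):
        if labels[i] is None:
            labels[i] = nxt
        else:
            nxt = labels[i]
    if labels[0] is None:
        return []

    # sample i owns [mid(i-1,i), mid(i,i+1)]
    mids = np.concatenate([[t[0]], 0.5 * (t[:-1] + t[1:]), [t[-1]]])
    intervals: list[list] = []
    for i in range(n):
        if intervals and intervals[-1][2] == labels[i]:
            intervals[-1][1] = mids[i + 1]
        else:
            intervals.append([mids[i], mids[i + 1], labels[i]])

    # absorb too-short intervals into the longer neighbor
    changed = True
    while changed and len(intervals) > 1:
        changed = False
        for i, iv in enumerate(intervals):
            if iv[1] - iv[0] >= config.min_phase_duration:
                continue
            left_nb = intervals[i - 1] if i > 0 else None
            right_nb = intervals[i + 1] if i < len(intervals) - 1 else None
            if left_nb is None:
                target = right_nb
            elif right_nb is None:
                target = left_nb
            else:
                target = (
                    left_nb
                    if (left_nb[1] - left_nb[0]) >= (right_nb[1] - right_nb[0])
                    else right_nb
                )
            if target is left_nb:
                left_nb[1] = iv[1]
            else:
                target[0] = iv[0]
            intervals.pop(i)
            changed = True
            break
    # merge any now-adjacent equal labels
    merged: list[list] = []
    for iv in intervals:
        if merged and merged[-1][2] == iv[2]:
            merged[-1][1] = iv[1]
        else:
            merged.append(iv)
    return [SupportPhase(float(a), float(b), lab) for a, b, lab in merged]


def clean_alternating(events: list[HeelStrikeEvent]) -> list[HeelStrikeEvent]:
    """Drop non-alternating same-side duplicates, keeping the larger peak."""
    cleaned: list[HeelStrikeEvent] = []
    for ev in sorted(events, key=lambda e: e.t):
        if cleaned and cleaned[-1].side == ev.side:
            if abs(ev.peak_value) > abs(cleaned[-1].peak_value):
                cleaned[-1] = ev
        else:
            cleaned.append(ev)
    return cleaned


def _phases_from_event_anchor(
    t: np.ndarray, events: list[HeelStrikeEvent], config: DetectorConfig
) -> list[SupportPhase]:
    """Phase partition anchored on contact instants.

    Covers [t[0], t[-1]]; the margins before the first and after the last
    event continue the pattern using the neighboring step duration.
    """
    ev = clean_alternating(events)
    if len(ev) < 2:
        return []
    f = config.swing_fraction if config.swing_fraction > 0 else 0.62
    t0, t1 = float(t[0]), float(t[-1])
    phases: list[SupportPhase] = []

    def add(a: float, b: float, label: str) -> None:
        a, b = max(a, t0), min(b, t1)
        if b > a:
            phases.append(SupportPhase(a, b, label))

    first_step = ev[1].t - ev[0].t
    # before the first contact: single support on the other side, preceded
    # by a nominal double-support window
    prev_side = "right" if ev[0].side == "left" else "left"
    add(t0, ev[0].t - f * first_step, "double")
    add(ev[0].t - f * first_step, ev[0].t, f"single_{prev_side}")
    for a, b in zip(ev, ev[1:]):
        split = a.t + (1.0 - f) * (b.t - a.t)
        add(a.t, split, "double")
        add(split, b.t, f"single_{a.side}")
    last_step = ev[-1].t - ev[-2].t
    add(ev[-1].t, ev[-1].t + (1.0 - f) * last_step, "double")
    add(ev[-1].t + (1.0 - f) * last_step, t1, f"single_{ev[-1].side}")
    return phases


# ---------------------------------------------------------------------------
# legacy force-difference detector


def detect_heel_strikes_force(
    loads: LoadStream, config: DetectorConfig | None = None
) -> tuple[list[HeelStrikeEvent], bool, FdiffSignal]:
    """Contacts from handlebar force difference; flagged by the 7 N gate.

    fdiff = (left - right) in newtons, low-passed with a zero-phase
    Butterworth filter; maxima are left events, minima right events (the
    contact side's handle is loaded harder).  ``valid`` is False when the
    peak-to-peak filtered fdiff falls below ``force_validity_threshold``:
    events are still returned but should not be trusted.
    """
    config = config or DetectorConfig()
    t = loads.t
    if t.size < 2 or t[-1] - t[0] < 2.0:
        raise ValidationError("force detector needs at least 2 s of load data")
    fdiff = (loads.left_load - loads.right_load) * GRAVITY

    fs = config.internal_rate
    n_out = int(math.floor((t[-1] - t[0]) * fs)) + 1
    tu = t[0] + np.arange(n_out) / fs
    raw_u = np.interp(tu, t, fdiff)
    sos = sp_signal.butter(
        config.butterworth_order, config.force_cutoff, btype="lowpass", fs=fs, output="sos"
    )
    filt = sp_signal.sosfiltfilt(sos, raw_u)
    p2p = float(filt.max() - filt.min()) if filt.size else 0.0

    # fdiff oscillates once per stride, so extrema sit a stride apart
    dist = max(1, int(round(2 * config.min_event_gap * fs)))
    prom = max(0.1, 0.2 * p2p)
    pk_l, _ = sp_signal.find_peaks(filt, distance=dist, prominence=prom)
    pk_r, _ = sp_signal.find_peaks(-filt, distance=dist, prominence=prom)
    events = [
        HeelStrikeEvent(t=float(tu[i]), side="left", source="force", peak_value=float(filt[i]))
        for i in pk_l
    ] + [
        HeelStrikeEvent(t=float(tu[i]), side="right", source="force", peak_value=float(filt[i]))
        for i in pk_r
    ]
    events.sort(key=lambda e: e.t)
    valid = p2p >= config.force_validity_threshold
    return events, valid, FdiffSignal(t=tu, raw=raw_u, filtered=filt, peak_to_peak=p2p)
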