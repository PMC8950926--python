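"""Leg tracking, filtering, event detection and support labeling."""

import itertools
import math

import numpy as np
import pytest

from rollagait import (
    DetectionArea,
    DetectorConfig,
    LaserScan,
    LegTrack,
    LoadStream,
    SimulationConfig,
    ValidationError,
    VdiffSignal,
    bandpass,
    cluster_legs,
    clean_alternating,
    default_frame_graph,
    detect_heel_strikes,
    detect_heel_strikes_force,
    filter_detection_area,
    label_support_phases,
    leg_velocities,
    simulate_session,
    track_legs,
)
from rollagait.session import LOAD_RESOLUTION


# ---------------------------------------------------------------------------
# detection area


def test_all_out_of_range_scan_yields_empty_cloud():
    scan = LaserScan(
        t=0.0,
        angle_start=-math.pi,
        angle_increment=math.radians(1),
        ranges=np.full(360, np.inf),
    )
    assert filter_detection_area(scan).shape == (0, 2)


def test_boundary_points_are_retained():
    area = DetectionArea()
    # a beam pointing backwards from the laser at (0.30, 0), hitting exactly
    # the near edge of the detection area, x = -0.1
    rng = np.full(360, np.inf)
    idx = 0  # angle -pi: the beam points backwards along -x
    rng[idx] = 0.40
    scan = LaserScan(
        t=0.0, angle_start=-math.pi, angle_increment=math.radians(1), ranges=rng
    )
    pts = filter_detection_area(scan, area, default_frame_graph())
    assert pts.shape == (1, 2)
    assert pts[0, 0] == pytest.approx(-0.1, abs=1e-12)


def test_rendered_leg_points_cluster_around_it(short_config):
    cfg = SimulationConfig.from_dict(
        {**short_config.to_dict(), "dropout_prob": 0.0}
    )
    session, gt = simulate_session(cfg)
    i = len(session.laser) // 2
    pts = filter_detection_area(session.laser[i], None, session.frames)
    centers = np.array(
        [gt.leg_positions["left"][i], gt.leg_positions["right"][i]]
    )
    dmin = np.min(
        np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2), axis=1
    )
    assert np.all(dmin <= cfg.leg_radius + 3 * cfg.laser_noise_sd)


# ---------------------------------------------------------------------------
# clustering


def _blobs(rng, centers, n_per=20, sd=0.01):
    return np.vstack(
        [c + rng.normal(0, sd, size=(n_per, 2)) for c in centers]
    )


def test_separated_blobs_recover_their_means():
    rng = np.random.default_rng(0)
    c_left, c_right = np.array([-0.5, 0.12]), np.array([-0.5, -0.12])
    cloud = _blobs(rng, [c_left, c_right])
    lc, rc, vl, vr = cluster_legs(cloud)
    assert vl and vr
    np.testing.assert_allclose(lc, cloud[:20].mean(axis=0), atol=1e-9)
    np.testing.assert_allclose(rc, cloud[20:].mean(axis=0), atol=1e-9)


def test_single_blob_marks_other_side_invalid():
    rng = np.random.default_rng(1)
    cloud = _blobs(rng, [np.array([-0.5, 0.12])], n_per=15)
    lc, rc, vl, vr = cluster_legs(cloud)
    assert vl and not vr
    assert rc is None
    np.testing.assert_allclose(lc, cloud.mean(axis=0), atol=1e-9)


def test_tiny_cluster_is_invalid():
    rng = np.random.default_rng(2)
    cloud = np.vstack(
        [_blobs(rng, [np.array([-0.5, 0.12])], n_per=20),
         np.array([[-0.5, -0.12], [-0.51, -0.12]])]
    )
    _, _, vl, vr = cluster_legs(cloud, config=DetectorConfig(min_cluster_points=3))
    assert vl and not vr


def test_empty_cloud_is_fully_invalid():
    lc, rc, vl, vr = cluster_legs(np.empty((0, 2)))
    assert lc is None and rc is None and not vl and not vr


def _brute_force_cost(cloud):
    """Optimal 2-partition cost by exhaustive enumeration (n <= 12)."""
    n = len(cloud)
    best = math.inf
    for bits in itertools.product([0, 1], repeat=n - 1):
        assign = np.array((0,) + bits)
        cost = 0.0
        for k in (0, 1):
            sel = cloud[assign == k]
            if len(sel):
                cost += float(np.sum((sel - sel.mean(axis=0)) ** 2))
        best = min(best, cost)
    return best


@pytest.mark.parametrize("seed", range(8))
def test_two_means_matches_brute_force_on_separable_clouds(seed):
    # blob separation > 4x blob radius guarantees a unique optimum
    rng = np.random.default_rng(seed)
    n_a = int(rng.integers(3, 9))
    n_b = int(rng.integers(3, 13 - n_a))
    cloud = np.vstack(
        [
            np.array([-0.5, 0.15]) + rng.uniform(-0.02, 0.02, size=(n_a, 2)),
            np.array([-0.5, -0.15]) + rng.uniform(-0.02, 0.02, size=(n_b, 2)),
        ]
    )
    lc, rc, _, _ = cluster_legs(cloud, config=DetectorConfig(min_cluster_points=1))
    centers = np.array([lc, rc])
    assign = np.argmin(
        np.linalg.norm(cloud[:, None] - centers[None], axis=2), axis=1
    )
    cost = sum(
        float(np.sum((cloud[assign == k] - cloud[assign == k].mean(axis=0)) ** 2))
        for k in (0, 1)
        if np.any(assign == k)
    )
    assert cost == pytest.approx(_brute_force_cost(cloud), abs=1e-9)


def test_two_means_agrees_with_sklearn_reference():
    from sklearn.cluster import KMeans

    rng = np.random.default_rng(3)
    cloud = _blobs(rng, [np.array([-0.4, 0.1]), np.array([-0.7, -0.1])], n_per=25)
    lc, rc, _, _ = cluster_legs(cloud)
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(cloud)
    ours = sorted([tuple(np.round(lc, 9)), tuple(np.round(rc, 9))])
    theirs = sorted(tuple(np.round(c, 9)) for c in km.cluster_centers_)
    np.testing.assert_allclose(ours, theirs, atol=1e-6)


def test_side_labels_stay_consistent_across_session(default_trial):
    session, _ = default_trial
    track = track_legs(session)
    both = track.valid_left & track.valid_right
    assert both.mean() > 0.8
    assert np.all(track.left[both, 1] >= track.right[both, 1])


# ---------------------------------------------------------------------------
# velocities


def _track_from_x(t, x_left, x_right):
    n = t.size
    left = np.column_stack([x_left, np.full(n, 0.12)])
    right = np.column_stack([x_right, np.full(n, -0.12)])
    return LegTrack(
        t=t,
        left=left,
        right=right,
        valid_left=np.ones(n, dtype=bool),
        valid_right=np.ones(n, dtype=bool),
    )


def test_stationary_centroids_have_zero_velocity():
    t = np.arange(50) / 5.5
    track = _track_from_x(t, np.full(50, -0.5), np.full(50, -0.6))
    vl, vr = leg_velocities(track)
    np.testing.assert_allclose(vl, 0.0, atol=1e-12)
    np.testing.assert_allclose(vr, 0.0, atol=1e-12)


def test_velocities_need_three_valid_frames():
    t = np.arange(5) / 5.5
    track = _track_from_x(t, np.full(5, -0.5), np.full(5, -0.6))
    track.valid_left[:] = [True, True, False, False, False]
    with pytest.raises(ValidationError):
        leg_velocities(track)


def test_stance_velocity_tracks_rollator_speed(default_trial):
    session, gt = default_trial
    track = track_legs(session)
    vl, vr = leg_velocities(track)
    v = SimulationConfig().base_speed
    # during ground-truth single_left phases the left leg is the still one
    for t0, t1, lab in gt.support_phases:
        if lab != "single_left" or t0 < 5:
            continue
        mid = (t0 + t1) / 2
        i = int(np.argmin(np.abs(track.t - mid)))
        if np.isfinite(vl[i]):
            assert vl[i] == pytest.approx(-v, abs=0.05)
        if np.isfinite(vr[i]) and abs(track.t[i] - mid) < 0.05:
            assert vr[i] > 0  # the swinging limb moves forwards
        if t0 > 30:
            break


def test_short_gaps_are_bridged_longer_gaps_stay_undefined():
    t = np.arange(40) / 5.5
    x = -0.5 + 0.01 * np.arange(40)
    track = _track_from_x(t, x, x)
    track.valid_left[10:12] = False  # 2-frame gap: bridged
    track.valid_right[20:25] = False  # 5-frame gap: undefined
    vl, vr = leg_velocities(track)
    assert np.all(np.isfinite(vl))
    assert np.all(~np.isfinite(vr[21:24]))


# ---------------------------------------------------------------------------
# bandpass


def test_bandpass_preserves_in_band_sinusoid():
    fs = 50.0
    t = np.arange(0, 30, 1 / fs)
    x = np.sin(2 * math.pi * 1.0 * t)
    y = bandpass(x, fs)
    mid = (t > 5) & (t < 25)
    # amplitude within 5%
    assert abs(y[mid].max() - 1.0) < 0.05
    # zero-phase: group delay at 1 Hz below 10 ms (quadrature projection)
    def phase(sig):
        return math.atan2(
            float(np.sum(sig[mid] * np.cos(2 * math.pi * t[mid]))),
            float(np.sum(sig[mid] * np.sin(2 * math.pi * t[mid]))),
        )

    delay = (phase(y) - phase(x)) / (2 * math.pi * 1.0)
    assert abs(delay) < 0.010


def test_bandpass_removes_dc():
    fs = 50.0
    x = np.full(2000, 5.0)
    assert abs(np.mean(bandpass(x, fs))) < 1e-3


def test_bandpass_attenuates_high_frequency():
    fs = 50.0
    t = np.arange(0, 30, 1 / fs)
    y = bandpass(np.sin(2 * math.pi * 10.0 * t), fs)
    assert np.max(np.abs(y[200:-200])) < 0.1  # > 90% attenuation


def test_bandpass_is_linear():
    fs = 50.0
    rng = np.random.default_rng(0)
    x = rng.normal(size=1500)
    np.testing.assert_allclose(bandpass(3.7 * x, fs), 3.7 * bandpass(x, fs), atol=1e-9)


def test_passband_above_nyquist_rejected():
    with pytest.raises(ValidationError):
        bandpass(np.zeros(100), 5.5)  # default 0.3-3.0 Hz band, Nyquist 2.75


# ---------------------------------------------------------------------------
# event detection


def test_sinusoid_vdiff_yields_symmetric_events():
    fs = 50.0
    t = np.arange(0, 10, 1 / fs)
    x = 0.5 * np.sin(2 * math.pi * 1.0 * t)
    sig = VdiffSignal(t=t, raw=x, filtered=x)
    events = detect_heel_strikes(sig, DetectorConfig(swing_fraction=0.0))
    assert sum(e.side == "left" for e in events) == 10
    assert sum(e.side == "right" for e in events) == 10


def test_silent_signal_yields_no_events():
    t = np.arange(0, 10, 0.02)
    sig = VdiffSignal(t=t, raw=np.zeros_like(t), filtered=np.zeros_like(t))
    assert detect_heel_strikes(sig) == []


def test_events_alternate_on_clean_straight_walk():
    cfg = SimulationConfig(seed=8, laser_noise_sd=0.0, dropout_prob=0.0)
    session, _ = simulate_session(cfg)
    from rollagait import analyze_session

    events = clean_alternating(analyze_session(session).events)
    sides = [e.side for e in events]
    assert all(a != b for a, b in zip(sides, sides[1:]))


def test_detection_survives_heavy_dropout():
    cfg = SimulationConfig(seed=9, dropout_prob=0.3)
    session, gt = simulate_session(cfg)
    from rollagait import analyze_session

    report = analyze_session(session).report  # must not crash
    assert report.nos > 0


# ---------------------------------------------------------------------------
# support phases


def test_slower_leg_rule_closed_forms():
    t = np.arange(30) / 5.5
    v = 0.5
    single = label_support_phases(t, np.full(30, -v), np.full(30, +v))
    assert [p.label for p in single] == ["single_left"]
    double = label_support_phases(t, np.full(30, -v), np.full(30, -v))
    assert [p.label for p in double] == ["double"]


def test_event_anchored_phases_agree_with_ground_truth(default_trial, default_result):
    from helpers import phase_label_at

    _, gt = default_trial
    tq = np.arange(0.0, 60.0, 0.02)
    g = phase_label_at(gt.support_phases, tq)
    p = phase_label_at(default_result.phases, tq)
    m = (g != None) & (p != None)  # noqa: E711
    assert np.mean(g[m] == p[m]) >= 0.90


# ---------------------------------------------------------------------------
# force detector


def _quantized_loads(t, left, right):
    q = lambda v: np.round(v / LOAD_RESOLUTION) * LOAD_RESOLUTION
    return LoadStream(t=t, left_load=q(left), right_load=q(right))


def test_force_detector_validity_gate():
    session, gt = simulate_session(SimulationConfig(seed=11))
    events, valid, fdiff = detect_heel_strikes_force(session.loads)
    assert valid and fdiff.peak_to_peak >= 14.0
    n_true = gt.true_params["NoS"]
    assert abs(len(events) - n_true) / n_true <= 0.10

    weak, _ = simulate_session(SimulationConfig(seed=12, handle_modulation=0.2))
    _, valid_weak, fd_weak = detect_heel_strikes_force(weak.loads)
    assert not valid_weak and fd_weak.peak_to_peak < 7.0


def test_zero_difference_loads_produce_no_events():
    t = np.arange(0, 30, 0.4)
    loads = _quantized_loads(t, np.full(t.size, 5.0), np.full(t.size, 5.0))
    events, valid, _ = detect_heel_strikes_force(loads)
    assert events == [] and not valid


def test_force_detector_needs_two_seconds():
    t = np.arange(0, 1.2, 0.4)
    loads = _quantized_loads(t, np.full(t.size, 5.0), np.full(t.size, 4.0))
    with pytest.raises(ValidationError):
        detect_heel_strikes_force(loads)
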