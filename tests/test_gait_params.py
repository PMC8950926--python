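"""Spatiotemporal parameters, support metrics, weight bearing, aggregation."""

import math

import numpy as np
import pytest

from helpers import REFERENCE_TABLE
from rollagait import (
    GRAVITY,
    AnalysisError,
    HeelStrikeEvent,
    LoadStream,
    PathSegment,
    SideFactors,
    SimulationConfig,
    SteeringBins,
    SupportPhase,
    ValidationError,
    aggregate_reports,
    analyze_session,
    integrate_pose,
    partial_weight_bearing,
    report_to_row,
    simulate_session,
    spatiotemporal,
    support_metrics,
)
from rollagait.session import LOAD_RESOLUTION


def _uniform_events(n=20, dt=0.5, start=0.5):
    return [
        HeelStrikeEvent(
            t=start + i * dt,
            side="left" if i % 2 == 0 else "right",
            source="laser",
            peak_value=1.0,
        )
        for i in range(n)
    ]


def _constant_speed_poses(v=0.6, duration=60.0):
    t = np.linspace(0, duration, int(duration * 50) + 1)
    return integrate_pose(t, np.full_like(t, v), np.zeros_like(t))


def test_uniform_cadence_closed_forms():
    poses = _constant_speed_poses(v=0.6)
    params = spatiotemporal(_uniform_events(), poses, tr=60.0)
    for side in ("left", "right"):
        assert params[f"spt_{side}"].mean == pytest.approx(0.5, abs=1e-9)
        assert params[f"spt_{side}"].sd == pytest.approx(0.0, abs=1e-9)
        assert params[f"spl_{side}"].mean == pytest.approx(0.3, abs=1e-6)
    assert params["sdt"].mean == pytest.approx(1.0, abs=1e-9)
    assert params["sdl"].mean == pytest.approx(0.6, abs=1e-6)
    assert params["cad"] == pytest.approx(20.0)  # 20 events in 60 s


def test_definitional_identities_hold_exactly():
    poses = _constant_speed_poses()
    params = spatiotemporal(_uniform_events(), poses, tr=60.0)
    assert params["cad"] * params["tr"] / 60.0 == pytest.approx(params["nos"], abs=1e-9)
    assert params["wv"] * params["tr"] == pytest.approx(params["d"], abs=1e-9)


def test_step_times_sum_to_stride_time():
    poses = _constant_speed_poses()
    params = spatiotemporal(_uniform_events(), poses, tr=60.0)
    assert params["spt_left"].mean + params["spt_right"].mean == pytest.approx(
        params["sdt"].mean, abs=1e-9
    )


def test_insufficient_events_raise():
    poses = _constant_speed_poses()
    with pytest.raises(ValidationError, match="insufficient steps"):
        spatiotemporal(_uniform_events(n=3), poses, tr=60.0)


def test_non_alternating_duplicates_keep_larger_peak():
    events = _uniform_events(n=8)
    # inject a weaker same-side duplicate right after the third event
    dup = HeelStrikeEvent(t=events[2].t + 0.1, side=events[2].side,
                          source="laser", peak_value=0.1)
    poses = _constant_speed_poses()
    params = spatiotemporal(events + [dup], poses, tr=60.0)
    assert params["nos"] == 8


# ---------------------------------------------------------------------------
# support metrics


def _constant_loads(total_kg, duration=20.0, rate=2.5):
    t = np.arange(0, duration, 1 / rate)
    half = np.round(total_kg / 2 / LOAD_RESOLUTION) * LOAD_RESOLUTION
    return LoadStream(t=t, left_load=np.full(t.size, half), right_load=np.full(t.size, half))


def test_constant_load_support_closed_form():
    loads = _constant_loads(10.0)
    urs_kg, urs_n, wb_inv, _ = support_metrics(loads, _uniform_events())
    assert urs_kg == pytest.approx(10.0, abs=2 * LOAD_RESOLUTION)
    assert urs_n == pytest.approx(10.0 * GRAVITY, rel=1e-3)
    assert wb_inv == pytest.approx(1.0 / (10.0 * GRAVITY), rel=1e-3)


def test_zero_load_weight_bearing_undefined_not_infinite():
    loads = _constant_loads(0.0)
    urs_kg, urs_n, wb_inv, _ = support_metrics(loads, _uniform_events())
    assert urs_kg == 0.0 and wb_inv is None


def test_simulated_support_matches_configured_mean(default_result):
    assert abs(default_result.report.urs_kg - 10.0) / 10.0 < 0.05


# ---------------------------------------------------------------------------
# partial weight bearing


def _single_phases(duration=20.0, step=0.5):
    phases = []
    side = "left"
    t = 0.0
    while t < duration:
        phases.append(SupportPhase(t, t + step, f"single_{side}"))
        side = "right" if side == "left" else "left"
        t += step
    return phases


def test_zero_handle_load_gives_full_weight_on_leg():
    loads = _constant_loads(0.0)
    pwb = partial_weight_bearing(loads, _single_phases(), user_weight=70.0)
    assert pwb.left == pytest.approx(100.0)
    assert pwb.right == pytest.approx(100.0)


def test_fifth_of_body_weight_on_handles_gives_eighty_percent():
    w = 68.75  # chosen so 0.2*W/2 is an exact multiple of the 5.5 g step
    loads = _constant_loads(0.2 * w)
    pwb = partial_weight_bearing(loads, _single_phases(), user_weight=w)
    assert pwb.left == pytest.approx(80.0, abs=1e-9)
    assert pwb.right == pytest.approx(80.0, abs=1e-9)


def test_pwb_and_handle_fraction_sum_to_hundred(default_trial, default_result):
    session, _ = default_trial
    loads = session.loads
    phases = default_result.phases
    w = session.user_weight
    for ph in phases[:40]:
        if not ph.label.startswith("single"):
            continue
        sel = (loads.t >= ph.t_start) & (loads.t < ph.t_end)
        pwb = 100.0 * (w - loads.total[sel]) / w
        handle = 100.0 * loads.total[sel] / w
        np.testing.assert_allclose(pwb + handle, 100.0, atol=1e-9)


def test_invalid_user_weight_rejected():
    with pytest.raises(ValidationError):
        partial_weight_bearing(_constant_loads(5.0), _single_phases(), user_weight=0.0)


def test_stance_load_boost_lowers_that_side_weight_bearing():
    cfg = SimulationConfig(seed=7, stance_load_factor=SideFactors(1.0, 1.7))
    session, _ = simulate_session(cfg)
    report = analyze_session(session).report
    expected = 100.0 * 10.0 * (1.7 - 1.0) / 70.0  # configured pwb asymmetry
    assert report.pwb.right < report.pwb.left
    assert report.pwb.left - report.pwb.right == pytest.approx(expected, abs=3.0)


def test_steering_bins_follow_reporting_sign_convention():
    bins = SteeringBins()
    # omega_report = -omega_odometry: a left turn reports negative
    assert bins.assign(np.array([-0.5]))[0] == 0
    assert bins.assign(np.array([0.0]))[0] == 2
    assert bins.assign(np.array([+0.5]))[0] == 4
    with pytest.raises(ValidationError):
        SteeringBins(edges=(0.0, -1.0))


def test_pwb_binned_by_steering_populates_straight_bin(default_trial, default_result):
    by = default_result.report.pwb.by_steering
    labels = SteeringBins().labels
    straight = by[labels[2]]
    assert straight["n_left"] > 0 and straight["n_right"] > 0
    assert straight["left"] == pytest.approx(default_result.report.pwb.left, abs=1.0)


# ---------------------------------------------------------------------------
# aggregation


def test_reference_table_average_row():
    table, means = aggregate_reports(REFERENCE_TABLE)
    assert means["CAD"] == pytest.approx(93.41, abs=0.01)
    assert means["SdL"] == pytest.approx(0.63, abs=0.01)
    assert means["WV"] == pytest.approx(0.72, abs=0.01)
    assert means["rSpL"] == pytest.approx(0.32, abs=0.01)
    assert means["lSpL"] == pytest.approx(0.31, abs=0.01)
    assert means["UrS"] == pytest.approx(15.21, abs=0.01)
    assert table.iloc[2]["UrS"] == "<1"
    assert table.iloc[-1]["User"] == "Av."


def test_single_report_average_equals_the_row(default_result):
    row = report_to_row(default_result.report, user="solo")
    table, means = aggregate_reports([row])
    assert means["CAD"] == pytest.approx(default_result.report.cad)
    assert table.iloc[0]["CAD"] == table.iloc[1]["CAD"]


def test_aggregation_matches_brute_force_recomputation():
    _, means = aggregate_reports(REFERENCE_TABLE)
    for col in ("CAD", "WV"):
        brute = sum(r[col] for r in REFERENCE_TABLE) / len(REFERENCE_TABLE)
        assert means[col] == pytest.approx(brute, abs=1e-12)
    for col in ("SdT", "SdL", "rSpT", "lSpT", "rSpL", "lSpL"):
        brute = sum(r[col][0] for r in REFERENCE_TABLE) / len(REFERENCE_TABLE)
        assert means[col] == pytest.approx(brute, abs=1e-12)
    brute_urs = sum(
        (r["UrS"] or 0.0) if (r["UrS"] or 0.0) >= 1.0 else 0.0
        for r in REFERENCE_TABLE
    ) / len(REFERENCE_TABLE)
    assert means["UrS"] == pytest.approx(brute_urs, abs=1e-12)


# ---------------------------------------------------------------------------
# full pipeline


def test_default_session_report_is_fully_populated(default_result):
    r = default_result.report
    assert r.nos > 0 and r.cad > 0 and r.d > 0 and r.wv > 0
    assert r.source == "laser"
    assert r.urs_kg is not None and r.pwb is not None
    assert math.isfinite(r.sdt.mean) and math.isfinite(r.sdl.mean)
    d = r.to_dict()
    assert d["CAD"] == r.cad and d["pwb_left"] == r.pwb.left


def test_laser_free_session_falls_back_to_force_events():
    session, _ = simulate_session(SimulationConfig(seed=13))
    session.laser = []
    report = analyze_session(session, source="force").report
    assert report.source == "force"
    assert report.nos >= 4 and report.pwb is not None


def test_too_short_session_reports_insufficient_steps():
    cfg = SimulationConfig(seed=14, path=(PathSegment(2.0, 0.0),))
    session, _ = simulate_session(cfg)
    with pytest.raises(AnalysisError, match="insufficient steps"):
        analyze_session(session)


@pytest.mark.parametrize("seed,asym", [(21, 1.0), (22, 1.15)])
def test_parameter_recovery_symmetric_and_asymmetric(seed, asym):
    cfg = SimulationConfig(
        seed=seed,
        cadence=88.0,
        step_time_asymmetry=SideFactors(asym, 2.0 - asym),
    )
    session, gt = simulate_session(cfg)
    report = analyze_session(session).report
    tp = gt.true_params
    assert abs(report.cad - tp["CAD"]) / tp["CAD"] < 0.05
    assert abs(report.sdl.mean - tp["SdL"]) / tp["SdL"] < 0.07
    if asym != 1.0:  # slower side has the longer step time
        assert (report.spt_left.mean > report.spt_right.mean) == (asym > 1.0)
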