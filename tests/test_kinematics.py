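"""Kinematic statistics: smoothing, speed, tortuosity, turn angles, trials."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from navscope.io import Trajectory
from navscope.kinematics import (compute_speed_accel, compute_tortuosity,
                                 compute_turn_angles, count_arm_entries,
                                 direction_series, extract_navigation_trials,
                                 label_immobility, learning_metrics,
                                 openfield_metrics, phase_series,
                                 running_speed_threshold, smooth_centroid,
                                 assign_regions)
from _helpers import make_trajectory


# --------------------------------------------------------------------------
# smoothing
# --------------------------------------------------------------------------
def test_smooth_constant_is_fixed_point():
    traj = make_trajectory(np.full(50, 3.0), np.full(50, -2.0))
    out = smooth_centroid(traj, 0.5)
    np.testing.assert_allclose(out.x, 3.0)
    np.testing.assert_allclose(out.y, -2.0)


def test_smooth_impulse_becomes_plateau():
    # 5-frame window at 10 Hz: a unit impulse spreads to height 1/5
    x = np.zeros(21)
    x[10] = 1.0
    out = smooth_centroid(make_trajectory(x, np.zeros(21)), 0.5)
    np.testing.assert_allclose(out.x[8:13], 0.2)
    assert out.x[5] == 0.0


def test_smooth_preserves_linear_ramp_interior():
    x = np.arange(40, dtype=float)
    out = smooth_centroid(make_trajectory(x, x * 2), 0.5)
    np.testing.assert_allclose(out.x[3:-3], x[3:-3], atol=1e-12)


def test_smooth_window_too_long_raises():
    with pytest.raises(ValueError, match="longer"):
        smooth_centroid(make_trajectory(np.zeros(3), np.zeros(3)), 5.0)


# --------------------------------------------------------------------------
# speed / acceleration
# --------------------------------------------------------------------------
def test_constant_velocity_speed_and_zero_accel():
    t = np.arange(50) / 10.0
    kin = compute_speed_accel(make_trajectory(t * 4.0, np.zeros(50)))
    np.testing.assert_allclose(kin.speed[1:], 4.0)
    np.testing.assert_allclose(kin.acceleration[2:], 0.0, atol=1e-9)
    assert not kin.valid[0]


def test_speed_ramp_gives_constant_acceleration():
    # speed 0 -> 10 cm/s over 2 s: acceleration = 5 cm/s^2
    fr = 10.0
    t = np.arange(0, 2.0 + 1e-9, 1 / fr)
    x = 0.5 * 5.0 * t**2  # integrates a linear speed ramp
    kin = compute_speed_accel(make_trajectory(x, np.zeros_like(x)))
    np.testing.assert_allclose(kin.acceleration[2:], 5.0, atol=1e-6)


def test_stationary_speed_zero():
    kin = compute_speed_accel(make_trajectory(np.zeros(30), np.zeros(30)))
    np.testing.assert_allclose(kin.speed[1:], 0.0)


def test_speed_invariant_under_time_shift_and_scales_with_space():
    rng = np.random.default_rng(0)
    x, y = rng.standard_normal(40).cumsum(), rng.standard_normal(40).cumsum()
    base = compute_speed_accel(make_trajectory(x, y))
    shifted = Trajectory(timestamps=np.arange(40) / 10.0 + 100.0, x=x, y=y,
                         frame_rate=10.0)
    np.testing.assert_allclose(compute_speed_accel(shifted).speed[1:], base.speed[1:])
    doubled = compute_speed_accel(make_trajectory(2 * x, 2 * y))
    np.testing.assert_allclose(doubled.speed[1:], 2 * base.speed[1:])


# --------------------------------------------------------------------------
# tortuosity
# --------------------------------------------------------------------------
def test_tortuosity_is_one_on_straight_path():
    t = np.arange(200) / 10.0
    traj = make_trajectory(t * 4.0, t * 3.0)
    kin = compute_speed_accel(traj)
    T, _ = compute_tortuosity(traj, kin)
    inner = T[np.isfinite(T)]
    assert len(inner) > 100
    np.testing.assert_allclose(inner, 1.0, atol=1e-6)


def test_tortuosity_matches_arc_chord_on_circle():
    # radius 10 cm at 4 cm/s, 100 Hz sampling: window arc 10 cm = 1 rad,
    # T = arc / chord = 10 / (2 * 10 * sin(0.5))
    fr, R, v = 100.0, 10.0, 4.0
    t = np.arange(0, 60, 1 / fr)
    theta = v * t / R
    traj = make_trajectory(R * np.cos(theta), R * np.sin(theta), frame_rate=fr)
    kin = compute_speed_accel(traj)
    T, _ = compute_tortuosity(traj, kin)
    expected = 1.0 / (2 * np.sin(0.5))  # approx 1.0429
    inner = T[np.isfinite(T)]
    np.testing.assert_allclose(inner.mean(), expected * 10 / 10, atol=1e-3)
    assert abs(np.median(inner) - 1.0429) < 1e-3


def test_tortuosity_out_and_back_is_undefined_not_infinite():
    x = np.concatenate([np.linspace(0, 10, 26), np.linspace(10, 0, 26)[1:]])
    traj = make_trajectory(x, np.zeros_like(x))
    kin = compute_speed_accel(traj)
    T, _ = compute_tortuosity(traj, kin)
    mid = len(x) // 2
    assert not np.isfinite(T[mid])
    assert np.isfinite(T[np.isfinite(T)]).all()


def test_tortuosity_at_least_one_where_defined():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(300).cumsum()
    y = rng.standard_normal(300).cumsum()
    traj = smooth_centroid(make_trajectory(x, y), 0.5)
    kin = compute_speed_accel(traj)
    T, _ = compute_tortuosity(traj, kin)
    assert np.all(T[np.isfinite(T)] >= 1.0 - 1e-9)


def test_tortuosity_summary_undefined_without_running_frames():
    traj = make_trajectory(np.zeros(100), np.zeros(100))
    kin = compute_speed_accel(traj)
    _, summary = compute_tortuosity(traj, kin, speed_threshold=2.0)
    assert np.isnan(summary)


def test_running_speed_threshold_is_mean_of_p75():
    k1 = compute_speed_accel(make_trajectory(np.arange(50) * 0.4, np.zeros(50)))
    k2 = compute_speed_accel(make_trajectory(np.arange(50) * 0.8, np.zeros(50)))
    thr = running_speed_threshold([k1, k2])
    assert thr == pytest.approx((4.0 + 8.0) / 2)


# --------------------------------------------------------------------------
# turn angles
# --------------------------------------------------------------------------
@pytest.mark.parametrize("pts,expected", [
    ([(0, 0), (1, 0), (2, 0)], 0.0),
    ([(0, 0), (1, 0), (1, 1)], 90.0),
    ([(0, 0), (1, 0), (0, 0)], 180.0),
])
def test_turn_angle_three_point_cases(pts, expected):
    x, y = zip(*pts)
    ang, _ = compute_turn_angles(make_trajectory(x, y))
    assert ang[1] == pytest.approx(expected, abs=1e-9)


def test_turn_angle_below_movement_floor_excluded():
    ang, _ = compute_turn_angles(make_trajectory([0, 0.01, 0.02], [0, 0, 0]))
    assert np.isnan(ang[1])


@given(st.floats(-np.pi, np.pi), st.floats(-50, 50), st.floats(-50, 50))
def test_turn_angles_invariant_under_rigid_motion(theta, dx, dy):
    rng = np.random.default_rng(12)
    x = rng.standard_normal(30).cumsum()
    y = rng.standard_normal(30).cumsum()
    base, _ = compute_turn_angles(make_trajectory(x, y))
    c, s = np.cos(theta), np.sin(theta)
    xr = c * x - s * y + dx
    yr = s * x + c * y + dy
    rot, _ = compute_turn_angles(make_trajectory(xr, yr))
    np.testing.assert_allclose(rot[1:-1], base[1:-1], atol=1e-8)


def test_turn_angle_histogram_counts_measured_steps():
    rng = np.random.default_rng(2)
    x = rng.standard_normal(200).cumsum()
    y = rng.standard_normal(200).cumsum()
    ang, hist = compute_turn_angles(make_trajectory(x, y))
    assert sum(hist.values()) == int(np.isfinite(ang).sum())


# --------------------------------------------------------------------------
# immobility
# --------------------------------------------------------------------------
def _kin_from_speed(speed, fr=10.0):
    from navscope.kinematics import KinematicSeries
    speed = np.asarray(speed, dtype=float)
    return KinematicSeries(timestamps=np.arange(len(speed)) / fr, speed=speed,
                           acceleration=np.zeros_like(speed))


def test_immobility_full_session_single_bout():
    bouts = label_immobility(_kin_from_speed(np.zeros(100)))
    assert bouts == [(0, 100)]


def test_immobility_short_dip_excluded():
    speed = np.full(100, 10.0)
    speed[40:49] = 0.5  # 0.9 s below threshold: no bout
    assert label_immobility(_kin_from_speed(speed)) == []


def test_immobility_two_separated_bouts():
    speed = np.full(120, 10.0)
    speed[10:30] = 1.0
    speed[70:90] = 1.0
    assert label_immobility(_kin_from_speed(speed)) == [(10, 30), (70, 90)]


# --------------------------------------------------------------------------
# trials on a hand-scripted session
# --------------------------------------------------------------------------
def _scripted_session(geom, n_round_trips=3, arm3_detour=False):
    """Piecewise path: dwell at arm1 spout, dash to arm2 spout, dwell, return."""
    fr = 10.0
    s1 = np.asarray(geom.spouts["arm1"])
    s2 = np.asarray(geom.spouts["arm2"])
    a3 = geom.centerline_point("arm3", geom.hub_radius + 12.0)
    blocks, events = [], []
    t = 0.0

    def dwell(p, n=15):
        nonlocal t
        blocks.append(np.repeat(p[None, :], n, axis=0))
        t += n / fr

    def dash(a, b, n=20, via=None):
        nonlocal t
        way = [a, np.zeros(2)] + ([via, np.zeros(2)] if via is not None else []) + [b]
        way = np.asarray(way)
        seg = np.hypot(*np.diff(way, axis=0).T)
        cum = np.concatenate([[0], np.cumsum(seg)])
        s = np.linspace(0, cum[-1], n)
        blocks.append(np.column_stack([np.interp(s, cum, way[:, 0]),
                                       np.interp(s, cum, way[:, 1])]))
        t += n / fr

    def deliver(spout_id):
        events.append((t + 0.2, "lick", spout_id))
        events.append((t + 0.2, "water_delivery", spout_id))

    deliver(1)  # reward consumed at the start of each dwell
    dwell(s1)
    expected = []
    for k in range(n_round_trips):
        t_start = t
        dash(s1, s2, via=(a3 if (arm3_detour and k == 0) else None))
        t_arrive = t
        expected.append(("arm1->arm2", t_start, t_arrive))
        deliver(2)
        dwell(s2)
        t_start = t
        dash(s2, s1)
        t_arrive = t
        expected.append(("arm2->arm1", t_start, t_arrive))
        deliver(1)
        dwell(s1)
    xy = np.concatenate(blocks)
    traj = Trajectory(timestamps=np.arange(len(xy)) / fr, x=xy[:, 0],
                      y=xy[:, 1], frame_rate=fr)
    ev = pd.DataFrame(events, columns=["time", "kind", "spout_id"])
    ev["frame"] = np.round(ev["time"].to_numpy() * fr).astype(int)
    return traj, ev, expected


def test_trial_extraction_recovers_scripted_trials(geom):
    traj, ev, expected = _scripted_session(geom)
    kin = compute_speed_accel(traj)
    regions = assign_regions(traj, geom)
    trials = extract_navigation_trials(regions, kin, ev, geom, traj)
    assert len(trials) == len(expected)
    for tr, (direction, t_start, t_arrive) in zip(trials, expected):
        assert tr.direction == direction
        assert abs(tr.start_frame - t_start * 10) <= 1
        # end frame: first frame inside the destination reward zone
        assert tr.end_frame <= t_arrive * 10 + 1
        assert tr.qualified


def test_trial_end_precedes_water_delivery(geom):
    traj, ev, _ = _scripted_session(geom)
    kin = compute_speed_accel(traj)
    regions = assign_regions(traj, geom)
    trials = extract_navigation_trials(regions, kin, ev, geom, traj)
    deliveries = ev[ev["kind"] == "water_delivery"]["frame"].to_numpy()
    for tr in trials:
        later = deliveries[deliveries >= tr.start_frame]
        assert tr.end_frame <= later.min()  # strictly before delivery frame


def test_arm3_heavy_traversal_flagged_unqualified(geom):
    traj, ev, expected = _scripted_session(geom, arm3_detour=True)
    kin = compute_speed_accel(traj)
    regions = assign_regions(traj, geom)
    trials = extract_navigation_trials(regions, kin, ev, geom, traj)
    assert len(trials) == len(expected)
    frac = np.mean(regions.region[trials[0].start_frame:trials[0].end_frame] == "arm3")
    assert frac > 0.2
    assert not trials[0].qualified
    assert all(tr.qualified for tr in trials[1:])


def test_no_alternation_gives_empty_trial_list(geom):
    traj, ev, _ = _scripted_session(geom)
    empty = ev.iloc[:0]
    kin = compute_speed_accel(traj)
    regions = assign_regions(traj, geom)
    assert extract_navigation_trials(regions, kin, empty, geom, traj) == []


def test_phase_and_direction_series_partition_trials(geom):
    traj, ev, _ = _scripted_session(geom)
    kin = compute_speed_accel(traj)
    regions = assign_regions(traj, geom)
    trials = extract_navigation_trials(regions, kin, ev, geom, traj)
    phases = phase_series(trials, len(traj))
    dirs = direction_series(trials, len(traj))
    for tr in trials:
        inside = slice(tr.start_frame, tr.end_frame)
        assert set(np.unique(dirs[inside])) == {tr.direction}
        assert set(np.unique(phases[inside])) <= {"starting", "central",
                                                  "terminal", "none"}
    assert np.all(phases[dirs == ""] == "none")


# --------------------------------------------------------------------------
# learning metrics
# --------------------------------------------------------------------------
def _regions_stub(labels):
    from navscope.kinematics import RegionSeries
    labels = np.asarray(labels, dtype="U10")
    return RegionSeries(region=labels, zone5=labels.copy())


def test_time_to_30_valid_licks():
    times = np.arange(10.0, 301.0, 10.0)  # 30 licks at t = 10..300
    ev = pd.DataFrame({
        "time": np.concatenate([times, times]),
        "kind": ["lick"] * 30 + ["water_delivery"] * 30,
        "spout_id": 1,
    })
    ts = np.arange(0, 320, 0.1)
    m = learning_metrics(ev, _regions_stub(["center"] * len(ts)), ts)
    assert m.time_to_30_valid_licks == pytest.approx(300.0)
    assert m.error_lick_rate == 0.0


def test_error_lick_rate_counts_dry_licks():
    ev = pd.DataFrame({
        "time": [1.0, 2.0, 3.0, 4.0],
        "kind": ["lick", "water_delivery", "lick", "lick"],
        "spout_id": 1,
    })
    ts = np.arange(0, 10, 0.1)
    m = learning_metrics(ev, _regions_stub(["center"] * len(ts)), ts)
    assert m.error_lick_rate == pytest.approx(2 / 3)


def test_reward_arm_entry_ratio():
    seq = (["center", "arm1"] * 10 + ["center", "arm2"] * 10
           + ["center", "arm3"] * 4)
    ev = pd.DataFrame({"time": [0.5], "kind": ["lick"], "spout_id": [1]})
    ts = np.arange(len(seq)) / 10.0
    m = learning_metrics(ev, _regions_stub(seq), ts)
    assert m.reward_arm_entry_ratio == pytest.approx(20 / 4)


def test_count_arm_entries_only_from_center():
    seq = ["arm1", "center", "arm1", "arm1", "center", "arm2", "arm2"]
    assert count_arm_entries(np.array(seq)) == {"arm1": 1, "arm2": 1, "arm3": 0}


# --------------------------------------------------------------------------
# open field
# --------------------------------------------------------------------------
def test_openfield_stationary_mouse():
    n = 2000  # 200 s at 10 Hz
    traj = make_trajectory(np.full(n, -15.0), np.full(n, -15.0),
                           arena_id="open_field")
    m = openfield_metrics(traj)
    assert m.accumulated_distance == pytest.approx(0.0)
    assert m.center_entries == 0
    assert m.mean_speed == pytest.approx(0.0)


def test_openfield_square_laps_distance():
    # 5 laps of a 30-cm-side square: accumulated distance = 5 * 120 cm
    side_pts = 50
    lap = np.concatenate([
        np.column_stack([np.linspace(-15, 15, side_pts), np.full(side_pts, -15.0)]),
        np.column_stack([np.full(side_pts, 15.0), np.linspace(-15, 15, side_pts)]),
        np.column_stack([np.linspace(15, -15, side_pts), np.full(side_pts, 15.0)]),
        np.column_stack([np.full(side_pts, -15.0), np.linspace(15, -15, side_pts)]),
    ])
    xy = np.concatenate([lap] * 6)  # first ~1 lap discarded with adaption
    traj = make_trajectory(xy[:, 0], xy[:, 1], arena_id="open_field")
    m = openfield_metrics(traj, adaption_s=len(lap) / 10.0, smoothing_window=0.2)
    assert m.accumulated_distance == pytest.approx(5 * 4 * 30.0, rel=0.02)


def test_openfield_no_center_entries_when_avoiding_center():
    t = np.arange(1000) / 10.0
    # circle of radius 17 cm: never inside the central 20x20 cm zone
    traj = make_trajectory(17 * np.cos(t), 17 * np.sin(t), arena_id="open_field")
    m = openfield_metrics(traj)
    assert m.center_entries == 0


def test_openfield_rejects_session_shorter_than_adaption():
    traj = make_trajectory(np.zeros(100), np.zeros(100), arena_id="open_field")
    with pytest.raises(ValueError, match="adaption"):
        openfield_metrics(traj)
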