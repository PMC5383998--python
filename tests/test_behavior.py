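"""Chemotaxis/locomotion analytics: bearings, turns, pirouettes, fields."""

import numpy as np
import pytest

from matrack.behavior import (
    BehaviorParams,
    Calibration,
    PirouetteEvent,
    RoiSet,
    attraction_field,
    bearing_series,
    chemotaxis_rate,
    delta_bearing_histogram,
    detect_pirouettes,
    detect_sharp_turns,
    directness_projection,
    pirouette_probability_vs_distance,
    roi_kinetics,
    speed_series,
)
from matrack.tracking import Track, TrackPoint

CAL = Calibration(px_per_mm=10.0, frames_per_second=1.0)
BEH = BehaviorParams()


def track_from(positions, start_frame=0, tid=0):
    return Track(
        id=tid,
        points=[
            TrackPoint(start_frame + i, (float(x), float(y)), "observed")
            for i, (x, y) in enumerate(positions)
        ],
    )


def corner_track(angle_deg, step=5.0):
    """Three points forming a corner of the given unsigned turning angle."""
    a = np.radians(angle_deg)
    p0 = (0.0, 0.0)
    p1 = (step, 0.0)
    p2 = (step + step * np.cos(a), step * np.sin(a))
    return track_from([p0, p1, p2])


class TestSpeed:
    def test_stationary_track_all_zero(self):
        assert np.all(speed_series(track_from([(5, 5)] * 10), CAL) == 0.0)

    def test_unit_arithmetic(self):
        t = track_from([(0, 0), (1, 0), (2, 0)])
        assert speed_series(t, CAL) == pytest.approx([0.1, 0.1])  # 1 px/f, 10 px/mm

    def test_single_point_track_empty(self):
        assert speed_series(track_from([(0, 0)]), CAL).size == 0

    def test_sinusoidal_walker_matches_analytic_speed(self):
        ts = np.arange(200, dtype=float)
        amp, period, vx = 30.0, 50.0, 3.0
        pts = np.c_[vx * ts, amp * np.sin(2 * np.pi * ts / period)]
        speeds = speed_series(track_from(pts), CAL)
        mid = (ts[:-1] + ts[1:]) / 2
        analytic = np.hypot(vx, amp * 2 * np.pi / period * np.cos(2 * np.pi * mid / period)) / CAL.px_per_mm
        assert np.all(np.abs(speeds - analytic) / analytic < 0.05)

    def test_subpixel_steps_count_as_zero_speed(self):
        t = track_from([(0, 0), (0.3, 0), (0.6, 0)])
        assert np.all(speed_series(t, CAL) == 0.0)


class TestBearing:
    def test_toward_away_orthogonal(self):
        target = (100.0, 0.0)
        toward = bearing_series(track_from([(0, 0), (1, 0)]), target)
        away = bearing_series(track_from([(0, 0), (-1, 0)]), target)
        assert toward[0] == pytest.approx(0.0)
        assert abs(away[0]) == pytest.approx(180.0)
        # v = (0, -1) (up-screen), target due east -> |B| = 90
        ortho = bearing_series(track_from([(0, 0), (0, -1)]), target)
        assert abs(ortho[0]) == pytest.approx(90.0)

    def test_zero_velocity_masked(self):
        b = bearing_series(track_from([(0, 0), (0, 0), (1, 0)]), (50.0, 0.0))
        assert np.isnan(b[0]) and np.isfinite(b[1])


class TestDirectness:
    def test_projection_equals_speed_toward_target(self):
        t = track_from([(0, 0), (2, 0), (4, 0)])
        proj = directness_projection(t, (100.0, 0.0), CAL)
        assert proj == pytest.approx(speed_series(t, CAL))

    def test_perpendicular_heading_projects_to_zero(self):
        proj = directness_projection(track_from([(0, 0), (0, 5)]), (100.0, 0.0), CAL)
        assert proj[0] == pytest.approx(0.0)

    def test_dot_product_arithmetic(self):
        # v = (1, 1), d = (1, 0) -> proj = 1 in px/frame units
        cal = Calibration(px_per_mm=1.0, frames_per_second=1.0)
        proj = directness_projection(track_from([(0, 0), (1, 1)]), (1.0, 0.0), cal)
        assert proj[0] == pytest.approx(1.0)

    def test_identity_speed_cos_bearing(self):
        rng = np.random.default_rng(8)
        pts = np.cumsum(rng.normal(0, 4, (200, 2)), axis=0)
        t = track_from(pts)
        target = (30.0, -20.0)
        speeds = speed_series(t, CAL)
        bearings = bearing_series(t, target)
        proj = directness_projection(t, target, CAL)
        ok = np.isfinite(bearings)
        assert ok.sum() > 100
        assert np.allclose(proj[ok], speeds[ok] * np.cos(np.radians(bearings[ok])), atol=1e-9)

    def test_first_visit_filter_masks_after_entry(self):
        pts = [(float(x), 0.0) for x in range(0, 100, 5)]
        t = track_from(pts)
        proj = directness_projection(t, (50.0, 0.0), CAL, stop_at_first_visit_radius_px=10.0)
        assert np.isfinite(proj[:8]).all() and np.isnan(proj[8:]).all()


class TestSharpTurns:
    def test_straight_line_has_none(self):
        t = track_from([(float(x), 0.0) for x in range(10)])
        assert detect_sharp_turns(t, BEH).size == 0

    @pytest.mark.parametrize("angle, flagged", [(90.0, False), (100.0, False), (101.0, True)])
    def test_threshold_is_strict(self, angle, flagged):
        turns = detect_sharp_turns(corner_track(angle), BEH)
        assert (turns.size == 1) == flagged

    def test_zero_length_step_not_flagged(self):
        t = track_from([(0, 0), (5, 0), (5, 0), (10, 0)])
        assert detect_sharp_turns(t, BEH).size == 0


def zigzag_track(turn_times_s, total_s=40, step=5.0):
    """Horizontal run with a ~170-deg about-face cornering at each requested
    second (the step leaving point index t reverses direction)."""
    pts = [(0.0, 0.0)]
    direction = 1.0
    turn_set = set(turn_times_s)
    for t in range(1, total_s + 1):
        if t - 1 in turn_set:
            direction = -direction
            dy = 0.9  # slight offset so reversals are ~170 deg, not exactly 180
        else:
            dy = 0.0
        x, y = pts[-1]
        pts.append((x + direction * step, y + dy))
    return track_from(pts)


class TestPirouettes:
    def test_close_turns_merge_into_one_event(self):
        t = zigzag_track([10, 13])
        events, runs = detect_pirouettes(t, BEH, CAL)
        assert len(events) == 1
        assert events[0].start_s == pytest.approx(10.0)
        assert events[0].end_s == pytest.approx(13.0)

    def test_distant_turns_form_two_events_with_run_between(self):
        t = zigzag_track([10, 20])
        events, runs = detect_pirouettes(t, BEH, CAL)
        assert len(events) == 2
        assert any(a == pytest.approx(10.0) and b == pytest.approx(20.0) for a, b in runs)

    def test_exact_t_crit_gap_separates(self):
        events, _ = detect_pirouettes(zigzag_track([10, 15]), BEH, CAL)
        assert len(events) == 2  # gap of exactly 5 s is a run, not a merge

    def test_no_turns_gives_single_run(self):
        t = track_from([(float(x), 0.0) for x in range(30)])
        events, runs = detect_pirouettes(t, BEH, CAL)
        assert events == []
        assert runs == [(0.0, 29.0)]

    def test_partition_covers_track_duration(self):
        t = zigzag_track([7, 9, 18, 30], total_s=50)
        events, runs = detect_pirouettes(t, BEH, CAL)
        total = sum(e.end_s - e.start_s for e in events) + sum(b - a for a, b in runs)
        duration = t.duration_s(CAL.frames_per_second)
        assert total == pytest.approx(duration, abs=1.0)

    def test_bearing_windows_before_and_after(self):
        target = (1000.0, 0.0)
        t = zigzag_track([10])
        (ev,), _ = detect_pirouettes(t, BEH, CAL, target=target)
        assert ev.B_before == pytest.approx(0.0, abs=1e-6)  # heading east at target
        assert abs(ev.B_after) > 160.0  # heading back west

    def test_event_without_full_window_has_nan_bearings(self):
        t = zigzag_track([2])  # only 2 steps before the turn
        (ev,), _ = detect_pirouettes(t, BEH, CAL, target=(1000.0, 0.0))
        assert np.isnan(ev.B_before)


class TestPirouetteRateVsDistance:
    def test_track_never_entering_bin_is_masked(self):
        t = track_from([(0.0, 0.0), (1.0, 0.0), (2.0, 0.0)])
        rate = pirouette_probability_vs_distance(
            [t], [[]], (1000.0, 0.0), np.array([0.0, 10.0, 2000.0]), CAL
        )
        assert np.isnan(rate[0]) and rate[1] == 0.0

    def test_all_events_in_one_bin(self):
        t = zigzag_track([10, 20, 30], total_s=40)
        events, _ = detect_pirouettes(t, BEH, CAL)
        far_target = (1e6, 0.0)
        rate = pirouette_probability_vs_distance(
            [t], [events], far_target, np.array([0.0, 1e5, 2e6]), CAL
        )
        assert np.isnan(rate[0])
        assert rate[1] == pytest.approx(3 / 41)

    def test_simulator_rate_recovered_in_single_bin(self):
        """Constant configured reorientation rate, one distance bin: the
        estimated event rate falls within 3 binomial SD of the configured
        per-second probability."""
        from matrack.simulate import ExitAngleModel, SimConfig, simulate_worm

        rate_cfg = 0.005  # low rate: bout merging is negligible
        flips = np.concatenate([np.random.default_rng(0).normal(180, 10, 500),
                                np.random.default_rng(1).normal(-180, 10, 500)])
        model = ExitAngleModel.from_tables("empirical_conditional", flips, flips)
        cfg = SimConfig(
            target_xy=(1e7, 0.0), speed_mm_s=0.15, p_pir_directed=rate_cfg,
            p_pir_undirected=rate_cfg, max_time_s=1500.0, arrival_radius_mm=1.0,
        )
        tracks, events = [], []
        rng_master = np.random.SeedSequence(77)
        for i, child in enumerate(rng_master.spawn(15)):
            _, _, traj = simulate_worm(cfg, model, np.random.default_rng(child), record_trajectory=True)
            t = track_from(traj * CAL.px_per_mm, tid=i)
            ev, _ = detect_pirouettes(t, BEH, CAL)
            tracks.append(t)
            events.append(ev)
        edges = np.array([0.0, 1e9])
        est = pirouette_probability_vs_distance(tracks, events, (1e7 * CAL.px_per_mm, 0.0), edges, CAL)[0]
        total_s = sum(len(t.points) for t in tracks)
        sd = np.sqrt(rate_cfg * (1 - rate_cfg) / total_s)
        assert abs(est - rate_cfg) <= 3 * sd


class TestRoiKinetics:
    ROIS = RoiSet({"start": (10.0, 10.0, 8.0), "cue": (90.0, 90.0, 8.0)})

    def test_counts_and_cumulative_arrivals(self):
        # two tracks start inside 'start'; one crosses into 'cue' at frame 5
        t1 = track_from([(10, 10)] * 3 + [(50, 50), (70, 70), (90, 90), (90, 90)], tid=0)
        t2 = track_from([(12, 10)] * 7, tid=1)
        counts, cum = roi_kinetics([t1, t2], self.ROIS, n_frames=7)
        assert counts.loc[0, "start"] == 2
        assert counts.loc[6, "start"] == 1
        assert list(cum["cue"]) == [0, 0, 0, 0, 0, 1, 1]
        assert (cum.diff().fillna(0) >= 0).all().all()  # non-decreasing

    def test_overlapping_rois_warn(self):
        rois = RoiSet({"a": (0.0, 0.0, 10.0), "b": (5.0, 0.0, 10.0)})
        with pytest.warns(UserWarning, match="overlap"):
            roi_kinetics([track_from([(0, 0)])], rois, n_frames=1)


class TestChemotaxisRate:
    def test_exact_linear_series(self):
        t = np.arange(0, 600.0, 60.0)
        y = 0.5 / 60.0 * t  # slope 0.5 per minute
        slope, se = chemotaxis_rate(y, t)
        assert slope * 60 == pytest.approx(0.5)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_constant_series_has_zero_slope(self):
        slope, se = chemotaxis_rate(np.full(10, 7.0), np.arange(10.0))
        assert slope == 0.0

    def test_noisy_series_recovered_within_2_se(self):
        rng = np.random.default_rng(2)
        t = np.arange(300.0)
        y = 0.02 * t + rng.normal(0, 0.5, t.size)
        slope, se = chemotaxis_rate(y, t)
        assert abs(slope - 0.02) <= 2 * se


class TestAttractionField:
    def test_straight_east_track_fills_bins_with_unit_x(self):
        t = track_from([(float(x), 50.0) for x in range(5, 100, 5)])
        af = attraction_field([t], (100.0, 100.0), nx=10, ny=10)
        filled = af.occupancy > 0
        assert af.occupancy.sum() == len(t.points)
        row = af.direction[filled & (np.abs(af.direction).sum(axis=2, keepdims=False) > 0)]
        assert np.allclose(row, [1.0, 0.0], atol=1e-12)

    def test_opposite_passes_cancel(self):
        east = track_from([(float(x), 50.0) for x in range(5, 100, 5)], tid=0)
        west = track_from([(float(x), 50.0) for x in range(95, 0, -5)], tid=1)
        af = attraction_field([east, west], (100.0, 100.0), nx=10, ny=10)
        assert af.occupancy.sum() == len(east.points) + len(west.points)
        # interior bins see one step of each direction: mean direction cancels
        assert np.allclose(af.direction[5, 1:9], 0.0, atol=1e-12)

    def test_norms_bounded_by_one(self):
        rng = np.random.default_rng(1)
        tracks = [track_from(np.cumsum(rng.normal(0, 3, (50, 2)), axis=0) + 100, tid=i) for i in range(5)]
        af = attraction_field(tracks, (300.0, 300.0))
        assert np.hypot(af.direction[..., 0], af.direction[..., 1]).max() <= 1 + 1e-12

    def test_radial_inflow_points_at_target(self):
        target = np.array([175.0, 125.0])
        tracks = []
        for k, ang in enumerate(np.linspace(0, 2 * np.pi, 12, endpoint=False)):
            start = target + 110 * np.array([np.cos(ang), np.sin(ang)])
            pts = np.linspace(start, target, 40)
            tracks.append(track_from(pts, tid=k))
        af = attraction_field(tracks, (350.0, 250.0), nx=35, ny=25)
        bw = 350.0 / 35
        xc = (af.x_edges[:-1] + af.x_edges[1:]) / 2
        yc = (af.y_edges[:-1] + af.y_edges[1:]) / 2
        for iy in range(25):
            for ix in range(35):
                d = target - np.array([xc[ix], yc[iy]])
                dist = np.hypot(*d)
                v = af.direction[iy, ix]
                if dist > 2 * bw and np.hypot(*v) > 0.1:
                    cosang = np.dot(v, d) / (np.hypot(*v) * dist)
                    assert cosang >= np.cos(np.radians(15.0))


class TestDeltaBearingHistogram:
    def test_all_zero_delta_mass_at_plus_one(self):
        events = [PirouetteEvent(0, 1, 10.0, 10.0) for _ in range(20)]
        out = delta_bearing_histogram(events, bins=4)
        assert out["on_course"][-1] == 20 and out["on_course"][:3].sum() == 0

    def test_full_reversal_mass_at_minus_one(self):
        events = [PirouetteEvent(0, 1, 120.0, -60.0) for _ in range(10)]
        out = delta_bearing_histogram(events, bins=4)
        assert out["off_course"][0] == 10

    def test_undefined_bearings_skipped_and_counted(self):
        events = [PirouetteEvent(0, 1, np.nan, 0.0), PirouetteEvent(0, 1, 0.0, 0.0)]
        out = delta_bearing_histogram(events)
        assert out["n_skipped"] == 1

    def test_mixture_weights_recovered(self):
        rng = np.random.default_rng(6)
        events = []
        w_keep = 0.7
        n = 2000
        for _ in range(n):
            b_before = rng.uniform(-80, 80)
            db = rng.normal(0, 5) if rng.random() < w_keep else 180 + rng.normal(0, 5)
            events.append(PirouetteEvent(0, 1, b_before, b_before - db))
        out = delta_bearing_histogram(events, bins=np.array([-1.0, 0.0, 1.0]))
        frac_keep = out["on_course"][1] / n
        sd = np.sqrt(w_keep * (1 - w_keep) / n)
        assert abs(frac_keep - w_keep) <= 3 * sd
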