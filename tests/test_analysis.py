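import numpy as np
import pytest

from echospace.analysis import (
    DirectionSeries,
    TurnRateSeries,
    echo_direction_series,
    edge_distance_summary,
    lagged_correlation,
    pulse_direction_series,
    pulses_affected,
    turn_rate_series,
)
from echospace.localize import EchoIncidencePoint
from echospace.scene import FlightTrack, PulseEvent, build_corridor_scene


def straight_track(speed=4.0, duration=2.0, fps=125.0):
    t = np.arange(0, duration, 1 / fps)
    return FlightTrack(times=t, positions=np.column_stack([speed * t, 0 * t + 0.75]))


def circle_track(radius=1.0, speed=4.0, duration=1.5, fps=125.0):
    t = np.arange(0, duration, 1 / fps)
    ang = speed / radius * t
    return FlightTrack(
        times=t, positions=np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])
    )


def make_pulse(pid, t, x, y, angle):
    return PulseEvent(
        id=pid, t_emit=t, position=np.array([x, y]),
        direction=np.array([np.cos(angle), np.sin(angle)]),
    )


class TestTurnRate:
    def test_straight_flight_zero(self):
        tr = turn_rate_series(straight_track())
        assert np.allclose(tr.values, 0.0, atol=1e-6)
        assert np.allclose(np.diff(tr.times), 1e-3)

    def test_circular_arc_closed_form(self):
        # constant-rate turn: omega = v / R
        tr = turn_rate_series(circle_track(radius=1.0, speed=4.0))
        interior = tr.values[50:-50]
        assert np.allclose(interior, 4.0, rtol=0.01)

    def test_stationary_track_rejected(self):
        t = np.arange(0, 1, 1 / 125.0)
        track = FlightTrack(times=t, positions=np.column_stack([0 * t + 1e-12 * t, 0 * t]))
        with pytest.raises(ValueError):
            turn_rate_series(track)


class TestDirectionSeries:
    def test_point_dead_ahead_is_zero(self):
        track = straight_track()
        pulses = [make_pulse(0, 0.5, 2.0, 0.75, 0.0)]
        pts = [EchoIncidencePoint(0, 0.5, 3.0, 0.75, 1.0)]
        ds = echo_direction_series(pts, pulses, track)
        assert ds.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_left_bearing_positive(self):
        track = straight_track()
        pulses = [make_pulse(0, 0.5, 2.0, 0.75, 0.0)]
        d = 1.0
        pts = [
            EchoIncidencePoint(
                0, 0.5, 2.0 + d * np.cos(np.pi / 6), 0.75 + d * np.sin(np.pi / 6), 1.0
            )
        ]
        ds = echo_direction_series(pts, pulses, track)
        assert ds.values[0] == pytest.approx(np.pi / 6)

    def test_strongest_point_selected(self):
        track = straight_track()
        pulses = [make_pulse(0, 0.5, 2.0, 0.75, 0.0)]
        pts = [
            EchoIncidencePoint(0, 0.5, 3.0, 0.75, 0.5),   # ahead, stronger
            EchoIncidencePoint(0, 0.5, 2.0, 1.75, 0.3),   # left, weaker
        ]
        ds = echo_direction_series(pts, pulses, track)
        assert ds.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_pulse_without_points_is_a_gap(self):
        track = straight_track()
        pulses = [make_pulse(0, 0.4, 1.6, 0.75, 0.0), make_pulse(1, 0.8, 3.2, 0.75, 0.0)]
        pts = [EchoIncidencePoint(1, 0.8, 4.0, 0.75, 1.0)]
        ds = echo_direction_series(pts, pulses, track)
        assert len(ds.times) == 1
        assert ds.times[0] == pytest.approx(0.8)

    def test_pulse_direction_relative_to_flight(self):
        track = straight_track()
        pulses = [make_pulse(0, 0.5, 2.0, 0.75, np.pi / 4)]
        ds = pulse_direction_series(pulses, track)
        assert ds.values[0] == pytest.approx(np.pi / 4, abs=1e-6)


class TestLaggedCorrelation:
    @staticmethod
    def smooth_series(rng, duration=6.0, dt=1e-3):
        t = np.arange(0.0, duration, dt)
        x = rng.normal(size=len(t))
        k = np.hanning(201)
        return t, np.convolve(x, k / k.sum(), mode="same")

    @pytest.mark.parametrize("tau_star", [-0.1, 0.0, 0.25, 0.6])
    def test_tau_max_recovery_exact_on_grid(self, tau_star, rng):
        t, x = self.smooth_series(rng)
        turn = TurnRateSeries(times=t, values=x)
        pulse_times = np.arange(1.0, 4.0, 0.05)
        direction = DirectionSeries(pulse_times, turn.at(pulse_times + tau_star))
        lc = lagged_correlation(direction, turn)
        assert lc.tau_max == pytest.approx(tau_star, abs=1e-12)
        k = int(np.argmin(np.abs(lc.lags - tau_star)))
        assert lc.r[k] == pytest.approx(1.0, abs=1e-9)

    def test_ci_half_width_arithmetic(self):
        # n = 403 paired samples: half-width on the z scale = 1.96/sqrt(400)
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 30.0, 1e-3)
        turn = TurnRateSeries(times=t, values=rng.normal(size=len(t)))
        times = np.linspace(1.0, 25.0, 403)
        direction = DirectionSeries(times, rng.normal(size=403))
        lc = lagged_correlation(direction, turn, lag_min=0.0, lag_max=0.0, step=0.01)
        assert lc.n[0] == 403
        z_half = np.arctanh(lc.ci_hi[0]) - np.arctanh(lc.r[0])
        assert z_half == pytest.approx(1.959964 / np.sqrt(400), rel=1e-4)

    def test_invariance_to_affine_rescaling(self, rng):
        t, x = self.smooth_series(rng)
        turn = TurnRateSeries(times=t, values=x)
        times = np.arange(1.0, 4.0, 0.06)
        vals = turn.at(times + 0.13) + 0.1 * rng.normal(size=len(times))
        d1 = DirectionSeries(times, vals)
        d2 = DirectionSeries(times, 3.7 * vals - 1.2)
        r1 = lagged_correlation(d1, turn).r
        r2 = lagged_correlation(d2, turn).r
        assert np.allclose(r1, r2, atol=1e-12, equal_nan=True)

    def test_invariance_to_common_time_shift(self, rng):
        t, x = self.smooth_series(rng)
        shift = 0.5
        turn1 = TurnRateSeries(times=t, values=x)
        turn2 = TurnRateSeries(times=t + shift, values=x)
        times = np.arange(1.0, 4.0, 0.06)
        vals = turn1.at(times + 0.2)
        lc1 = lagged_correlation(DirectionSeries(times, vals), turn1)
        lc2 = lagged_correlation(DirectionSeries(times + shift, vals), turn2)
        assert np.allclose(lc1.r, lc2.r, atol=1e-10, equal_nan=True)

    def test_sparse_lags_reported_missing(self):
        t = np.arange(0.0, 0.2, 1e-3)
        turn = TurnRateSeries(times=t, values=np.sin(t * 20))
        direction = DirectionSeries(np.array([0.05, 0.1]), np.array([0.1, -0.2]))
        lc = lagged_correlation(direction, turn)
        assert np.isnan(lc.r[-1])  # lag 0.6 s has no overlap


class TestEdgeDistanceSummary:
    def test_hand_computed_mean_and_se(self):
        scene = build_corridor_scene(4.5, 1.5, 1.0, 1.0, 1)
        plate = scene.plates[0]
        inner = plate.inner_edge
        along = (plate.attached_end - inner) / plate.length
        pts = []
        for i, d in enumerate((0.0, 0.1, 0.2)):
            p = inner + d * along + np.array([plate.thickness / 2, 0.0])
            pts.append(EchoIncidencePoint(i, 0.1 * i, p[0], p[1], 1.0, obstacle_id=0))
        table, summary = edge_distance_summary(pts, scene)
        assert len(table) == 3
        assert summary["mean_m"].iloc[0] == pytest.approx(0.1)
        assert summary["se_m"].iloc[0] == pytest.approx(0.05773502, rel=1e-5)

    def test_inner_half_filter_matches_bruteforce(self, rng):
        from echospace.scene import edge_distance

        scene = build_corridor_scene(4.5, 1.5, 1.0, 1.0, 3)
        pts = []
        for i in range(120):
            plate = scene.plates[rng.integers(0, 3)]
            s = rng.uniform(-0.1, 1.1)
            p = plate.inner_edge + s * (plate.attached_end - plate.inner_edge)
            pts.append(
                EchoIncidencePoint(i, 0.0, p[0], p[1], 1.0, obstacle_id=plate.id)
            )
        table, _ = edge_distance_summary(pts, scene)
        expected = sum(
            1
            for p in pts
            if edge_distance((p.x, p.y), scene.plate_by_id(p.obstacle_id))
            <= scene.plate_by_id(p.obstacle_id).length / 2
        )
        assert len(table) == expected

    def test_boundary_inclusive_and_outer_excluded(self):
        scene = build_corridor_scene(4.5, 1.5, 1.0, 1.0, 1)
        plate = scene.plates[0]
        inner = plate.inner_edge
        along = (plate.attached_end - inner) / plate.length
        at_half = inner + 0.5 * along
        outer = inner + 0.6 * along
        pts = [
            EchoIncidencePoint(0, 0.0, at_half[0], at_half[1], 1.0, obstacle_id=0),
            EchoIncidencePoint(1, 0.0, outer[0], outer[1], 1.0, obstacle_id=0),
        ]
        table, _ = edge_distance_summary(pts, scene)
        assert list(table["pulse_id"]) == [0]


class TestPulsesAffected:
    def test_simple_ratio(self):
        assert pulses_affected(0.1, [0.05] * 10) == pytest.approx(2.0)
        assert pulses_affected(0.0, [0.03, 0.07]) == 0.0

    def test_against_pulse_train_counting(self, rng):
        # brute force: count emissions inside (t, t + lag) along a long
        # simulated train, averaged over uniformly random onset times
        # (counting from emissions instead would under-count: the first
        # interval after an emission is a full IPI by construction)
        ipis = rng.uniform(0.04, 0.08, size=4000)
        times = np.cumsum(ipis)
        lag = 0.191
        onsets = rng.uniform(times[0], times[-1] - lag, size=2000)
        counts = [np.sum((times > t0) & (times <= t0 + lag)) for t0 in onsets]
        assert pulses_affected(lag, ipis) == pytest.approx(np.mean(counts), rel=0.02)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pulses_affected(0.1, [])
        with pytest.raises(ValueError):
            pulses_affected(0.1, [0.05, -0.01])
        with pytest.raises(ValueError):
            pulses_affected(-0.1, [0.05])
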