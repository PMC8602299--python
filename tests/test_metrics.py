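"""Kinematic metrics: EPD, holds, AROM, sweep area, speed, smoothness."""

import numpy as np
import pytest

from wristkin import metrics as met
from wristkin.chain import WristTrajectory
from wristkin.errors import (
    InsufficientDataError,
    TargetLookupError,
    UndefinedMetricError,
)

RATE = 100.0


def wt(p, rate=RATE):
    p = np.asarray(p, dtype=float)
    return WristTrajectory(t=np.arange(len(p)) / rate, p=p)


class TestEpd:
    def test_pythagorean(self):
        assert met.epd(np.array([[3.0, 4.0, 0.0]]))[0] == pytest.approx(5.0)

    def test_zero(self):
        assert met.epd(np.array([[0.0, 0.0, 0.0]]))[0] == 0.0

    def test_full_extension_constant(self, limb):
        from wristkin import synthetic as syn

        gt = syn.simulate_static(limb, duration=2.0)
        assert np.allclose(met.epd(gt.p_true), 55.0, atol=1e-9)


def ramp_profile(levels_durations, rate=RATE, ramp=1.0):
    """EPD series visiting the given (level, duration) plateaus with smooth ramps."""
    segs = []
    prev = levels_durations[0][0]
    for level, dur in levels_durations:
        if level != prev:
            s = np.linspace(0, 1, int(ramp * rate))
            segs.append(prev + (level - prev) * (3 * s**2 - 2 * s**3))
        segs.append(np.full(int(dur * rate), float(level)))
        prev = level
    return np.concatenate(segs)


class TestSegmentHolds:
    def test_single_plateau_detected(self):
        series = ramp_profile([(20.0, 4.0), (50.0, 3.0), (20.0, 3.0)])
        t = np.arange(len(series)) / RATE
        seg = met.segment_holds(t, series, speed_threshold=2.0, min_hold=1.0)
        assert len(seg.holds) == 1
        (iv, label) = seg.holds[0]
        assert label == "T1"
        mask = (t >= iv[0]) & (t <= iv[1])
        assert np.mean(series[mask]) == pytest.approx(50.0, abs=0.5)
        assert seg.rest_interval[0] == pytest.approx(0.0)

    def test_constant_series_single_hold_after_rest(self):
        n = int(10 * RATE)
        t = np.arange(n) / RATE
        series = np.full(n, 30.0)
        seg = met.segment_holds(t, series, rest_duration=2.0)
        assert len(seg.holds) == 1
        iv, _ = seg.holds[0]
        assert iv[0] > 2.0 and iv[1] == pytest.approx(t[-1])

    def test_short_plateau_excluded(self):
        series = ramp_profile([(20.0, 3.0), (50.0, 0.4), (20.0, 3.0)])
        t = np.arange(len(series)) / RATE
        seg = met.segment_holds(t, series, speed_threshold=2.0, min_hold=1.0)
        assert len(seg.holds) == 0 or all(
            abs(np.mean(series[(t >= iv[0]) & (t <= iv[1])]) - 50.0) > 5 for iv, _ in seg.holds
        )

    def test_no_holds_warns_not_raises(self):
        t = np.arange(500) / RATE
        series = 30.0 + 10.0 * np.sin(2 * np.pi * 1.0 * t)  # never stationary
        with pytest.warns(UserWarning):
            seg = met.segment_holds(t, series, speed_threshold=1.0, min_hold=1.0)
        assert seg.holds == []


class TestReachMetrics:
    def test_arom_is_difference(self):
        series = ramp_profile([(20.0, 4.0), (52.3, 3.0), (20.0, 3.0)])
        t = np.arange(len(series)) / RATE
        seg = met.segmentation_from_annotations(
            [("rest", 0.5, 3.5), ("T1", 5.5, 7.5)]
        )
        (m,) = met.reach_metrics(t, series, seg)
        assert m.epd_at_target == pytest.approx(52.3)
        assert m.rest_epd == pytest.approx(20.0)
        assert m.arom == pytest.approx(32.3)

    def test_zero_arom_when_hold_equals_rest(self):
        t = np.arange(800) / RATE
        series = np.full(800, 20.0)
        seg = met.segmentation_from_annotations([("rest", 0.0, 3.0), ("T1", 4.0, 7.0)])
        (m,) = met.reach_metrics(t, series, seg)
        assert m.arom == 0.0

    def test_matches_brute_force_interval_means(self, rng):
        """Multi-target session vs direct interval averaging, exact."""
        t = np.arange(3000) / RATE
        series = 30.0 + np.cumsum(rng.normal(size=3000)) * 0.01
        rows = [("rest", 0.0, 3.0)]
        intervals = [((4.0 + 6 * k, 7.0 + 6 * k), f"T{k + 1}") for k in range(4)]
        rows += [("rest", iv[1] + 0.5, iv[1] + 2.5) for iv, _ in intervals[:-1]]
        rows += [(lab, iv[0], iv[1]) for iv, lab in intervals]
        seg = met.segmentation_from_annotations(rows)
        out = met.reach_metrics(t, series, seg)
        assert len(out) == 4
        for m, (iv, lab) in zip(out, intervals):
            mask = (t >= iv[0]) & (t <= iv[1])
            assert m.epd_at_target == pytest.approx(series[mask].mean(), abs=1e-12)

    def test_session_rest_reference(self):
        series = ramp_profile([(20.0, 4.0), (50.0, 3.0), (25.0, 3.0), (50.0, 3.0), (20.0, 2.0)])
        t = np.arange(len(series)) / RATE
        rows = [("rest", 0.5, 3.5), ("T1", 5.5, 7.5), ("rest", 9.5, 11.0), ("T2", 13.0, 15.0)]
        seg = met.segmentation_from_annotations(rows)
        per_reach = met.reach_metrics(t, series, seg)
        session = met.reach_metrics(t, series, seg, rest_reference="session")
        assert per_reach[1].rest_epd == pytest.approx(25.0, abs=0.5)
        assert session[1].rest_epd == pytest.approx(20.0, abs=0.5)


class TestDeltas:
    def make(self, vals):
        return [
            met.ReachMetrics(target=t, epd_at_target=e, rest_epd=r)
            for t, e, r in vals
        ]

    def test_simple_difference(self):
        ms = self.make([("T1", 52.0, 20.0), ("T2", 47.5, 20.0)])
        out = met.delta_between_targets(ms, [("T1", "T2")])
        assert out[("T1", "T2")]["depd"] == pytest.approx(4.5)

    def test_identical_targets_zero(self):
        ms = self.make([("T1", 50.0, 20.0), ("T2", 50.0, 20.0)])
        assert met.delta_between_targets(ms, [("T1", "T2")])[("T1", "T2")]["depd"] == 0.0

    def test_three_target_pairwise_hand_computation(self):
        ms = self.make(
            [("T1", 50.0, 20.0), ("T1", 52.0, 22.0), ("T2", 45.0, 20.0), ("T3", 40.0, 21.0)]
        )
        out = met.delta_between_targets(ms, [("T1", "T2"), ("T1", "T3"), ("T2", "T3")])
        assert out[("T1", "T2")]["depd"] == pytest.approx(51.0 - 45.0)
        assert out[("T1", "T3")]["depd"] == pytest.approx(51.0 - 40.0)
        assert out[("T2", "T3")]["darom"] == pytest.approx(25.0 - 19.0)

    def test_missing_target_rejected(self):
        ms = self.make([("T1", 50.0, 20.0)])
        with pytest.raises(TargetLookupError):
            met.delta_between_targets(ms, [("T1", "T9")])


class TestSweepArea:
    def test_semicircle_analytic(self):
        ang = np.deg2rad(np.arange(0.0, 180.5, 1.0))
        p = np.column_stack([55 * np.cos(ang), 55 * np.sin(ang), np.full(len(ang), -5.0)])
        area = met.sweep_area(wt(p))
        assert area == pytest.approx(np.pi * 55**2 / 2, rel=1e-3)

    def test_unit_square(self):
        p = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0.0]])
        assert met.sweep_area(wt(p)) == pytest.approx(1.0)

    def test_collinear_zero(self):
        p = np.column_stack([np.linspace(0, 1, 10), np.linspace(0, 2, 10), np.zeros(10)])
        assert met.sweep_area(wt(p)) == pytest.approx(0.0, abs=1e-12)

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            met.sweep_area(wt(np.zeros((2, 3))))

    def test_invariance_to_yaw_and_vertical_shift(self, rng):
        p = rng.normal(size=(50, 3)) * 10
        base = met.sweep_area(wt(p))
        for _ in range(5):
            ang = rng.uniform(0, 2 * np.pi)
            Rz = np.array(
                [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
            )
            moved = p @ Rz.T + np.array([0.0, 0.0, rng.normal() * 20])
            assert met.sweep_area(wt(moved)) == pytest.approx(base, rel=1e-9)


class TestEndpointSpeed:
    def test_linear_motion_exact_in_interior(self):
        t = np.arange(0, 3, 0.01)
        p = np.column_stack([10 * t, np.zeros_like(t), np.zeros_like(t)])
        v = met.endpoint_speed(WristTrajectory(t=t, p=p), window=7)
        assert np.allclose(v[5:-5], 10.0, atol=1e-9)

    def test_stationary_zero(self):
        p = np.tile([1.0, 2.0, 3.0], (100, 1))
        v = met.endpoint_speed(wt(p))
        assert np.allclose(v, 0.0, atol=1e-12)

    def test_circle_analytic(self):
        t = np.arange(0, 6.28, 0.01)
        p = np.column_stack([20 * np.cos(t), 20 * np.sin(t), np.zeros_like(t)])
        v = met.endpoint_speed(WristTrajectory(t=t, p=p), window=7)
        interior = v[10:-10]
        assert np.max(np.abs(interior - 20.0)) / 20.0 < 1e-3

    def test_convergence_under_refinement(self):
        """Error on a quintic shrinks with the sample interval (method order)."""
        errs = []
        for rate in (50.0, 100.0, 200.0):
            t = np.arange(0, 2, 1 / rate)
            x = t**5 - 2 * t**3 + t
            dx = 5 * t**4 - 6 * t**2 + 1
            p = np.column_stack([x, np.zeros_like(t), np.zeros_like(t)])
            v = met.endpoint_speed(WristTrajectory(t=t, p=p), window=7)
            k = len(t) // 4
            errs.append(np.max(np.abs(v[k:-k] - np.abs(dx)[k:-k])))
        assert errs[1] < errs[0] / 2 and errs[2] < errs[1] / 2

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            met.endpoint_speed(wt(np.zeros((5, 3))), window=7)


class TestPeakEnvelope:
    def test_constant_series_unchanged(self):
        s = np.full(100, 3.0)
        assert np.array_equal(met.peak_envelope(s), s)

    def test_amplitude_modulation_recovered(self):
        t = np.arange(0, 4, 0.005)
        A = 2.0 + np.sin(2 * np.pi * 0.25 * t)
        s = A * np.abs(np.sin(2 * np.pi * 8 * t))
        env = met.peak_envelope(s, t)
        core = slice(len(t) // 8, -len(t) // 8)
        rel = np.abs(env[core] - A[core]) / A[core]
        assert np.percentile(rel, 95) < 0.05

    def test_single_bell_returned_unchanged(self):
        t = np.linspace(0, 1, 200)
        s = np.exp(-((t - 0.5) ** 2) / 0.02)
        assert np.array_equal(met.peak_envelope(s, t), s)


class TestSmoothness:
    def test_constant_envelope_is_exactly_one(self):
        assert met.smoothness(np.full(500, 2.5)) == 1.0

    def test_minimum_jerk_ratio(self):
        """Single min-jerk stroke: peak/mean = 1.875 (numerical oracle)."""
        tau = np.linspace(0, 1, 5001)
        v = 30 * tau**2 - 60 * tau**3 + 30 * tau**4
        oracle = v.max() / np.trapezoid(v, tau)  # peak over integral-mean
        assert oracle == pytest.approx(1.875, abs=1e-6)
        assert met.smoothness(v) == pytest.approx(1.875, abs=0.01)

    def test_pause_between_bells_increases_value(self):
        tau = np.linspace(0, 1, 1001)
        bell = 30 * tau**2 - 60 * tau**3 + 30 * tau**4
        single = met.smoothness(bell)
        double = met.smoothness(np.concatenate([bell, np.zeros(500), bell]))
        assert double > single

    def test_nonnegative_envelope_bound(self, rng):
        e = np.abs(rng.normal(size=300)) + 0.1
        assert met.smoothness(e) >= 1.0

    def test_zero_mean_rejected(self):
        with pytest.raises(UndefinedMetricError):
            met.smoothness(np.zeros(100))
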