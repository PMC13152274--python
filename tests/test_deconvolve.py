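import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import photosurge as ps
from photosurge.deconvolve import DetectionCriteria, detect_oscillations
from photosurge.io import ChannelSeries

from conftest import bump_train, make_trace
from oracles import peaks_bruteforce


class TestMovingAverage:
    def test_constant_trace(self):
        trace = make_trace(np.full(3600, 5.0))
        dec = ps.moving_average(trace, 30.0)
        np.testing.assert_allclose(dec.slow, 5.0)
        np.testing.assert_allclose(dec.fast, 0.0)

    def test_impulse_plateau(self):
        x = np.zeros(2001)
        x[1000] = 1.0
        dec = ps.moving_average(make_trace(x), 30.0)
        w = 2 * (int(round(30 * 60 / 4.0)) // 2) + 1
        # away from edges the window never shrinks: plateau of height 1/w
        assert dec.slow[1000] == pytest.approx(1.0 / w)
        assert dec.slow[1000 - w // 2] == pytest.approx(1.0 / w)
        assert dec.slow[1000 + w // 2 + 1] == 0.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_reconstruction_identity(self, seed):
        x = np.random.default_rng(seed).normal(size=700)
        dec = ps.moving_average(make_trace(x), 30.0)
        np.testing.assert_allclose(dec.slow + dec.fast, x, rtol=0, atol=1e-12)

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError, match="window"):
            ps.moving_average(make_trace(np.zeros(100)), 0.1)


class TestBuildCriteria:
    def test_height_from_quiet_window(self, rng):
        x = rng.normal(0, 1, 19800)
        trace = make_trace(x)  # starts 11:00, quiet window = first 2 hr
        crit = ps.build_criteria(trace, reference_trace=trace)
        dec = ps.moving_average(trace)
        q = dec.slow[:1800]
        assert crit.min_height == pytest.approx(q.mean() + 2 * q.std())
        assert crit.trough_tolerance == pytest.approx(2 * q.std())

    def test_prominence_from_reference_max(self):
        ref = make_trace(np.full(19800, 20.0))
        trace = make_trace(np.zeros(19800))
        crit = ps.build_criteria(trace, reference_trace=ref)
        assert crit.min_prominence == pytest.approx(0.15 * 20.0)

    def test_fallback_to_own_max(self, caplog):
        trace = make_trace(np.full(19800, 10.0))
        crit = ps.build_criteria(trace, reference_trace=None)
        assert crit.min_prominence == pytest.approx(1.5)

    def test_quiet_window_outside_recording_rejected(self):
        trace = make_trace(np.zeros(100), clock_start="14:00")
        with pytest.raises(ValueError, match="quiet"):
            ps.build_criteria(trace, quiet_window=("11:00", "13:00"))


class TestDetectOscillations:
    def test_flat_trace_gives_empty_list(self):
        crit = DetectionCriteria(min_height=2.0, min_prominence=1.0)
        assert detect_oscillations(ChannelSeries(np.arange(100) * 4.0, np.zeros(100)), crit) == []

    def test_three_bumps_recovered_with_durations(self):
        events = [(3600 + i * (5400 + 1800), 5400.0, 7.0) for i in range(3)]
        t, y = bump_train(30000.0, events)
        crit = DetectionCriteria(min_height=2.0, min_prominence=1.05)
        osc = detect_oscillations(ChannelSeries(t, y), crit)
        assert len(osc) == 3
        for o, (onset, dur, amp) in zip(osc, events):
            assert o.duration_min == pytest.approx(90.0, rel=0.10)
            assert o.onset_trough_time == pytest.approx(onset, abs=30.0)
            assert o.amplitude == pytest.approx(amp, rel=0.05)

    def test_distance_rule_keeps_taller(self):
        # two bumps 20 min apart; the taller second one must win
        t, y = bump_train(12000.0, [(2000, 2400.0, 5.0), (2000 + 1200, 2400.0, 6.0)])
        crit = DetectionCriteria(min_height=1.0, min_prominence=0.5, min_distance_min=30.0)
        osc = detect_oscillations(ChannelSeries(t, y), crit)
        assert len(osc) == 1
        assert osc[0].peak_value == pytest.approx(y.max())

    def test_no_two_peaks_closer_than_min_distance(self, rng):
        for _ in range(20):
            y = rng.normal(0, 1, 800)
            crit = DetectionCriteria(min_height=0.5, min_prominence=0.2, min_distance_min=2.0)
            osc = detect_oscillations(ChannelSeries(np.arange(800) * 4.0, y), crit)
            times = np.array([o.peak_time for o in osc])
            if len(times) > 1:
                assert np.diff(times).min() >= 2.0 * 60.0

    def test_matches_bruteforce_criteria_scan(self, rng):
        """Exhaustive local-maximum scan with the three criteria applied
        literally must select the same peak set."""
        for _ in range(10):
            n_b = rng.integers(2, 5)
            events = []
            cursor = 2000.0
            for _ in range(n_b):
                dur = rng.uniform(3000, 7000)
                events.append((cursor, dur, rng.uniform(4, 9)))
                cursor += dur + rng.uniform(0, 4000)
            t, y = bump_train(cursor + 4000, events, noise_sd=0.15, rng=rng)
            crit = DetectionCriteria(min_height=1.0, min_prominence=0.9, min_distance_min=30.0)
            osc = detect_oscillations(ChannelSeries(t, y), crit)
            dist = int(round(30.0 * 60 / 4.0))
            expected = peaks_bruteforce(y, 1.0, 0.9, dist)
            assert [o.peak_time for o in osc] == [t[i] for i in expected]

    def test_constant_shift_with_rebuilt_height_criterion(self, rng):
        """Height/tolerance are quiet-window-relative so a constant shift
        rebuilt from the shifted trace finds the same peaks; prominence is
        reference-max-relative and therefore *not* shift-invariant, which
        is the documented behaviour."""
        events = [(3600, 5400.0, 7.0), (12600, 5400.0, 6.0)]
        t, y = bump_train(25000.0, events, noise_sd=0.1, rng=rng)
        trace = make_trace(y)
        shifted = make_trace(y + 5.0)
        for prom_frac in (0.0,):
            c1 = ps.build_criteria(trace, trace, prominence_frac=prom_frac)
            c2 = ps.build_criteria(shifted, shifted, prominence_frac=prom_frac)
            o1 = detect_oscillations(ps.moving_average(trace), c1)
            o2 = detect_oscillations(ps.moving_average(shifted), c2)
            assert [o.peak_time for o in o1] == [o.peak_time for o in o2]
        # prominence threshold scales with the shifted maximum, as documented
        c2 = ps.build_criteria(shifted, shifted, prominence_frac=0.15)
        c1 = ps.build_criteria(trace, trace, prominence_frac=0.15)
        assert c2.min_prominence > c1.min_prominence


class TestSurgeBounds:
    def _osc(self, onset_hr, offset_hr):
        peak = (onset_hr + offset_hr) / 2 * 3600
        return ps.Oscillation(peak, 5.0, onset_hr * 3600, offset_hr * 3600,
                              (offset_hr - onset_hr) * 60, 5.0, 5.0)

    def test_total_duration(self):
        surge = ps.surge_bounds([self._osc(2, 4), self._osc(4, 6), self._osc(13, 15)])
        assert surge.total_duration_hr == pytest.approx(13.0)
        assert surge.count == 3

    def test_single_oscillation(self):
        surge = ps.surge_bounds([self._osc(3, 4.5)])
        assert surge.total_duration_hr == pytest.approx(1.5)

    def test_empty_flagged_undefined(self):
        surge = ps.surge_bounds([])
        assert surge.count == 0 and not surge.defined
        assert np.isnan(surge.onset_s)


class TestAuc:
    def test_constant(self):
        t = np.linspace(0, 10, 11)
        assert ps.compute_auc(ps.CalciumTrace(t, np.ones(11))) == pytest.approx(10.0)

    def test_ramp(self):
        t = np.linspace(0, 10, 101)
        assert ps.compute_auc(ps.CalciumTrace(t, t)) == pytest.approx(50.0)

    def test_matches_manual_trapezoids(self, rng):
        t = np.sort(rng.uniform(0, 100, 1000))
        t += np.arange(1000) * 1e-6  # ensure strictly increasing
        y = rng.normal(size=1000)
        manual = sum(
            (y[i] + y[i + 1]) / 2 * (t[i + 1] - t[i]) for i in range(999)
        )
        assert ps.compute_auc(ps.CalciumTrace(t, y)) == pytest.approx(manual)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ps.compute_auc(ps.CalciumTrace(np.array([0.0]), np.array([1.0])))


class TestMeanProfile:
    def test_identical_traces(self):
        t = np.arange(100.0)
        v = np.sin(t / 10)
        grid, mean, sem = ps.mean_profile([(t, v), (t, v)], grid=t)
        np.testing.assert_allclose(mean, v, atol=1e-12)
        np.testing.assert_allclose(sem, 0.0, atol=1e-12)

    def test_two_point_sem(self):
        t = np.arange(10.0)
        grid, mean, sem = ps.mean_profile([(t, np.ones(10)), (t, -np.ones(10))], grid=t)
        np.testing.assert_allclose(mean, 0.0, atol=1e-12)
        np.testing.assert_allclose(sem, 1.0)

    def test_recovers_known_mean_function(self, rng):
        t = np.arange(0, 500.0)
        truth = np.sin(t / 40)
        traces = [(t, truth + rng.normal(0, 0.3, len(t))) for _ in range(10)]
        grid, mean, sem = ps.mean_profile(traces, grid=t)
        ok = np.abs(mean - truth) <= 3 * np.maximum(sem, 1e-12)
        assert ok.mean() >= 0.99

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ps.mean_profile([])
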