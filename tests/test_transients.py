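import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import photosurge as ps
from photosurge.transients import (
    DEFAULT_K_GRID,
    significance_mask,
    zscore_median,
)

from oracles import runs_bruteforce, significance_mask_bruteforce


def _ztrace(values, dt=4.0):
    values = np.asarray(values, float)
    return zscore_median(np.arange(len(values)) * dt, values)


class TestZscoreMedian:
    def test_small_example(self):
        z = _ztrace([-1.0, 0.0, 1.0])
        assert np.median(z.z) == pytest.approx(0.0)
        assert np.std(z.z) == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.01, 100), st.floats(-50, 50))
    def test_affine_invariance(self, a, b):
        x = np.random.default_rng(0).normal(2, 3, 500)
        z1 = _ztrace(x)
        z2 = _ztrace(a * x + b)
        np.testing.assert_allclose(z1.z, z2.z, atol=1e-9)

    def test_skewed_input_median_centred(self, rng):
        x = rng.normal(0, 1, 1000)
        x[:100] += 20.0  # heavy positive excursions: mean shifts, median not
        z = _ztrace(np.sort(x)[::-1].copy())
        assert np.median(z.z) == pytest.approx(0.0, abs=1e-12)
        assert abs(np.mean(z.z)) > 0.1

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            _ztrace(np.full(10, 3.0))


class TestThresholdSegments:
    def test_simple_run(self):
        z = _ztrace_raw([0.0, 2.0, 2.0, 0.0])
        segs = ps.threshold_segments(z, 1.0, "+")
        assert len(segs) == 1
        assert (segs[0].start_index, segs[0].end_index, segs[0].size) == (1, 3, 2)

    def test_all_zero(self):
        z = _ztrace_raw(np.zeros(50))
        assert ps.threshold_segments(z, 1.0, "+") == []
        assert ps.threshold_segments(z, 1.0, "-") == []

    def test_matches_runlength_oracle(self, rng):
        z = _ztrace_raw(rng.normal(0, 1, 400))
        for k in (0.5, 1.0, 2.0):
            got = [(s.start_index, s.end_index) for s in ps.threshold_segments(z, k, "+")]
            assert got == runs_bruteforce(z.z > k)
            gotn = [(s.start_index, s.end_index) for s in ps.threshold_segments(z, k, "-")]
            assert gotn == runs_bruteforce(z.z < -k)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            ps.threshold_segments(_ztrace_raw(np.zeros(5)), -1.0, "+")


def _ztrace_raw(values, dt=4.0):
    """ZTrace wrapping raw values without re-normalisation."""
    values = np.asarray(values, float)
    return ps.ZTrace(np.arange(len(values)) * dt, values)


class TestDetectSignificant:
    def test_sixteen_thresholds_iterated(self):
        np.testing.assert_allclose(DEFAULT_K_GRID, np.arange(1.0, 4.01, 0.2))
        assert len(DEFAULT_K_GRID) == 16

    def test_single_large_excursion_recovered(self, rng):
        # symmetric noise whose runs beyond any k are short, one clear event
        z = rng.normal(0, 0.5, 500)
        z[200:212] = 6.0
        mask, transients = ps.detect_significant(_ztrace_raw(z))
        assert len(transients) == 1
        assert mask[200:212].all()
        assert transients[0].duration_s == pytest.approx(12 * 4.0, rel=0.35)

    def test_sign_symmetric_trace_has_no_transients(self, rng):
        half = rng.normal(0, 1, 250)
        z = np.concatenate([half, -half])  # n_neg == n_pos at every (k, s)
        mask, transients = ps.detect_significant(_ztrace_raw(z))
        assert not mask.any()
        assert transients == []

    def test_amplitude_measured_on_residual(self):
        z = np.zeros(100)
        z[50:54] = 5.0
        resid = np.zeros(100)
        resid[50:54] = [1.0, 7.5, 3.0, 1.0]
        _, transients = ps.detect_significant(_ztrace_raw(z), residual=resid)
        assert transients and transients[0].amplitude == pytest.approx(7.5)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            z = rng.normal(0, 1, 300)
            for _ in range(rng.integers(0, 4)):
                i = rng.integers(20, 280)
                z[i : i + rng.integers(2, 8)] += rng.uniform(2, 6)
            zt = _ztrace_raw(z)
            for strict in (False, True):
                mask = significance_mask(
                    zt.z, size_comparison="gt" if strict else "gte"
                )
                expected = significance_mask_bruteforce(
                    z, DEFAULT_K_GRID, strict=strict
                )
                np.testing.assert_array_equal(mask, expected)

    def test_inclusive_vs_strict_differ_on_lone_run(self, rng):
        """A single positive run with no negative counterpart: inclusive
        counting accepts it at its own size (n_pos=1, n_neg=0); strict
        counting leaves n_pos=0 so nothing is ever significant."""
        z = np.zeros(100)
        z[40:50] = 5.0
        inc = significance_mask(z, size_comparison="gte")
        strict = significance_mask(z, size_comparison="gt")
        assert inc[40:50].all()
        assert not strict.any()

    def test_affine_invariant_mask(self, rng):
        x = rng.normal(0, 1, 600)
        x[100:110] += 5.0
        m1, _ = ps.detect_significant(zscore_median(np.arange(600.0), x))
        m2, _ = ps.detect_significant(zscore_median(np.arange(600.0), 2.0 * x + 7.0))
        np.testing.assert_array_equal(m1, m2)

    def test_monotonicity_in_size(self, rng):
        """At fixed k, samples accepted at size s' >= s are a subset of
        those accepted at s."""
        z = rng.normal(0, 1, 500)
        z[50:70] += 4.0
        z[200:204] += 4.0
        pos = runs_bruteforce(z > 2.0)
        sizes = sorted({e - s for s, e in pos})
        prev = None
        for s in sizes[::-1]:  # descending sizes
            cur = np.zeros(len(z), bool)
            for a, b in pos:
                if b - a >= s:
                    cur[a:b] = True
            if prev is not None:
                assert not (prev & ~cur).any()
            prev = cur


class TestTransientStats:
    def test_frequency_scale(self):
        ts = [
            ps.Transient(i * 80.0, i * 80.0 + 12.0, 12.0, 3.0) for i in range(950)
        ]
        stats = ps.transient_stats(ts, 79200.0)
        assert stats.frequency_hz == pytest.approx(0.0120, abs=0.0001)

    def test_empty(self):
        stats = ps.transient_stats([], 1000.0)
        assert stats.frequency_hz == 0.0
        assert np.isnan(stats.mean_duration_s)

    def test_mean_duration(self):
        ts = [ps.Transient(0, 10, 10.0, 1.0), ps.Transient(20, 40, 20.0, 2.0)]
        stats = ps.transient_stats(ts, 100.0)
        assert stats.mean_duration_s == pytest.approx(15.0)
        assert stats.mean_amplitude == pytest.approx(1.5)

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            ps.transient_stats([], 0.0)
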