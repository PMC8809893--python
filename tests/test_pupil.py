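"""Pupil preprocessing and dilation-event detection."""
import numpy as np
import pytest

import lcpupil as lp
from lcpupil.pupil import (
    compute_slopes,
    detect_dilation_events,
    percent_change,
    smooth_trace,
    zscore_trace,
)


def make_trace(values, rate=50.0, units="mm"):
    return lp.PupilTrace(values=np.asarray(values, dtype=float), rate=rate, units=units)


class TestZscore:
    def test_three_point_example(self):
        z = zscore_trace(make_trace([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(z.values, [-1.0, 0.0, 1.0])
        assert z.units == "z"

    def test_output_standardized(self, rng):
        z = zscore_trace(make_trace(rng.normal(3, 2, 500)))
        assert z.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.values.std(ddof=1) == pytest.approx(1.0)

    def test_constant_raises(self):
        with pytest.raises(ValueError):
            zscore_trace(make_trace([2.0, 2.0, 2.0]))


class TestSmooth:
    def test_constant_unchanged(self):
        tr = make_trace(np.full(200, 3.0))
        np.testing.assert_allclose(smooth_trace(tr, 0.5).values, 3.0)

    def test_impulse_plateau(self):
        x = np.zeros(201)
        x[100] = 1.0
        sm = smooth_trace(make_trace(x, rate=50.0), window=0.5)  # 25 samples
        plateau = sm.values[100 - 12 : 100 + 13]
        np.testing.assert_allclose(plateau, 1 / 25)
        assert sm.values[100 - 13] == 0.0

    def test_single_sample_window_identity(self):
        x = np.sin(np.arange(100) / 7.0)
        sm = smooth_trace(make_trace(x, rate=50.0), window=0.02)
        np.testing.assert_array_equal(sm.values, x)

    def test_subsample_window_warns_identity(self, caplog):
        x = np.arange(50.0)
        with caplog.at_level("WARNING", logger="lcpupil"):
            sm = smooth_trace(make_trace(x, rate=50.0), window=0.001)
        np.testing.assert_array_equal(sm.values, x)
        assert any("window" in r.message for r in caplog.records)


class TestSlopes:
    def test_ramp_constant_slope(self):
        a = 0.7
        t = np.arange(0, 20, 0.02)
        s = compute_slopes(make_trace(a * t, rate=50.0), step=0.2)
        np.testing.assert_allclose(s.slopes, a, rtol=1e-10)

    def test_constant_zero_slope(self):
        s = compute_slopes(make_trace(np.full(1000, 5.0), rate=50.0), step=0.2)
        np.testing.assert_allclose(s.slopes, 0.0)

    def test_sinusoid_matches_analytic_derivative(self):
        period = 20.0
        t = np.arange(0, 100, 0.02)
        tr = make_trace(np.sin(2 * np.pi * t / period), rate=50.0)
        s = compute_slopes(tr, step=0.2)
        analytic = (2 * np.pi / period) * np.cos(2 * np.pi * s.times / period)
        big = np.abs(analytic) > 0.1
        np.testing.assert_allclose(s.slopes[big], analytic[big], rtol=0.02)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            compute_slopes(make_trace([1.0, 2.0], rate=50.0), step=0.2)


def brute_force_events(trace, slopes):
    """Oracle: local maxima of the trace between slope sign changes."""
    s = slopes.slopes
    crossings = [k for k in range(1, s.size) if s[k - 1] <= 0 and s[k] > 0]
    out = []
    times = slopes.times
    for a, b in zip(crossings[:-1], crossings[1:]):
        ia, ib = trace.index_at(times[a]), trace.index_at(times[b])
        if ib <= ia:
            continue
        seg = trace.values[ia : ib + 1]
        k = int(np.argmax(seg))
        out.append((ia + k, seg[k]))
    return out


class TestDilationEvents:
    def test_monotone_decreasing_no_events(self):
        tr = make_trace(np.linspace(3, 1, 500), units="z")
        s = compute_slopes(tr, 0.2)
        assert detect_dilation_events(tr, s) == []

    def test_sine_one_event_per_period(self):
        period, amp = 10.0, 1.5
        t = np.arange(0, 100, 0.02)
        tr = make_trace(amp * np.sin(2 * np.pi * t / period), units="z")
        s = compute_slopes(tr, 0.2)
        events = detect_dilation_events(tr, s)
        # 10 periods -> between-crossing spans cover 9 peaks
        assert len(events) == 9
        for e in events:
            assert e.amplitude == pytest.approx(amp, rel=0.01)
            assert e.rise_start < e.time

    def test_two_gaussian_bumps(self):
        t = np.arange(0, 60, 0.02)
        x = 2.0 * np.exp(-((t - 15) ** 2) / 4) + 1.0 * np.exp(-((t - 40) ** 2) / 4)
        tr = make_trace(x + 1e-4 * np.sin(t), units="z")  # break flat stretches
        s = compute_slopes(tr, 0.2)
        events = detect_dilation_events(tr, s)
        apex = sorted(events, key=lambda e: -e.amplitude)[:2]
        assert sorted(round(e.time) for e in apex) == [15, 40]

    def test_matches_brute_force_oracle(self, uncoupled_session):
        _, _, trace, _ = uncoupled_session
        z, slopes = lp.preprocess(trace)
        events = detect_dilation_events(z, slopes)
        oracle = brute_force_events(z, slopes)
        assert len(events) == len(oracle)
        for e, (idx, val) in zip(events, oracle):
            assert z.index_at(e.time) == idx
            assert e.amplitude == pytest.approx(val)

    def test_event_count_nonincreasing_in_smoothing(self, rng):
        # average over noise traces: smoothing suppresses false positives
        totals = np.zeros(4)
        for _ in range(5):
            x = rng.normal(0, 1, 10000)
            tr = make_trace(x, rate=50.0, units="z")
            for j, w in enumerate((0.02, 0.1, 0.3, 0.5)):
                sm = smooth_trace(tr, w)
                s = compute_slopes(sm, 0.2)
                totals[j] += len(detect_dilation_events(sm, s))
        assert list(totals) == sorted(totals, reverse=True)

    def test_large_events_infrequent_on_null_data(self, uncoupled_session):
        _, _, trace, _ = uncoupled_session
        z, slopes = lp.preprocess(trace)
        events = detect_dilation_events(z, slopes)
        amps = np.array([e.amplitude for e in events])
        assert (amps > 2.0).mean() < 0.10

    def test_event_amplitude_is_trace_value_and_ordered(self, coupled_session):
        _, _, trace, _ = coupled_session
        z, slopes = lp.preprocess(trace)
        events = detect_dilation_events(z, slopes)
        assert len(events) > 10
        times = [e.time for e in events]
        assert times == sorted(times)
        for e in events:
            assert e.amplitude == z.value_at(e.time)
            assert e.rise_start <= e.time


class TestPercentChange:
    def test_simple_ratio(self):
        tr = make_trace(np.r_[np.full(100, 2.0), np.full(100, 2.2)], rate=50.0)
        series, b = percent_change(tr, t_ref=2.0, baseline_window=1.0)
        assert b == pytest.approx(2.0)
        assert series[-1] == pytest.approx(10.0)

    def test_constant_zero_percent(self):
        tr = make_trace(np.full(200, 1.5))
        series, _ = percent_change(tr, 2.0, 1.0)
        np.testing.assert_allclose(series, 0.0)

    def test_flat_then_ramp(self):
        # flat 1.0 for 2 s, then ramp to 4.0 at t=3 s
        t = np.arange(0, 3.02, 0.02)
        x = np.where(t < 2.0, 1.0, 1.0 + 3.0 * (t - 2.0))
        tr = make_trace(x, rate=50.0)
        series, b = percent_change(tr, t_ref=2.0, baseline_window=1.0)
        assert b == pytest.approx(1.0)
        assert series[tr.index_at(3.0)] == pytest.approx(300.0, rel=0.01)

    def test_zero_baseline_raises(self):
        tr = make_trace(np.r_[np.zeros(100), np.ones(100)])
        with pytest.raises(ValueError):
            percent_change(tr, 2.0, 1.0)
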