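"""Forward and reverse coupling quantification."""
import numpy as np
import pytest
from scipy import stats

import lcpupil as lp
from lcpupil.coupling import (
    bin_events,
    coupling_curve,
    derivative_response,
    event_spike_counts,
    exclude_licking,
    fit_linear,
    fit_linear_responses,
    spikes_before_event,
    triggered_peak,
)


def ztrace(values, rate=20.0):
    return lp.PupilTrace(values=np.asarray(values, dtype=float), rate=rate, units="z")


class TestTriggeredPeak:
    def test_lookup_peak_and_latency(self):
        x = np.zeros(400)
        x[262] = 1.7  # 13.1 s at 20 Hz
        r = triggered_peak(ztrace(x), onset=10.0, window=6.0)
        assert r.peak == pytest.approx(1.7)
        assert r.latency == pytest.approx(3.1)

    def test_window_past_end_excluded(self):
        r = triggered_peak(ztrace(np.zeros(100)), onset=3.0, window=6.0)  # ends 4.95 s
        assert r.excluded

    def test_kernel_latency_in_measured_range(self):
        cfg = lp.SimConfig(duration=100.0, noise_sd=0.0, drift_sd=0.0)
        train = lp.SpikeTrain("u", [40.0], t_start=0, t_end=100.0)
        trace = lp.generate_pupil(train, cfg)
        r = triggered_peak(trace, onset=40.0, window=6.0)
        assert 2.5 <= r.latency <= 4.0

    def test_absolute_mode_picks_magnitude(self):
        x = np.zeros(400)
        x[210], x[220] = -2.0, 1.0
        signed = triggered_peak(ztrace(x), 10.0, 6.0, peak_mode="signed")
        absolute = triggered_peak(ztrace(x), 10.0, 6.0, peak_mode="absolute")
        assert signed.peak == 1.0
        assert absolute.peak == -2.0


class TestCouplingCurve:
    def test_single_size_flagged_unfittable(self):
        rs = [lp.TriggeredResponse(0, 1, 0.5, 3.0) for _ in range(4)]
        curve = coupling_curve(rs)
        assert curve.sizes.tolist() == [1]
        with pytest.raises(ValueError):
            fit_linear(curve)

    def test_occurrence_sums_to_one(self, rng):
        rs = [
            lp.TriggeredResponse(0, int(s), float(p), 3.0)
            for s, p in zip(rng.integers(1, 6, 50), rng.normal(0, 1, 50))
        ]
        curve = coupling_curve(rs)
        assert curve.occurrence.sum() == pytest.approx(1.0)

    def test_synthetic_linear_coupling_recovered(self, coupled_session):
        cfg, train, trace, _ = coupled_session
        fw = lp.forward_analysis(train, trace)
        assert fw.slope > 0
        # affine-in-size in expectation: positive rank correlation of means
        well_sampled = fw.curve.n >= 10
        rho = stats.spearmanr(
            fw.curve.sizes[well_sampled], fw.curve.mean_peak[well_sampled]
        ).statistic
        assert rho > 0.5


class TestFitLinear:
    def test_exact_line(self):
        curve = lp.CouplingCurve(
            sizes=np.array([1, 2, 3, 4]),
            mean_peak=0.25 * np.array([1, 2, 3, 4.0]),
            sem=np.zeros(4),
            occurrence=np.full(4, 0.25),
            n=np.full(4, 10),
        )
        slope, r2 = fit_linear(curve)
        assert slope == pytest.approx(0.25)
        assert r2 == pytest.approx(1.0)

    def test_flat_points_zero_slope(self):
        curve = lp.CouplingCurve(
            sizes=np.array([1, 2, 3]),
            mean_peak=np.full(3, 0.4),
            sem=np.zeros(3),
            occurrence=np.full(3, 1 / 3),
            n=np.full(3, 10),
        )
        slope, r2 = fit_linear(curve)
        assert slope == pytest.approx(0.0)
        assert r2 == pytest.approx(0.0)

    def test_closed_form_three_points(self):
        # OLS by hand: slope = Sxy/Sxx = 0.4/2; r2 = Sxy^2/(Sxx*Syy) = 12/13
        curve = lp.CouplingCurve(
            sizes=np.array([1, 2, 3]),
            mean_peak=np.array([0.3, 0.4, 0.7]),
            sem=np.zeros(3),
            occurrence=np.full(3, 1 / 3),
            n=np.full(3, 10),
        )
        slope, r2 = fit_linear(curve)
        assert slope == pytest.approx(0.2)
        assert r2 == pytest.approx(12 / 13)

    def test_responses_fit_needs_three_sizes(self):
        rs = [lp.TriggeredResponse(0, s, 0.1 * s, 3.0) for s in (1, 1, 2, 2)]
        with pytest.raises(ValueError):
            fit_linear_responses(rs)


class TestSpikesBeforeEvent:
    @pytest.mark.parametrize(
        "offsets,expected",
        [
            ([-3.0], 1),  # inside the window
            ([-1.0], 0),  # after the window
            ([-4.0, -2.0], 1),  # -4 inclusive, -2 exclusive
            ([-4.001, -3.999, -2.001], 2),
        ],
    )
    def test_boundary_rules(self, offsets, expected):
        ev = lp.DilationEvent(time=100.0, amplitude=1.0, rise_start=99.0)
        train = lp.SpikeTrain("u", sorted(100.0 + o for o in offsets), t_start=0, t_end=200)
        assert spikes_before_event(train, ev).count == expected

    def test_window_before_start_excluded(self):
        ev = lp.DilationEvent(time=3.0, amplitude=1.0, rise_start=2.0)
        train = lp.SpikeTrain("u", [1.0, 2.0], t_start=0, t_end=10)
        assert spikes_before_event(train, ev).excluded

    def test_alternative_window_similar_relation(self, coupled_session):
        # -1..-3 s window yields the same qualitative monotone relation
        _, train, trace, _ = coupled_session
        z, slopes = lp.preprocess(trace)
        events = lp.detect_dilation_events(z, slopes)
        for window in [(-4.0, -2.0), (-3.0, -1.0)]:
            counts = event_spike_counts(train, events, window)
            tab, _ = bin_events(counts)
            ok = tab.dropna(subset=["mean_count"])
            ok = ok[ok.n_events >= 10]
            rho = stats.spearmanr(ok["bin"], ok["mean_count"]).statistic
            assert rho > 0.6


class TestBinEvents:
    def test_bin_index_examples(self):
        ev = lambda amp: lp.DilationEvent(10.0, amp, 9.0)
        c1 = lp.EventSpikeCount(ev(0.31), 2, 1)
        assert c1.bin_index == 1
        tab, n_out = bin_events(
            [
                lp.EventSpikeCount(ev(0.31), 2, 1),
                lp.EventSpikeCount(ev(3.2), 5, None),
            ]
        )
        assert n_out == 1
        assert tab.loc[tab.bin == 1, "n_events"].iloc[0] == 1
        assert len(tab) == 10

    def test_coupled_data_monotone_mean_counts(self, coupled_session):
        _, train, trace, _ = coupled_session
        rv = lp.reverse_analysis(train, trace)
        ok = rv.bins.dropna(subset=["mean_count"])
        ok = ok[ok.n_events >= 10]
        rho = stats.spearmanr(ok["bin"], ok["mean_count"]).statistic
        assert rho > 0.6


class TestExcludeLicking:
    def test_no_licks_identity(self):
        clusters = [lp.SpikeCluster([1.0]), lp.SpikeCluster([5.0])]
        assert exclude_licking(clusters, np.array([])) == clusters

    def test_boundary_closed_interval(self):
        clusters = [lp.SpikeCluster([10.5]), lp.SpikeCluster([10.51])]
        kept = exclude_licking(clusters, np.array([10.0]), halfwidth=0.5)
        assert [c.onset for c in kept] == [10.51]

    def test_dense_licks_exclude_all(self):
        clusters = [lp.SpikeCluster([float(t)]) for t in range(1, 20)]
        licks = np.arange(0.0, 20.0, 0.9)
        assert exclude_licking(clusters, licks, halfwidth=0.5) == []


class TestDerivativeResponse:
    def test_ramp_constant_derivative(self):
        a = 0.4
        t = np.arange(0, 30, 0.05)
        slopes = lp.compute_slopes(ztrace(a * t), step=0.2)
        assert derivative_response(slopes, 5.0, 6.0) == pytest.approx(a, rel=1e-6)

    def test_flat_zero(self):
        slopes = lp.compute_slopes(ztrace(np.full(600, 2.0)), step=0.2)
        assert derivative_response(slopes, 5.0, 6.0) == 0.0

    def test_derivative_peak_precedes_value_peak(self):
        cfg = lp.SimConfig(duration=100.0, noise_sd=0.0, drift_sd=0.0)
        train = lp.SpikeTrain("u", [40.0], t_start=0, t_end=100.0)
        trace = lp.generate_pupil(train, cfg)
        slopes = lp.compute_slopes(trace, step=0.2)
        t = slopes.times
        mask = (t >= 40.0) & (t <= 46.0)
        t_dpeak = t[mask][np.argmax(slopes.slopes[mask])]
        r = triggered_peak(trace, 40.0, 6.0)
        assert t_dpeak - 40.0 < r.latency


def test_forward_reverse_same_sign(coupled_session):
    """Both directions of analysis give a positive monotone coupling."""
    _, train, trace, _ = coupled_session
    fw = lp.forward_analysis(train, trace)
    rv = lp.reverse_analysis(train, trace)
    assert fw.slope > 0
    ok = rv.bins.dropna(subset=["mean_count"])
    ok = ok[ok.n_events >= 10]
    assert stats.spearmanr(ok["bin"], ok["mean_count"]).statistic > 0
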