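import math

import numpy as np
import pytest

from ng2circuit.core import PulseProtocol, Trace
from ng2circuit.ephys_features import (
    FeatureError,
    SpikeFeatureSet,
    accommodation,
    ahp_metrics,
    ap_slopes,
    classify_interneuron,
    detect_spikes,
    firing_frequencies,
    input_resistance,
    spike_amplitude,
    spike_duration,
    spike_threshold,
)
from ng2circuit.synthetic.ephys import (
    FWHM_FACTOR,
    HYPER_PROTOCOL,
    gen_rc_trace,
)

DT = 0.05
PROTO = PulseProtocol(holding_mv=-70, step_pa=200, onset_ms=50, duration_ms=500)


def make_trace(samples, dt=DT, t0=0.0, kind="voltage"):
    return Trace(dt=dt, samples=np.asarray(samples, dtype=float), kind=kind, t0=t0)


def gaussian_spike_trace(peaks_ms, sigma_ms=0.5, amp=80.0, base=-70.0,
                         total_ms=600.0, dt=DT):
    t = np.arange(0.0, total_ms, dt)
    v = np.full(t.size, base)
    for pk in peaks_ms:
        v += amp * np.exp(-0.5 * ((t - pk) / sigma_ms) ** 2)
    return make_trace(v, dt=dt)


class TestDetectSpikes:
    def test_flat_trace_empty(self):
        tr = make_trace(np.full(20000, -70.0))
        assert detect_spikes(tr, PROTO).size == 0

    def test_five_spikes_at_generator_times(self):
        peaks = [100.0, 150.0, 200.0, 250.0, 300.0]
        tr = gaussian_spike_trace(peaks)
        got = detect_spikes(tr, PROTO)
        assert got.size == 5
        assert np.allclose(got, peaks, atol=DT)

    def test_two_spikes_within_1ms_stay_separate(self):
        tr = gaussian_spike_trace([100.0, 100.8], sigma_ms=0.15)
        assert detect_spikes(tr, PROTO).size == 2

    def test_current_trace_rejected(self):
        tr = make_trace(np.zeros(10000), kind="current")
        with pytest.raises(FeatureError):
            detect_spikes(tr, PROTO)

    def test_empty_trace_rejected(self):
        with pytest.raises(FeatureError):
            detect_spikes(make_trace([]), PROTO)


class TestFiringFrequencies:
    def test_count_over_duration(self):
        proto = PulseProtocol(-70, 200, 0, 1000)
        st = np.linspace(50, 950, 10)
        assert firing_frequencies(st, proto).f_total == pytest.approx(10.0)

    def test_regular_train(self):
        proto = PulseProtocol(-70, 200, 0, 1000)
        st = np.arange(25, 1000, 50.0)  # 50-ms ISIs
        r = firing_frequencies(st, proto)
        assert r.f_init == pytest.approx(20.0)
        assert r.f_200 == pytest.approx(20.0)
        assert r.f_final == pytest.approx(20.0)

    def test_first_isi_25ms(self):
        proto = PulseProtocol(-70, 200, 0, 1000)
        st = np.array([10.0, 35.0, 85.0, 135.0, 250.0, 400.0])
        assert firing_frequencies(st, proto).f_init == pytest.approx(40.0)

    def test_single_spike_flagged(self):
        r = firing_frequencies(np.array([100.0]), PROTO)
        assert r.f_init is None
        assert "insufficient_spikes" in r.flags

    def test_time_shift_invariance(self):
        proto0 = PulseProtocol(-70, 200, 0, 1000)
        proto1 = PulseProtocol(-70, 200, 300, 1000)
        st = np.array([20.0, 60.0, 120.0, 260.0, 500.0, 800.0])
        r0 = firing_frequencies(st, proto0)
        r1 = firing_frequencies(st + 300.0, proto1)
        assert r0.f_total == r1.f_total
        assert r0.f_init == pytest.approx(r1.f_init)
        assert r0.f_200 == pytest.approx(r1.f_200)
        assert r0.f_final == pytest.approx(r1.f_final)


class TestAccommodation:
    @pytest.mark.parametrize("fi,f200,ff,early,late", [
        (40, 30, 30, 25.0, 0.0),
        (30, 30, 30, 0.0, 0.0),
        (50, 40, 30, 20.0, 20.0),
    ])
    def test_formula(self, fi, f200, ff, early, late):
        e, l = accommodation(fi, f200, ff)
        assert e == pytest.approx(early)
        assert l == pytest.approx(late)

    def test_zero_f_init_raises(self):
        with pytest.raises(FeatureError):
            accommodation(0.0, 10.0, 10.0)


class TestThresholdAndAmplitude:
    def test_threshold_near_base_for_sharp_gaussian(self):
        # for a Gaussian spike on a quiet baseline the derivative-doubling
        # point sits just above the resting level
        tr = gaussian_spike_trace([100.0], sigma_ms=0.6, amp=70.0, base=-36.0)
        thr = spike_threshold(tr, 100.0)
        assert -36.0 < thr < -34.0

    def test_no_spike_raises(self):
        t = np.arange(0, 200, DT)
        tr = make_trace(-70 + 0.01 * t)  # pure slow ramp
        with pytest.raises((FeatureError, IndexError)):
            spike_threshold(tr, 100.0)

    def test_amplitude_peak_minus_threshold(self):
        tr = gaussian_spike_trace([100.0], amp=70.0, base=-36.0)
        i = tr.index_at(100.0)
        assert spike_amplitude(tr, 100.0, -36.0) == pytest.approx(
            tr.samples[i] + 36.0)

    def test_amplitude_reduction_formula(self):
        a1, a2 = 70.0, 64.7
        assert 100 * (a1 - a2) / a1 == pytest.approx(7.571, abs=1e-3)


class TestSpikeDuration:
    def test_exact_gaussian_fwhm(self):
        sigma = 0.5
        tr = gaussian_spike_trace([100.0], sigma_ms=sigma, amp=80.0, base=-70.0)
        fwhm = spike_duration(tr, 100.0, threshold=-69.0)
        expected = FWHM_FACTOR * sigma  # 2*sqrt(2 ln 2)*sigma ~ 1.177
        assert fwhm == pytest.approx(expected, rel=1e-3)
        assert expected == pytest.approx(1.1774, abs=1e-3)

    def test_fwhm_scales_with_sigma(self):
        f1 = spike_duration(gaussian_spike_trace([100.0], sigma_ms=0.4), 100.0, -69.0)
        f2 = spike_duration(gaussian_spike_trace([100.0], sigma_ms=0.8), 100.0, -69.0)
        assert f2 / f1 == pytest.approx(2.0, rel=1e-3)

    def test_paper_duration_increase_consistency(self):
        d1, d2 = 1.37, 1.46
        assert 100 * (d2 - d1) / d1 == pytest.approx(6.57, abs=0.01)


class TestAhpMetrics:
    def _trace_with_trough(self, depth=15.0, sigma=3.0, trough_at=110.0):
        t = np.arange(0, 300, DT)
        v = np.full(t.size, -36.0)
        v += 80 * np.exp(-0.5 * ((t - 100.0) / 0.5) ** 2)
        v -= depth * np.exp(-0.5 * ((t - trough_at) / sigma) ** 2)
        return make_trace(v)

    def test_depth_relative_to_threshold(self):
        tr = self._trace_with_trough(depth=15.0)
        ahp, width, lat = ahp_metrics(tr, 100.0, threshold=-36.0)
        assert ahp == pytest.approx(-15.0, abs=0.05)
        assert lat == pytest.approx(10.0, abs=0.2)

    def test_width_matches_analytic_fwhm(self):
        sigma = 3.0
        tr = self._trace_with_trough(depth=15.0, sigma=sigma)
        _, width, _ = ahp_metrics(tr, 100.0, threshold=-36.0)
        assert width == pytest.approx(FWHM_FACTOR * sigma, rel=0.02)

    def test_missing_ahp_flagged(self):
        tr = gaussian_spike_trace([100.0], base=-36.0)  # no trough below thr
        with pytest.raises(FeatureError, match="missing AHP"):
            ahp_metrics(tr, 100.0, threshold=-36.0)


class TestApSlopes:
    def test_sinusoid_max_slope(self):
        # d/dt A sin(w t) has extrema +-A*w
        a, period = 30.0, 4.0  # ms
        w = 2 * np.pi / period
        t = np.arange(0, 200, DT)
        v = -40 + a * np.sin(w * (t - 100.0))
        tr = make_trace(v)
        mx, mn = ap_slopes(tr, 100.0, window_ms=period)
        assert mx == pytest.approx(a * w, rel=0.01)
        assert mn == pytest.approx(-a * w, rel=0.01)

    def test_template_matches_finite_difference_oracle(self):
        tr = gaussian_spike_trace([100.0], sigma_ms=0.6, amp=70.0)
        mx, mn = ap_slopes(tr, 100.0)
        d = np.diff(tr.samples) / DT  # independent forward-difference oracle
        assert mx == pytest.approx(d.max(), rel=0.01)
        assert mn == pytest.approx(d.min(), rel=0.01)

    def test_flat_trace_raises(self):
        with pytest.raises(FeatureError):
            ap_slopes(make_trace(np.full(10000, -70.0)), 100.0)


class TestInputResistance:
    def test_simple_ratio(self):
        # -40 mV steady drop under -200 pA -> 200 MOhm
        proto = PulseProtocol(-60, -200, 100, 800)
        t = np.arange(0, 1000, DT)
        v = np.full(t.size, -60.0)
        v[(t >= 100) & (t < 900)] = -100.0
        assert input_resistance(make_trace(v), proto) == pytest.approx(200.0)

    def test_rc_model_recovery(self):
        tr = gen_rc_trace(400.0, HYPER_PROTOCOL)
        r = input_resistance(tr, HYPER_PROTOCOL)
        assert r == pytest.approx(400.0, abs=2.0)

    def test_zero_step_raises(self):
        proto = PulseProtocol(-60, 0, 100, 800)
        with pytest.raises(FeatureError):
            input_resistance(make_trace(np.zeros(30000) - 60), proto)


class TestClassifier:
    def test_fsi_table_means(self):
        fs = SpikeFeatureSet(ahp=-15.89, duration_increase=6.79, amplitude_reduction=-0.24)
        assert classify_interneuron(fs) == "FSI"

    def test_nfsi_table_means(self):
        fs = SpikeFeatureSet(ahp=-8.43, duration_increase=55.06, amplitude_reduction=7.59)
        assert classify_interneuron(fs) == "NFSI"

    def test_midpoint_is_ambiguous(self):
        fs = SpikeFeatureSet(ahp=-12.16, duration_increase=30.925, amplitude_reduction=3.675)
        assert classify_interneuron(fs) == "ambiguous"

    def test_missing_features_abstain(self):
        fs = SpikeFeatureSet(ahp=-15.0)
        assert classify_interneuron(fs) == "ambiguous"

    def test_majority_vote(self):
        fs = SpikeFeatureSet(ahp=-15.0, duration_increase=10.0, amplitude_reduction=9.0)
        assert classify_interneuron(fs) == "FSI"
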