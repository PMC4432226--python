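import numpy as np
import pytest

from ng2circuit.core import Trace
from ng2circuit.synaptic_quantal import (
    PSCEvent,
    classify_release_sites,
    detect_psc,
    dzp_effect,
    fit_kinetics,
    is_unitary_connection,
    noise_sd,
    recovery_curve,
    summarize_connection,
)
from ng2circuit.synthetic.release import (
    PairedSweep,
    ReleaseModelParams,
    biexp_template,
    gen_paired_sweeps,
)

DT = 0.05


def make_sweep(samples, stims=(50.0, 100.0)):
    return PairedSweep(trace=Trace(dt=DT, samples=samples, kind="current"),
                       stim_times_ms=stims)


def analysed(params, seed):
    sweeps, truth = gen_paired_sweeps(params, seed=seed)
    sd = float(np.median([noise_sd(s) for s in sweeps]))
    events = [detect_psc(s, sd) for s in sweeps]
    return events, truth, sd


class TestGenerator:
    def test_deterministic(self):
        p = ReleaseModelParams(n_sweeps=5)
        s1, t1 = gen_paired_sweeps(p, seed=3)
        s2, t2 = gen_paired_sweeps(p, seed=3)
        assert all(np.array_equal(a.trace.samples, b.trace.samples)
                   for a, b in zip(s1, s2))
        assert np.array_equal(t1["b1"], t2["b1"])

    def test_noiseless_saturated_psc1_equals_q(self):
        p = ReleaseModelParams(n_sites=1, p1=1.0, p2=0.5, noise_sd_pa=0.0, n_sweeps=20)
        sweeps, truth = gen_paired_sweeps(p, seed=0)
        assert np.all(truth["amp1_pa"] == p.quantal_size_pa)
        ev = [detect_psc(s, 0.5) for s in sweeps]
        for e1, _ in ev:
            assert e1.amplitude_pa == pytest.approx(p.quantal_size_pa, abs=0.15)

    def test_two_site_nonfailure_mean_matches_binomial_expectation(self):
        # oracle: q * E[B | B > 0] for B ~ Binomial(2, p1), computed by
        # brute-force enumeration of the binomial outcomes
        p1, q = 0.5, -7.71
        probs = np.array([(1 - p1) ** 2, 2 * p1 * (1 - p1), p1 ** 2])
        expected = q * (probs[1] * 1 + probs[2] * 2) / (probs[1] + probs[2])
        p = ReleaseModelParams(n_sites=2, p1=p1, p2=0.25, quantal_size_pa=q,
                               noise_sd_pa=0.0, n_sweeps=4000)
        _, truth = gen_paired_sweeps(p, seed=1)
        amp1 = truth["amp1_pa"]
        assert amp1[amp1 != 0].mean() == pytest.approx(expected, rel=0.03)

    def test_ppr_converges_to_p2_over_p1(self):
        p = ReleaseModelParams(n_sites=1, p1=0.8, p2=0.4, noise_sd_pa=0.0,
                               n_sweeps=10_000)
        _, truth = gen_paired_sweeps(p, seed=2)
        ppr = truth["amp2_pa"].mean() / truth["amp1_pa"].mean()
        assert ppr == pytest.approx(0.5, rel=0.03)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            ReleaseModelParams(n_sites=3)
        with pytest.raises(ValueError):
            ReleaseModelParams(p1=0.4, p2=0.5)
        with pytest.raises(ValueError):
            ReleaseModelParams(quantal_size_pa=5.0)
        with pytest.raises(ValueError):
            ReleaseModelParams(n_sweeps=0)


class TestNoiseSd:
    def test_zero_noise(self):
        assert noise_sd(make_sweep(np.zeros(5001))) == 0.0

    def test_white_noise_recovered(self, rng):
        y = rng.normal(0, 2.0, size=5001)
        assert noise_sd(make_sweep(y)) == pytest.approx(2.0, abs=0.2)

    def test_window_outside_trace_raises(self):
        with pytest.raises((ValueError, IndexError)):
            noise_sd(make_sweep(np.zeros(100)), baseline_window_ms=(0, 500))


class TestDetect:
    def _sweep_with_event(self, amp, noise=1.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(0, 250, DT)
        y = rng.normal(0, noise, size=t.size)
        y += amp * biexp_template(t - 51.5, 0.414, 12.7)
        return make_sweep(y)

    def test_three_sigma_event_detected(self):
        sw = self._sweep_with_event(-3.0, noise=1.0)
        e1, _ = detect_psc(sw, 1.0)
        assert not e1.is_failure

    def test_one_sigma_event_is_failure(self):
        sw = self._sweep_with_event(-1.0, noise=1.0)
        e1, _ = detect_psc(sw, 1.0)
        assert e1.is_failure
        assert e1.amplitude_pa == 0.0

    def test_failure_fraction_tracks_generator(self):
        p = ReleaseModelParams(n_sites=1, p1=0.6, p2=0.35, n_sweeps=400)
        events, truth, _ = analysed(p, seed=9)
        frac_fail = np.mean([e1.is_failure for e1, _ in events])
        true_fail = np.mean(truth["b1"] == 0)
        # within the binomial 95% CI of the generator failure rate
        se = np.sqrt(true_fail * (1 - true_fail) / 400)
        assert abs(frac_fail - true_fail) < 1.96 * se + 0.02

    def test_scale_invariance_of_failure_labels(self):
        p = ReleaseModelParams(n_sites=1, p1=0.6, p2=0.35, n_sweeps=50)
        sweeps, _ = gen_paired_sweeps(p, seed=4)
        sd = float(np.median([noise_sd(s) for s in sweeps]))
        labels = [(detect_psc(s, sd)[0].is_failure, detect_psc(s, sd)[1].is_failure)
                  for s in sweeps]
        scaled = [make_sweep(3.0 * s.trace.samples, s.stim_times_ms) for s in sweeps]
        labels2 = [(detect_psc(s, 3.0 * sd)[0].is_failure,
                    detect_psc(s, 3.0 * sd)[1].is_failure) for s in scaled]
        assert labels == labels2


class TestUnitary:
    def test_pure_noise_mostly_negative(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            sweeps = [make_sweep(rng.normal(0, 1.0, 5001)) for _ in range(30)]
            hits += not is_unitary_connection(sweeps)
        assert hits >= 38  # >= 95% of seeds

    def test_deterministic_response_positive(self):
        t = np.arange(0, 250, DT)
        y = -10.0 * biexp_template(t - 51.5, 0.414, 12.7)
        rng = np.random.default_rng(0)
        sweeps = [make_sweep(y + rng.normal(0, 1.0, t.size)) for _ in range(30)]
        assert is_unitary_connection(sweeps)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            is_unitary_connection([])


class TestSummary:
    def _events(self, a1_list, a2_list):
        return [
            (PSCEvent(1, a1, 2.0 if a1 else None, a1 == 0),
             PSCEvent(2, a2, 2.0 if a2 else None, a2 == 0))
            for a1, a2 in zip(a1_list, a2_list)
        ]

    def test_ppr_half(self):
        ev = self._events([-10.0] * 10, [-5.0] * 10)
        s = summarize_connection(ev)
        assert s.ppr == pytest.approx(0.5)

    def test_identical_responses(self):
        ev = self._events([-8.0] * 10, [-8.0] * 10)
        s = summarize_connection(ev)
        assert s.ppr == pytest.approx(1.0)
        assert s.cv == pytest.approx(0.0)

    def test_all_failures_pulse1_raises(self):
        ev = self._events([0.0] * 10, [-5.0] * 10)
        with pytest.raises(ValueError):
            summarize_connection(ev)

    def test_probabilities(self):
        ev = self._events([-8, 0, -8, 0], [-4, 0, 0, 0])
        s = summarize_connection(ev)
        assert s.p1 == pytest.approx(0.5)
        assert s.p2 == pytest.approx(0.25)


class TestKinetics:
    def test_t10_90_equals_tau_ln9(self):
        tau_r = 0.5
        t = np.arange(0, 30, 0.01)
        y = -10 * (1 - np.exp(-t / tau_r))  # pure exponential rise
        t10_90, _ = fit_kinetics(t, y)
        assert t10_90 == pytest.approx(tau_r * np.log(9), rel=0.01)

    def test_biexp_decay_recovered(self):
        # default kinetics reproduce the reported unitary-event values
        t = np.arange(0, 120, DT)
        y = -10 * biexp_template(t - 1.0, 0.5676, 12.7)
        t10_90, tau = fit_kinetics(t, y)
        assert tau == pytest.approx(12.7, abs=0.1)
        assert t10_90 == pytest.approx(0.91, abs=0.02)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            fit_kinetics(np.arange(3.0), np.array([-1.0, -2.0, -3.0]))


class TestRecovery:
    def _group(self, ppr, n=30):
        return [
            (PSCEvent(1, -10.0, 2.0, False), PSCEvent(2, -10.0 * ppr, 2.0, False))
            for _ in range(n)
        ]

    def test_flat_depression_free(self):
        groups = {isi: self._group(1.0) for isi in (10, 50, 100, 250)}
        df = recovery_curve(groups)
        assert np.allclose(df["ppr"], 1.0)

    def test_constant_depression(self):
        groups = {isi: self._group(0.4) for isi in (10, 100, 250)}
        df = recovery_curve(groups)
        assert np.allclose(df["ppr"], 0.4)

    def test_single_isi(self):
        df = recovery_curve({50: self._group(0.5)})
        assert len(df) == 1


class TestReleaseSites:
    def test_one_site_recovery(self):
        p = ReleaseModelParams(n_sites=1, p1=0.6, p2=0.35, quantal_size_pa=-7.71,
                               noise_sd_pa=1.5, n_sweeps=200)
        events, _, _ = analysed(p, seed=21)
        res = classify_release_sites(events)
        assert res.n_sites == 1
        assert res.quantal_size_pa == pytest.approx(-7.71, abs=0.8)

    def test_two_site_recovery_and_doubled_psc1(self):
        p1s = ReleaseModelParams(n_sites=1, p1=0.6, p2=0.35, noise_sd_pa=1.5,
                                 n_sweeps=200)
        p2s = ReleaseModelParams(n_sites=2, p1=0.9, p2=0.45, noise_sd_pa=1.5,
                                 n_sweeps=200)
        ev1, _, _ = analysed(p1s, seed=5)
        ev2, _, _ = analysed(p2s, seed=6)
        assert classify_release_sites(ev2).n_sites == 2
        m1 = summarize_connection(ev1).mean_without_failures_pa[0]
        m2 = summarize_connection(ev2).mean_without_failures_pa[0]
        assert m2 / m1 == pytest.approx(2.0, abs=0.5)

    def test_refuses_below_100_sweeps(self):
        p = ReleaseModelParams(n_sites=1, p1=0.6, p2=0.35, n_sweeps=99)
        events, _, _ = analysed(p, seed=0)
        with pytest.raises(ValueError, match="at least 100"):
            classify_release_sites(events)

    def test_ppr_expectation_invariant(self):
        # E[PPR] -> p2/p1 under the 1-site model at large sweep count
        p = ReleaseModelParams(n_sites=1, p1=0.8, p2=0.32, noise_sd_pa=0.0,
                               n_sweeps=10_000)
        _, truth = gen_paired_sweeps(p, seed=8)
        ppr = truth["amp2_pa"].mean() / truth["amp1_pa"].mean()
        assert ppr == pytest.approx(0.4, rel=0.03)


class TestDzp:
    def _events(self, amps1, amps2):
        return [
            (PSCEvent(1, a1, 2.0, a1 == 0), PSCEvent(2, a2, 2.0, a2 == 0))
            for a1, a2 in zip(amps1, amps2)
        ]

    def test_amplitude_increase_detected_ppr_preserved(self, rng):
        base1 = -8 + rng.normal(0, 0.8, 80)
        base2 = 0.5 * base1
        ctl = self._events(base1, base2)
        dzp = self._events(1.5 * base1 + rng.normal(0, 0.1, 80), 1.5 * base2)
        out = dzp_effect(ctl, dzp)
        assert out["amplitude_significant"]
        assert out["amplitude_fold_change"] == pytest.approx(1.5, abs=0.1)
        assert not out["ppr_significant"]

    def test_identical_samples_null(self):
        ev = self._events([-8.0, -7.5, -8.5] * 20, [-4.0, -3.8, -4.2] * 20)
        out = dzp_effect(ev, list(ev))
        assert out["amplitude_fold_change"] == pytest.approx(1.0)
        assert not out["amplitude_significant"]

    def test_empty_condition_raises(self):
        ev = self._events([-8.0] * 5, [-4.0] * 5)
        with pytest.raises(ValueError):
            dzp_effect(ev, [])
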