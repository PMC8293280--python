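"""Current- and voltage-clamp feature extraction on constructed fixtures and
simulated traces."""

import math

import numpy as np
import pytest

from kv4pace.channels import GateSpec, steady_state
from kv4pace.features import (
    FitQualityWarning,
    SpikeTrain,
    ap_features,
    detect_spikes,
    excitability,
    fit_boltzmann_inactivation,
    fit_monoexp_decay,
    ih_features,
    ikdr_iv,
    integrate_charge,
    isi_stats,
    isolate_ia,
    rebound_delay,
    sag_amplitude,
)


def make_spike_trace(spike_times, duration=None, dt=0.02, baseline=-60.0, peak=20.0):
    """Triangular action potentials (2 ms rise, 3 ms fall) on a flat baseline."""
    duration = duration or (max(spike_times) + 50.0)
    t = np.arange(0.0, duration, dt)
    v = np.full_like(t, baseline)
    for ts in spike_times:
        rise = (t >= ts - 2.0) & (t < ts)
        fall = (t >= ts) & (t < ts + 3.0)
        v[rise] = baseline + (peak - baseline) * (1 - (ts - t[rise]) / 2.0)
        v[fall] = baseline + (peak - baseline) * (1 - (t[fall] - ts) / 3.0)
    return t, v


class TestDetectSpikes:
    def test_flat_trace_empty_train(self):
        t = np.arange(0, 1000, 0.02)
        assert detect_spikes(t, np.full_like(t, -60.0)).n == 0

    def test_two_hz_train_recovered(self):
        times = np.arange(500.0, 5000.0, 500.0)  # 2 Hz
        t, v = make_spike_trace(times)
        train = detect_spikes(t, v)
        assert train.n == len(times)
        assert np.allclose(train.times, times, atol=0.05)

    def test_robust_to_small_noise(self):
        times = np.arange(500.0, 5000.0, 500.0)
        t, v = make_spike_trace(times)
        rng = np.random.default_rng(0)
        noisy = v + 0.1 * rng.standard_normal(v.size)
        assert detect_spikes(t, noisy).n == detect_spikes(t, v).n


class TestISIStats:
    def test_periodic_train_zero_cv(self):
        train = SpikeTrain(times=np.arange(0.0, 20075.0, 669.5))
        out = isi_stats(train)
        assert out.mean_isi == pytest.approx(669.5)
        assert out.cv_percent == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_cv(self):
        train = SpikeTrain(times=np.array([0.0, 100.0, 300.0]))
        out = isi_stats(train)  # ISIs {100, 200}
        assert out.mean_isi == pytest.approx(150.0)
        assert out.cv_percent == pytest.approx(100.0 * np.std([100, 200], ddof=1) / 150.0)

    def test_time_scaling_leaves_cv_unchanged(self):
        rng = np.random.default_rng(1)
        times = np.cumsum(rng.uniform(50, 150, size=30))
        a = isi_stats(SpikeTrain(times=times))
        b = isi_stats(SpikeTrain(times=2.0 * times))
        assert b.mean_isi == pytest.approx(2.0 * a.mean_isi)
        assert b.cv_percent == pytest.approx(a.cv_percent)

    def test_too_few_spikes_flagged(self):
        out = isi_stats(SpikeTrain(times=np.array([0.0, 100.0])))
        assert not out.valid and math.isnan(out.mean_isi)


class TestReboundDelay:
    def test_first_peak_after_offset(self):
        t, v = make_spike_trace([4029.0, 4400.0], duration=6000.0)
        assert rebound_delay(t, v, 4000.0) == pytest.approx(29.0, abs=0.05)

    def test_spike_exactly_at_offset(self):
        t, v = make_spike_trace([4000.0, 4500.0], duration=6000.0)
        assert rebound_delay(t, v, 4000.0) == pytest.approx(0.0, abs=0.05)

    def test_no_spike_censored(self):
        t, v = make_spike_trace([1000.0], duration=10000.0)
        assert math.isnan(rebound_delay(t, v, 4000.0))

    def test_model_delay_increases_with_ga(self, morph):
        from kv4pace.simulator import (
            BiophysParamSet,
            SimConfig,
            assemble_model,
            calibrate_hyperpolarizing_amplitude,
            run_rebound,
        )

        delays = {}
        for ga in (15.0, 150.0):
            model = assemble_model(morph, biophys=BiophysParamSet(g_A=ga))
            cfg = SimConfig(dt=0.05, record_sites=("soma",))
            amp = calibrate_hyperpolarizing_amplitude(model, cfg=cfg)
            reb = run_rebound(model, amp, SimConfig(dt=0.05, record_sites=("soma",)))
            delays[ga] = rebound_delay(reb.time, reb.voltage["soma"], 4000.0)
        assert delays[150.0] > delays[15.0]


class TestAPFeatures:
    def test_triangular_spike_geometry(self):
        t, v = make_spike_trace([500.0], duration=1000.0, baseline=-60.0, peak=20.0)
        train = detect_spikes(t, v)
        f = ap_features(t, v, train)
        # threshold sits on the 40 mV/ms rising ramp where dV/dt crosses 10
        assert f.amplitude == pytest.approx(20.0 - f.threshold, abs=0.5)
        # half level between threshold and peak; triangular -> closed form
        half = 0.5 * (f.threshold + 20.0)
        t_up = 500.0 - 2.0 * (20.0 - half) / 80.0
        t_dn = 500.0 + 3.0 * (20.0 - half) / 80.0
        assert f.half_width == pytest.approx(t_dn - t_up, abs=0.1)

    def test_offset_equivariance(self):
        t, v = make_spike_trace([500.0, 1000.0, 1500.0], duration=2000.0)
        f0 = ap_features(t, v)
        f1 = ap_features(t, v + 10.0)
        assert f1.threshold == pytest.approx(f0.threshold + 10.0, abs=1e-6)
        assert f1.ahp_trough == pytest.approx(f0.ahp_trough + 10.0, abs=1e-6)
        assert f1.amplitude == pytest.approx(f0.amplitude, abs=1e-6)
        assert f1.half_width == pytest.approx(f0.half_width, abs=1e-6)

    def test_simulated_half_width_in_physiological_band(self, pacemaking_trace):
        f = ap_features(pacemaking_trace.time, pacemaking_trace.voltage["soma"])
        assert 1.3 / 2 < f.half_width < 1.3 * 2  # within a factor 2 of ~1.3 ms
        assert f.amplitude > 40.0
        assert f.ahp_trough < f.threshold


class TestSag:
    def test_exponential_relaxation_fixture(self):
        t = np.arange(0, 1000, 0.1)
        v = np.full_like(t, -60.0)
        pulse = (t >= 100) & (t <= 900)
        tp = t[pulse] - 100.0
        v[pulse] = -90.0 + 30.0 * (1 - np.exp(-tp / 50.0))  # peak -90, plateau -60
        assert sag_amplitude(t, v, (100.0, 900.0)) == pytest.approx(30.0, abs=0.05)

    def test_depolarizing_pulse_rejected(self):
        t = np.arange(0, 1000, 0.1)
        v = np.full_like(t, -60.0)
        v[(t >= 100) & (t <= 900)] = -40.0
        with pytest.raises(ValueError, match="hyperpolarizing"):
            sag_amplitude(t, v, (100.0, 900.0))

    def test_sag_increases_with_gh(self, morph):
        """With the pulse calibrated to the same -120 mV peak, the sag grows
        with the H conductance and collapses without it."""
        from kv4pace.simulator import (
            BiophysParamSet,
            SimConfig,
            StimulusProtocol,
            assemble_model,
            calibrate_hyperpolarizing_amplitude,
            integrate,
        )

        sags = {}
        cal_cfg = SimConfig(dt=0.05, record_sites=("soma",))
        for gh in (0.0, 1.375, 2.5):
            model = assemble_model(morph, biophys=BiophysParamSet(g_H=gh))
            amp = calibrate_hyperpolarizing_amplitude(model, cfg=cal_cfg)
            stim = StimulusProtocol(segments=((3000.0, 1000.0, amp),))
            tr = integrate(model, stim, SimConfig(dt=0.05, duration=4000.0, record_sites=("soma",)))
            sags[gh] = sag_amplitude(tr.time, tr.voltage["soma"], (3000.0, 4000.0))
        assert sags[0.0] < 2.0  # no H current, no sag
        assert sags[0.0] < sags[1.375] < sags[2.5]


class TestExcitability:
    @staticmethod
    def train_from_isis(first_spike, isis):
        return SpikeTrain(times=first_spike + np.concatenate([[0.0], np.cumsum(isis)]))

    def test_linear_fi_gain(self):
        responses = []
        for amp in (50.0, 100.0, 150.0, 200.0):
            f_hz = 3.0 + 0.0875 * amp  # 8.75 Hz per 100 pA
            isi = 1000.0 / f_hz
            responses.append((amp, self.train_from_isis(100.0, [isi] * 8)))
        out = excitability(responses)
        assert out.gain_start == pytest.approx(8.75, rel=1e-6)
        assert out.gain_end == pytest.approx(8.75, rel=1e-6)

    def test_constant_isi_no_adaptation(self):
        responses = [
            (100.0, self.train_from_isis(0.0, [100.0] * 10)),
            (200.0, self.train_from_isis(0.0, [80.0] * 10)),
        ]
        assert excitability(responses).sfa_index == pytest.approx(1.0)

    def test_adapting_fixture_sfa_two(self):
        responses = [
            (100.0, self.train_from_isis(0.0, [60.0, 120.0, 120.0])),
            (200.0, self.train_from_isis(0.0, [50.0, 100.0, 100.0])),
        ]
        # start 1/50 = 20 Hz, end 1/mean(100,100) = 10 Hz at the largest step
        assert excitability(responses).sfa_index == pytest.approx(2.0)

    def test_insufficient_data_flagged(self):
        out = excitability([(100.0, SpikeTrain(times=np.array([1.0])))])
        assert not out.valid


class TestIsolateIA:
    def test_identical_traces_cancel(self):
        t = np.arange(0, 500, 0.1)
        i = 100.0 + 5.0 * np.sin(t / 30.0)
        out = isolate_ia(t, i, i)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_known_transient_recovered(self):
        t = np.arange(0, 500, 0.1)
        leak = 20.0 + 0.01 * t
        transient = 800.0 * np.exp(-t / 30.0)
        out = isolate_ia(t, leak + transient, leak)
        tail = 800.0 * math.exp(-450.0 / 30.0)  # residual baseline estimate ~ 0
        assert np.allclose(out, transient, atol=tail + 1e-6)

    def test_mismatched_time_base_rejected(self):
        t = np.arange(0, 500, 0.1)
        with pytest.raises(ValueError):
            isolate_ia(t, np.zeros(t.size), np.zeros(t.size - 1))


class TestBoltzmannFit:
    def test_noiseless_recovery(self):
        v = np.arange(-110.0, -25.0, 10.0)
        h = 1.0 / (1.0 + np.exp(-(v + 68.91) / -6.0))
        peaks = 2140.0 * h
        v50, k = fit_boltzmann_inactivation(peaks, v)
        assert v50 == pytest.approx(-68.91, abs=0.01)
        assert k == pytest.approx(-6.0, abs=0.01)

    def test_monte_carlo_recovery_under_noise(self):
        rng = np.random.default_rng(42)
        v = np.arange(-110.0, -25.0, 10.0)
        h = 1.0 / (1.0 + np.exp(-(v + 68.91) / -6.0))
        errs = []
        for _ in range(100):
            peaks = 2140.0 * h * (1.0 + 0.05 * rng.standard_normal(v.size))
            v50, _ = fit_boltzmann_inactivation(peaks, v)
            errs.append(abs(v50 + 68.91))
        assert np.median(errs) < 1.0

    def test_saturated_data_warns(self):
        v = np.arange(-140.0, -90.0, 10.0)
        peaks = np.full(v.size, 2140.0)
        with pytest.warns(FitQualityWarning):
            fit_boltzmann_inactivation(peaks, v)


class TestMonoexpFit:
    def test_noiseless_tau_recovery(self):
        t = np.arange(0, 300, 0.1)
        i = 1500.0 * np.exp(-t / 30.9)
        assert fit_monoexp_decay(t, i) == pytest.approx(30.9, rel=1e-3)

    def test_amplitude_scaling_invariance(self):
        t = np.arange(0, 300, 0.1)
        i = np.exp(-t / 42.0)
        assert fit_monoexp_decay(t, 1000.0 * i) == pytest.approx(
            fit_monoexp_decay(t, 10.0 * i), rel=1e-6
        )

    def test_biexponential_warns(self):
        t = np.arange(0, 300, 0.1)
        i = 1000.0 * np.exp(-t / 10.0) + 1000.0 * np.exp(-t / 120.0)
        with pytest.warns(FitQualityWarning):
            fit_monoexp_decay(t, i)

    def test_non_decaying_rejected(self):
        t = np.arange(0, 300, 0.1)
        with pytest.raises(ValueError):
            fit_monoexp_decay(t, t.copy())


class TestCharge:
    def test_rectangle(self):
        t = np.arange(0, 500.0 + 1e-9, 0.1)
        assert integrate_charge(t, np.full(t.size, 1000.0), (0.0, 500.0)) == pytest.approx(500.0)

    def test_exponential_closed_form(self):
        t = np.arange(0, 500.0 + 1e-9, 0.01)
        i = 2000.0 * np.exp(-t / 50.0)
        expected = 2.0 * 50.0 * (1.0 - math.exp(-10.0))  # A tau (1 - e^-10), pA s
        assert integrate_charge(t, i, (0.0, 500.0)) == pytest.approx(expected, rel=1e-4)

    def test_zero_trace(self):
        t = np.arange(0, 500.0, 0.1)
        assert integrate_charge(t, np.zeros(t.size), (0.0, 499.0)) == 0.0

    def test_window_outside_trace_rejected(self):
        t = np.arange(0, 100.0, 0.1)
        with pytest.raises(ValueError):
            integrate_charge(t, np.zeros(t.size), (0.0, 500.0))


def make_ih_family(g_scale=1.0, v50=-88.41, steps=(-120, -110, -100, -90, -80, -70)):
    """Two-step family built from the model's own H-current kinetics: ohmic
    current with Boltzmann steady-state activation and slow mono-exponential
    relaxation from the resting activation level."""
    gate = GateSpec(v50, -7.25, 1)
    m_rest = steady_state(-50.0, gate)
    t = np.arange(0, 4000.0, 1.0)
    fam = []
    for v_step in steps:
        m_inf = steady_state(v_step, gate)
        m = m_inf + (m_rest - m_inf) * np.exp(-t / 600.0)
        i = g_scale * 400.0 * m * (v_step - (-40.0))  # pA, inward negative
        fam.append((float(v_step), t, i))
    return fam


class TestIHFeatures:
    def test_v50_recovery_from_own_kinetics(self):
        out = ih_features(make_ih_family())
        assert out.v50_act == pytest.approx(-88.41, abs=0.5)

    def test_zero_conductance_amplitude(self):
        out = ih_features(make_ih_family(g_scale=0.0))
        assert out.amplitude == 0.0

    def test_amplitude_linear_in_conductance(self):
        a1 = ih_features(make_ih_family(g_scale=1.0)).amplitude
        a2 = ih_features(make_ih_family(g_scale=2.0)).amplitude
        assert a2 == pytest.approx(2.0 * a1, rel=1e-9)

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError):
            ih_features(make_ih_family()[:3])


class TestIKDRIV:
    @staticmethod
    def make_family(inactivating=False):
        t = np.arange(0, 500.0, 0.5)
        fam = []
        for v_step in np.arange(-30.0, 41.0, 10.0):
            act = 1.0 / (1.0 + np.exp(-(v_step + 30.0) / 9.0)) ** 4
            i = 3000.0 * act * (v_step + 90.0) / 130.0 * np.ones_like(t)
            if inactivating:
                i = i * (0.6 + 0.4 * np.exp(-t / 80.0))
            fam.append((float(v_step), t, i))
        return fam

    def test_non_inactivating_peak_equals_steady(self):
        iv = ikdr_iv(self.make_family(False))
        assert np.allclose(iv.peak, iv.steady, rtol=1e-9)

    def test_peak_dominates_steady_for_inactivating(self):
        iv = ikdr_iv(self.make_family(True))
        assert np.all(iv.peak >= iv.steady)

    def test_monotone_iv_for_boltzmann_ohmic_family(self):
        iv = ikdr_iv(self.make_family(False))
        assert np.all(np.diff(iv.peak) > 0)


class TestResamplingInvariance:
    def test_features_stable_at_double_rate(self):
        times = np.arange(500.0, 8000.0, 400.0)
        t1, v1 = make_spike_trace(times, duration=8200.0, dt=0.04)
        t2, v2 = make_spike_trace(times, duration=8200.0, dt=0.02)
        s1 = isi_stats(detect_spikes(t1, v1))
        s2 = isi_stats(detect_spikes(t2, v2))
        assert s1.mean_isi == pytest.approx(s2.mean_isi, rel=0.01)
        f1 = ap_features(t1, v1)
        f2 = ap_features(t2, v2)
        assert f1.half_width == pytest.approx(f2.half_width, rel=0.01)
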