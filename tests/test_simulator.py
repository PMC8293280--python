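"""Integration correctness: passive oracles, region rules, pacemaking,
calibration and numerical convergence."""

import math

import numpy as np
import pytest

from kv4pace.features import detect_spikes, isi_stats
from kv4pace.morphology import (
    DiscretizationPolicy,
    Morphology,
    MorphologyTemplate,
    PassiveSpec,
    Section,
    generate_population,
)
from kv4pace.simulator import (
    BiophysParamSet,
    SimConfig,
    StimulusProtocol,
    assemble_model,
    calibrate_hyperpolarizing_amplitude,
    integrate,
    run_pacemaking,
)

PASSIVE = PassiveSpec()


def passive_model(morph, zero_densities, policy=None):
    return assemble_model(
        morph,
        biophys=BiophysParamSet(g_A=0.0, g_H=0.0),
        densities=zero_densities,
        policy=policy,
    )


class TestPassiveOracles:
    def test_rc_step_response_matches_closed_form(
        self, soma_only_morph, zero_active_densities
    ):
        """A passive compartment under a current step follows
        V = V_inf + (V_0 - V_inf) exp(-t/tau) with tau = Rm Cm."""
        model = passive_model(soma_only_morph, zero_active_densities)
        amp = -5.0  # pA
        cfg = SimConfig(dt=0.02, duration=1500.0, v_init=-50.0, record_sites=("soma",))
        tr = integrate(model, StimulusProtocol(segments=((500.0, 1000.0, amp),)), cfg)
        area_cm2 = model.comps.area[0] * 1e-8
        r_in = PASSIVE.specific_membrane_resistance / area_cm2  # Ohm
        # Ohm cm^2 * uF/cm^2 = Ohm uF = us -> ms
        tau = PASSIVE.specific_membrane_resistance * PASSIVE.specific_capacitance * 1e-3
        v_inf = PASSIVE.e_leak + amp * 1e-12 * r_in * 1e3  # mV
        t = tr.time
        expected = np.where(
            t < 500.0,
            PASSIVE.e_leak,
            v_inf + (PASSIVE.e_leak - v_inf) * np.exp(-(t - 500.0) / tau),
        )
        in_pulse = (t >= 500.0) & (t <= 1500.0)
        deflection = abs(v_inf - PASSIVE.e_leak)
        err = np.max(np.abs(tr.voltage["soma"][in_pulse] - expected[in_pulse]))
        assert err < 0.005 * deflection

    def test_leak_only_equilibrates_at_e_leak(self, morph, zero_active_densities):
        model = passive_model(morph, zero_active_densities)
        tr = integrate(model, None, SimConfig(duration=800.0, record_sites=("soma",)))
        assert tr.voltage["soma"][-1] == pytest.approx(-50.0, abs=0.01)

    def test_charge_balance_at_steady_state(self, soma_only_morph, zero_active_densities):
        """In a passive compartment at steady state the injected current is
        carried entirely by the leak."""
        model = passive_model(soma_only_morph, zero_active_densities)
        amp = -8.0
        cfg = SimConfig(duration=1200.0, v_init=-50.0, record_sites=("soma",))
        tr = integrate(model, StimulusProtocol(segments=((200.0, 1000.0, amp),)), cfg)
        v_ss = tr.voltage["soma"][-1]
        g_leak = model.G["leak"][0]  # mS
        leak_uA = g_leak * (v_ss - PASSIVE.e_leak)
        assert leak_uA == pytest.approx(amp * 1e-6, rel=1e-3)

    def test_spatial_consistency_of_passive_cable(self, zero_active_densities):
        """Refining the discretization of a passive cable leaves the somatic
        steady state essentially unchanged."""
        tpl = MorphologyTemplate(n_dendrites=(2, 2), branch_prob=0.0)
        (m,) = generate_population(1, seed=5, template=tpl)
        v = {}
        for dl in (0.1, 0.05):
            model = passive_model(
                m, zero_active_densities, policy=DiscretizationPolicy(d_lambda=dl)
            )
            cfg = SimConfig(duration=1000.0, v_init=-50.0, record_sites=("soma",))
            tr = integrate(model, StimulusProtocol(segments=((100.0, 900.0, -20.0),)), cfg)
            v[dl] = tr.voltage["soma"][-1]
        assert abs(v[0.1] - v[0.05]) / abs(v[0.05]) < 1e-3


class TestAssembly:
    def test_ais_and_axon_carry_only_na_kdr_leak(self, default_model):
        comps = default_model.comps
        for region in ("AIS", "axon"):
            sel = np.asarray(comps.region) == region
            assert sel.any()
            for chan in ("A", "H", "CaL", "SK"):
                assert np.all(default_model.G[chan][sel] == 0.0)
            for chan in ("Na", "KDR", "leak"):
                assert np.all(default_model.G[chan][sel] > 0.0)

    def test_zero_ga_everywhere(self, morph):
        model = assemble_model(morph, biophys=BiophysParamSet(g_A=0.0))
        assert np.all(model.G["A"] == 0.0)

    def test_total_a_conductance_scales_linearly(self, morph):
        g1 = assemble_model(morph, biophys=BiophysParamSet(g_A=30.0)).G["A"].sum()
        g2 = assemble_model(morph, biophys=BiophysParamSet(g_A=90.0)).G["A"].sum()
        assert g2 == pytest.approx(3.0 * g1, rel=1e-12)

    def test_leak_fixed_by_membrane_resistance(self, default_model):
        dens = default_model.G["leak"] / (default_model.comps.area * 1e-9)
        assert np.allclose(dens, 1e4 / PASSIVE.specific_membrane_resistance)


class TestPacemaking:
    def test_spontaneous_firing_without_injected_current(self, pacemaking_trace):
        assert pacemaking_trace.meta["pacemaking"]
        assert len(pacemaking_trace.meta["spike_times"]) >= 6
        assert np.all(np.abs(pacemaking_trace.voltage["soma"]) < 200)

    def test_ap_initiates_in_ais_before_soma(self, pacemaking_trace):
        tr = pacemaking_trace
        ais = detect_spikes(tr.time, tr.voltage["AIS"])
        soma = detect_spikes(tr.time, tr.voltage["soma"])
        n = min(ais.n, soma.n)
        assert n >= 5
        assert np.all(ais.threshold_times[:n] < soma.threshold_times[:n])

    def test_stabilization_marker(self, pacemaking_trace):
        assert pacemaking_trace.meta["stabilization_index"] == 4

    def test_silent_model_flagged_not_error(self, morph, zero_active_densities):
        model = assemble_model(
            morph, biophys=BiophysParamSet(g_A=0.0, g_H=0.0), densities=zero_active_densities
        )
        tr = run_pacemaking(model, SimConfig(duration=1000.0))
        assert not tr.meta["pacemaking"]
        assert len(tr.meta["spike_times"]) == 0

    def test_isi_stationary_when_duration_doubles(self, default_model, pacemaking_trace):
        long = run_pacemaking(default_model, SimConfig(duration=16000.0))

        def post_stab_isi(tr):
            st = tr.meta["spike_times"]
            return isi_stats(
                detect_spikes(tr.time, tr.voltage["soma"]), (st[4], tr.time[-1])
            ).mean_isi

        a = post_stab_isi(pacemaking_trace)
        b = post_stab_isi(long)
        assert abs(a - b) / b < 0.01

    def test_temporal_convergence_halving_dt(self, default_model):
        isis = {}
        for dt in (0.02, 0.01):
            tr = run_pacemaking(default_model, SimConfig(dt=dt, duration=6000.0))
            st = tr.meta["spike_times"]
            isis[dt] = isi_stats(
                detect_spikes(tr.time, tr.voltage["soma"]), (st[4], tr.time[-1])
            ).mean_isi
        assert abs(isis[0.02] - isis[0.01]) / isis[0.01] < 0.01


class TestCalibration:
    def test_calibrated_amplitude_reproduces_peak(self, default_model):
        cfg = SimConfig(dt=0.05, record_sites=("soma",))
        amp = calibrate_hyperpolarizing_amplitude(default_model, cfg=cfg)
        stim = StimulusProtocol(segments=((3000.0, 1000.0, amp),))
        tr = integrate(default_model, stim, SimConfig(dt=0.05, duration=4000.0, record_sites=("soma",)))
        peak = tr.voltage["soma"][tr.time >= 3000.0].min()
        assert abs(peak - (-120.0)) <= 2.0

    def test_larger_gh_needs_larger_amplitude(self, morph):
        amps = {}
        cfg = SimConfig(dt=0.05, record_sites=("soma",))
        for gh in (0.25, 2.5):
            model = assemble_model(morph, biophys=BiophysParamSet(g_H=gh))
            amps[gh] = calibrate_hyperpolarizing_amplitude(model, cfg=cfg)
        assert abs(amps[2.5]) > abs(amps[0.25])

    def test_loose_tolerance_converges_fast(self, default_model):
        calls = []
        import kv4pace.simulator as sim

        orig = sim.integrate

        def counting(*args, **kwargs):
            calls.append(1)
            return orig(*args, **kwargs)

        sim.integrate = counting
        try:
            amp = calibrate_hyperpolarizing_amplitude(
                default_model, tolerance=50.0, cfg=SimConfig(dt=0.05, record_sites=("soma",))
            )
        finally:
            sim.integrate = orig
        assert amp < 0
        assert len(calls) <= 6  # bracketing plus at most a couple of bisections


class TestGuards:
    def test_divergence_error_names_step(self, soma_only_morph, zero_active_densities):
        model = passive_model(soma_only_morph, zero_active_densities)
        stim = StimulusProtocol(segments=((0.0, 100.0, 1e9),))
        with pytest.raises(RuntimeError, match="diverged"):
            integrate(model, stim, SimConfig(duration=100.0, record_sites=("soma",)))

    def test_overlapping_stimulus_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            StimulusProtocol(segments=((0.0, 100.0, 10.0), (50.0, 100.0, 20.0)))

    def test_trace_export_long_format(self, soma_only_morph, zero_active_densities, tmp_path):
        model = passive_model(soma_only_morph, zero_active_densities)
        tr = integrate(model, None, SimConfig(duration=10.0, record_sites=("soma",)))
        df = tr.to_frame()
        assert set(df.columns) == {"time_ms", "site", "variable", "value"}
        out = tmp_path / "trace.csv"
        tr.to_csv(out)
        assert out.exists()

    def test_trace_hdf5_round_trip(self, soma_only_morph, zero_active_densities, tmp_path):
        from kv4pace.simulator import TraceSet

        model = passive_model(soma_only_morph, zero_active_densities)
        tr = integrate(model, None, SimConfig(duration=10.0, record_sites=("soma",)))
        path = tmp_path / "trace.h5"
        tr.to_hdf5(path)
        back = TraceSet.from_hdf5(path)
        assert np.array_equal(back.time, tr.time)
        assert np.array_equal(back.voltage["soma"], tr.voltage["soma"])
        assert np.array_equal(back.calcium, tr.calcium)
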