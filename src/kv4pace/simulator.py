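"""Compartmental Hodgkin-Huxley simulation of SNc dopaminergic neurons.

The membrane equation per compartment,

    Cm dV/dt = -sum_i g_i (V - E_i) - I_axial + I_stim,

is integrated with an implicit (backward-Euler) step: channel conductances are
frozen at the current gate states, the resulting linear branched-cable system
is solved by Hines-ordered tridiagonal elimination (parents precede children),
and gates are then advanced by their exact exponential update at the new
step's voltage (first-order staggering).  This is unconditionally stable at
the model's working step of dt = 0.02 ms.

Intracellular calcium follows a single-shell decay model: influx proportional
to the inward L-type calcium current (Faraday scaling over a thin submembrane
shell) with first-order decay back to baseline; the SK current is an
instantaneous Hill function of shell calcium.

Internal unit scheme: mV, ms, uA, mS, uF, mM; densities enter as pS/um^2 and
areas as um^2 (1 pS/um^2 * 1 um^2 = 1e-9 mS).  Stimulus amplitudes are pA.
The heavy per-step loop is numba-compiled; voltage-dependent steady states and
exponential gate factors are pre-tabulated on a 0.05 mV grid and linearly
interpolated, which reproduces the closed forms to well below solver error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .channels import (
    GateSpec,
    IAKineticsLink,
    RegionDensities,
    TimeConstantRule,
    V50Coupling,
    load_channel_defaults,
    steady_state,
    time_constant,
)
from .morphology import (
    CompartmentSet,
    DiscretizationPolicy,
    Morphology,
    PassiveSpec,
    discretize,
)

__all__ = [
    "BiophysParamSet",
    "CalciumModel",
    "SimConfig",
    "StimulusProtocol",
    "TraceSet",
    "ModelInstance",
    "assemble_model",
    "integrate",
    "calibrate_hyperpolarizing_amplitude",
    "run_pacemaking",
    "run_rebound",
]

FARADAY = 96485.332  # C/mol

# gate order in the state matrix / kinetics tables
GATE_NAMES = ("na_m", "na_h", "kdr_m", "a_m", "a_h", "h_m", "cal_m")

_VMIN, _VMAX, _DV = -150.0, 100.0, 0.05


@dataclass(frozen=True)
class BiophysParamSet:
    """The four swept biophysical parameters of the I_A / I_H study.

    Defaults are the centers of the model's grid ranges.  The I_A voltage
    dependence is derived from ``v50_h_act`` through the linear coupling and
    the 50-mV activation shift; activation tau is ``tau_h_A / 50``.
    """

    g_A: float = 82.5  # pS/um^2, grid 15-150
    g_H: float = 1.375  # pS/um^2, grid 0.25-2.5
    v50_h_act: float = -90.0  # mV, grid -100..-80
    tau_h_A: float = 82.5  # ms, grid 15-150

    @property
    def v50_a_inact(self) -> float:
        return V50Coupling()(self.v50_h_act)

    @property
    def v50_a_act(self) -> float:
        return self.v50_a_inact + IAKineticsLink().v50_shift

    @property
    def tau_m_A(self) -> float:
        return self.tau_h_A / IAKineticsLink().tau_ratio


@dataclass(frozen=True)
class CalciumModel:
    """Single-shell calcium decay model (constants configurable)."""

    shell_depth: float = 1.0  # um
    decay_tau: float = 5.0  # ms
    baseline: float = 5e-5  # mM


@dataclass(frozen=True)
class SimConfig:
    dt: float = 0.02  # ms
    duration: float = 8000.0  # ms
    v_init: float = -70.0  # mV
    stabilization_spikes: int = 4
    record_sites: Tuple[str, ...] = ("soma", "AIS")

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")


@dataclass(frozen=True)
class StimulusProtocol:
    """Somatic current injection: non-overlapping (start, duration, pA) segments."""

    segments: Tuple[Tuple[float, float, float], ...] = ()
    site: str = "soma"

    def __post_init__(self) -> None:
        segs = sorted(self.segments)
        for (s0, d0, _), (s1, _, _) in zip(segs, segs[1:]):
            if s0 + d0 > s1 + 1e-9:
                raise ValueError("stimulus segments must not overlap")

    def amplitudes(self, n_steps: int, dt: float) -> np.ndarray:
        out = np.zeros(n_steps)
        t = np.arange(n_steps) * dt
        for start, dur, amp in self.segments:
            out[(t >= start) & (t < start + dur)] = amp
        return out


@dataclass
class TraceSet:
    """Uniformly sampled simulation traces with stimulus metadata."""

    time: np.ndarray  # ms
    voltage: Dict[str, np.ndarray]  # mV per recorded site
    stimulus: np.ndarray  # pA at the injection site
    calcium: Optional[np.ndarray] = None  # mM at the soma
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def to_frame(self):
        """Long-format DataFrame (time_ms, site, variable, value)."""
        import pandas as pd

        parts = [
            pd.DataFrame(
                {"time_ms": self.time, "site": site, "variable": "v_mV", "value": v}
            )
            for site, v in self.voltage.items()
        ]
        parts.append(
            pd.DataFrame(
                {
                    "time_ms": self.time,
                    "site": "soma",
                    "variable": "i_stim_pA",
                    "value": self.stimulus,
                }
            )
        )
        return pd.concat(parts, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("time_ms", data=self.time)
            f.create_dataset("stimulus_pA", data=self.stimulus)
            if self.calcium is not None:
                f.create_dataset("calcium_mM", data=self.calcium)
            g = f.create_group("voltage_mV")
            for site, v in self.voltage.items():
                g.create_dataset(site, data=v)

    @classmethod
    def from_hdf5(cls, path) -> "TraceSet":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                time=f["time_ms"][:],
                voltage={k: f["voltage_mV"][k][:] for k in f["voltage_mV"]},
                stimulus=f["stimulus_pA"][:],
                calcium=f["calcium_mM"][:] if "calcium_mM" in f else None,
            )


@dataclass
class ModelInstance:
    """A simulatable cell: compartment arrays + channel placement + kinetics."""

    comps: CompartmentSet
    biophys: BiophysParamSet
    passive: PassiveSpec
    calcium: CalciumModel
    densities: RegionDensities
    # derived arrays (absolute conductances in mS, capacitance in uF)
    cap: np.ndarray = field(default=None, repr=False)
    gax: np.ndarray = field(default=None, repr=False)
    G: Dict[str, np.ndarray] = field(default=None, repr=False)
    e_rev: Dict[str, float] = field(default=None, repr=False)
    _gate_specs: dict = field(default=None, repr=False)
    _table_cache: dict = field(default_factory=dict, repr=False)

    def site_index(self, site: str) -> int:
        return self.comps.middle_of(site)

    def kinetics_tables(self, dt: float) -> Tuple[np.ndarray, np.ndarray]:
        """(m_inf, exp(-dt/tau)) tables, shape (7, n_grid), on the 0.05 mV grid."""
        key = round(dt, 9)
        if key not in self._table_cache:
            vgrid = np.arange(_VMIN, _VMAX + _DV / 2, _DV)
            minf = np.empty((len(GATE_NAMES), vgrid.size))
            efact = np.empty_like(minf)
            for gi, gname in enumerate(GATE_NAMES):
                gate, rule = self._gate_specs[gname]
                minf[gi] = steady_state(vgrid, gate)
                efact[gi] = np.exp(-dt / time_constant(vgrid, rule))
            self._table_cache[key] = (minf, efact)
        return self._table_cache[key]


def assemble_model(
    morph: Morphology,
    biophys: Optional[BiophysParamSet] = None,
    densities: Optional[RegionDensities] = None,
    passive: Optional[PassiveSpec] = None,
    calcium: Optional[CalciumModel] = None,
    policy: Optional[DiscretizationPolicy] = None,
) -> ModelInstance:
    """Discretize a morphology and attach channels region by region.

    Na, KDR and leak are present everywhere; A, H, CaL and SK only in the
    soma/dendrites/axon-start region.  Leak density is fixed by the passive
    specific membrane resistance.
    """
    defaults = load_channel_defaults()
    biophys = biophys or BiophysParamSet()
    densities = densities or defaults["densities"]
    passive = passive or PassiveSpec()
    calcium = calcium or CalciumModel()
    comps = discretize(morph, policy or DiscretizationPolicy(), passive)

    n = comps.n
    area_um2 = comps.area
    cap = passive.specific_capacitance * area_um2 * 1e-8  # uF

    # axial conductance to parent (mS): half-cylinder resistances in series
    gax = np.zeros(n)
    ra = passive.axial_resistivity  # Ohm cm
    half_r = ra * (comps.length * 1e-4 / 2.0) / (
        math.pi * (comps.diameter * 1e-4 / 2.0) ** 2
    )  # Ohm per compartment half
    for i in range(1, n):
        p = comps.parent[i]
        r_ohm = half_r[i] + half_r[p]
        gax[i] = 1000.0 / r_ohm  # mS

    # 1/Rm in S/cm^2 -> pS/um^2 (1 S/cm^2 = 1e4 pS/um^2)
    leak_density = 1e4 / passive.specific_membrane_resistance
    G: Dict[str, np.ndarray] = {}
    for chan in ("Na", "KDR", "A", "H", "CaL", "SK"):
        dens = np.array([densities.get(chan, r) for r in comps.region])
        G[chan] = dens * area_um2 * 1e-9  # mS
    G["leak"] = np.full(n, leak_density) * area_um2 * 1e-9
    # swept parameters override the defaults-file densities
    G["A"] = np.where(np.asarray(comps.region) == "soma_dend", biophys.g_A, 0.0) * area_um2 * 1e-9
    G["H"] = np.where(np.asarray(comps.region) == "soma_dend", biophys.g_H, 0.0) * area_um2 * 1e-9

    raw = defaults["raw"]["channels"]
    e_rev = {name: raw[name]["e_rev"] for name in ("Na", "KDR", "A", "H", "CaL", "SK")}
    e_rev["leak"] = passive.e_leak

    chans = defaults["channels"]
    gate_specs = {
        "na_m": (chans["Na"].m_gate, chans["Na"].tau_m),
        "na_h": (chans["Na"].h_gate, chans["Na"].tau_h),
        "kdr_m": (chans["KDR"].m_gate, chans["KDR"].tau_m),
        "a_m": (
            GateSpec(biophys.v50_a_act, 7.0, 1),
            TimeConstantRule("constant", {"value": biophys.tau_m_A}),
        ),
        "a_h": (
            GateSpec(biophys.v50_a_inact, -7.0, 1),
            TimeConstantRule("constant", {"value": biophys.tau_h_A}),
        ),
        "h_m": (GateSpec(biophys.v50_h_act, -7.25, 1), chans["H"].tau_m),
        "cal_m": (chans["CaL"].m_gate, chans["CaL"].tau_m),
    }
    return ModelInstance(
        comps=comps,
        biophys=biophys,
        passive=passive,
        calcium=calcium,
        densities=densities,
        cap=cap,
        gax=gax,
        G=G,
        e_rev=e_rev,
        _gate_specs=gate_specs,
    )


@njit(cache=True)
def _step_loop(
    V,
    m,
    ca,
    parent,
    gax,
    cap_dt,
    Gna,
    Gkdr,
    Ga,
    Gh,
    Gcal,
    Gsk,
    Gleak,
    Ena,
    Ekdr,
    Ea,
    Eh,
    Ecal,
    Esk,
    Eleak,
    minf_t,
    ef_t,
    vmin,
    inv_dv,
    stim,
    stim_comp,
    rec_sites,
    rec_out,
    ca_rec,
    ca_base,
    ca_efact,
    ca_kflux,
    ca_tau,
    inv_area_cm2,
    k4,
):  # pragma: no cover - exercised via integrate()
    n = V.size
    nv = minf_t.shape[1]
    n_steps = stim.size
    d = np.empty(n)
    rhs = np.empty(n)
    for step in range(n_steps):
        # exact exponential gate update at the current voltage
        for i in range(n):
            x = (V[i] - vmin) * inv_dv
            if x < 0.0:
                x = 0.0
            elif x > nv - 1.001:
                x = nv - 1.001
            j = int(x)
            fr = x - j
            for g in range(7):
                mi = minf_t[g, j] * (1.0 - fr) + minf_t[g, j + 1] * fr
                ef = ef_t[g, j] * (1.0 - fr) + ef_t[g, j + 1] * fr
                m[g, i] = mi + (m[g, i] - mi) * ef
        # assemble the implicit system with frozen conductances
        for i in range(n):
            m0 = m[0, i]
            m2 = m[2, i]
            gna = Gna[i] * m0 * m0 * m0 * m[1, i]
            gk = Gkdr[i] * m2 * m2 * m2 * m2
            ga = Ga[i] * m[3, i] * m[4, i]
            gh = Gh[i] * m[5, i]
            gca = Gcal[i] * m[6, i]
            c = ca[i]
            c4 = c * c * c * c
            gsk = Gsk[i] * c4 / (c4 + k4)
            d[i] = (
                cap_dt[i] + gna + gk + ga + gh + gca + gsk + Gleak[i]
            )
            rhs[i] = (
                cap_dt[i] * V[i]
                + gna * Ena
                + gk * Ekdr
                + ga * Ea
                + gh * Eh
                + gca * Ecal
                + gsk * Esk
                + Gleak[i] * Eleak
            )
        rhs[stim_comp] += stim[step]
        for i in range(1, n):
            d[i] += gax[i]
            d[parent[i]] += gax[i]
        # Hines elimination (parents precede children)
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = gax[i] / d[i]
            d[p] -= gax[i] * f
            rhs[p] += rhs[i] * f
        V[0] = rhs[0] / d[0]
        for i in range(1, n):
            V[i] = (rhs[i] + gax[i] * V[parent[i]]) / d[i]
        # calcium shell update from the L-type current at the new voltage
        for i in range(n):
            if Gcal[i] > 0.0:
                idens = Gcal[i] * m[6, i] * (V[i] - Ecal) * inv_area_cm2[i]
                influx = -idens * ca_kflux
                if influx < 0.0:
                    influx = 0.0
                cinf = ca_base + ca_tau * influx
                ca[i] = cinf + (ca[i] - cinf) * ca_efact
        for s in range(rec_sites.size):
            rec_out[step + 1, s] = V[rec_sites[s]]
        ca_rec[step + 1] = ca[0]
        if step % 500 == 0:
            for i in range(n):
                if not (-200.0 < V[i] < 200.0):
                    return step
    return -1


def integrate(
    model: ModelInstance,
    stim: Optional[StimulusProtocol] = None,
    cfg: Optional[SimConfig] = None,
) -> TraceSet:
    """Run the implicit compartmental integration under a stimulus protocol."""
    cfg = cfg or SimConfig()
    stim = stim or StimulusProtocol()
    comps = model.comps
    n = comps.n
    n_steps = int(round(cfg.duration / cfg.dt))

    V = np.full(n, cfg.v_init, dtype=float)
    m = np.empty((len(GATE_NAMES), n))
    for gi, gname in enumerate(GATE_NAMES):
        gate, _ = model._gate_specs[gname]
        m[gi, :] = steady_state(cfg.v_init, gate)
    ca = np.full(n, model.calcium.baseline)

    minf_t, ef_t = model.kinetics_tables(cfg.dt)
    stim_uA = stim.amplitudes(n_steps, cfg.dt) * 1e-6
    site_names = list(cfg.record_sites)
    rec_sites = np.array([model.site_index(s) for s in site_names], dtype=np.int64)
    rec_out = np.empty((n_steps + 1, rec_sites.size))
    rec_out[0] = V[rec_sites]
    ca_rec = np.empty(n_steps + 1)
    ca_rec[0] = ca[comps.middle_of("soma")]

    cal = model.calcium
    bad_step = _step_loop(
        V,
        m,
        ca,
        comps.parent,
        model.gax,
        model.cap / cfg.dt,
        model.G["Na"],
        model.G["KDR"],
        model.G["A"],
        model.G["H"],
        model.G["CaL"],
        model.G["SK"],
        model.G["leak"],
        model.e_rev["Na"],
        model.e_rev["KDR"],
        model.e_rev["A"],
        model.e_rev["H"],
        model.e_rev["CaL"],
        model.e_rev["SK"],
        model.e_rev["leak"],
        minf_t,
        ef_t,
        _VMIN,
        1.0 / _DV,
        stim_uA,
        model.site_index(stim.site),
        rec_sites,
        rec_out,
        ca_rec,
        cal.baseline,
        math.exp(-cfg.dt / cal.decay_tau),
        1e-3 / (2.0 * FARADAY * cal.shell_depth * 1e-4),
        cal.decay_tau,
        1.0 / (comps.area * 1e-8),
        0.00019**4,
    )
    if bad_step >= 0:
        raise RuntimeError(
            f"simulation diverged (|V| > 200 mV) at step {bad_step} "
            f"(t = {bad_step * cfg.dt:.2f} ms)"
        )
    time = np.arange(n_steps + 1) * cfg.dt
    stim_pA = np.concatenate([[0.0], stim_uA * 1e6])
    return TraceSet(
        time=time,
        voltage={s: rec_out[:, k] for k, s in enumerate(site_names)},
        stimulus=stim_pA,
        calcium=ca_rec,
        meta={
            "dt": cfg.dt,
            "duration": cfg.duration,
            "morphology_id": comps.morphology_id,
            "biophys": model.biophys,
            "protocol": stim,
        },
    )


def run_pacemaking(model: ModelInstance, cfg: Optional[SimConfig] = None) -> TraceSet:
    """Simulate spontaneous activity; flag the first stabilization spikes.

    The trace metadata carries the detected somatic spike times, the
    stabilization marker (index of the first spike retained for analysis) and
    a ``pacemaking`` flag (False when fewer than 6 spikes occurred).
    """
    from .features import detect_spikes

    cfg = cfg or SimConfig()
    traces = integrate(model, StimulusProtocol(), cfg)
    train = detect_spikes(traces.time, traces.voltage["soma"])
    n_stab = cfg.stabilization_spikes
    traces.meta["spike_times"] = train.times
    traces.meta["stabilization_index"] = min(n_stab, train.times.size)
    traces.meta["pacemaking"] = train.times.size >= 6
    return traces


def calibrate_hyperpolarizing_amplitude(
    model: ModelInstance,
    target_peak: float = -120.0,
    tolerance: float = 2.0,
    cfg: Optional[SimConfig] = None,
    stabilization_ms: float = 3000.0,
    pulse_ms: float = 1000.0,
    bracket_max_pA: float = -6400.0,
) -> float:
    """Bisect the 1-s hyperpolarizing pulse amplitude (pA) to a target somatic
    peak hyperpolarization (default -120 +/- 2 mV).

    Deterministic: the pulse starts after a fixed stabilization period and the
    simulation stops at pulse offset (the peak occurs within the pulse).
    """
    cfg = cfg or SimConfig()

    def peak_for(amp: float) -> float:
        sub = SimConfig(
            dt=cfg.dt,
            duration=stabilization_ms + pulse_ms,
            v_init=cfg.v_init,
            record_sites=("soma",),
        )
        stim = StimulusProtocol(segments=((stabilization_ms, pulse_ms, amp),))
        tr = integrate(model, stim, sub)
        in_pulse = tr.time >= stabilization_ms
        return float(tr.voltage["soma"][in_pulse].min())

    # bracket: grow the amplitude until the peak overshoots the target
    hi_amp, hi_peak = 0.0, peak_for(0.0)
    if hi_peak <= target_peak:
        raise RuntimeError("resting trajectory already below target peak")
    lo_amp = -100.0
    while True:
        lo_peak = peak_for(lo_amp)
        if abs(lo_peak - target_peak) <= tolerance:
            return lo_amp
        if lo_peak < target_peak:
            break
        hi_amp, hi_peak = lo_amp, lo_peak
        lo_amp *= 2.0
        if lo_amp < bracket_max_pA:
            raise RuntimeError(
                f"target peak {target_peak} mV not bracketable above {bracket_max_pA} pA"
            )
    for _ in range(40):
        mid = 0.5 * (lo_amp + hi_amp)
        p = peak_for(mid)
        if abs(p - target_peak) <= tolerance:
            return mid
        if p < target_peak:
            lo_amp = mid
        else:
            hi_amp = mid
    raise RuntimeError("bisection failed to converge")


def run_rebound(
    model: ModelInstance,
    amplitude_pA: float,
    cfg: Optional[SimConfig] = None,
    stabilization_ms: float = 3000.0,
    pulse_ms: float = 1000.0,
    post_ms: float = 4000.0,
) -> TraceSet:
    """Hyperpolarizing-pulse protocol: stabilized pacemaking, a 1-s pulse of
    the given amplitude, then a post-pulse window for the rebound spike."""
    cfg = cfg or SimConfig()
    sub = replace(cfg, duration=stabilization_ms + pulse_ms + post_ms)
    stim = StimulusProtocol(segments=((stabilization_ms, pulse_ms, amplitude_pA),))
    tr = integrate(model, stim, sub)
    tr.meta["pulse_offset_ms"] = stabilization_ms + pulse_ms
    tr.meta["pulse_onset_ms"] = stabilization_ms
    tr.meta["pulse_amplitude_pA"] = amplitude_pA
    return tr
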