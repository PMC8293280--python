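"""Voltage-gated channel kinetics for the SNc dopaminergic neuron model.

Six active conductances (fast sodium I_Na, delayed-rectifier potassium I_KDR,
A-type potassium I_A, hyperpolarization-activated cation I_H, L-type calcium
I_CaL and SK calcium-gated potassium I_SK) plus an ohmic leak.  Gating follows
first-order Hodgkin-Huxley kinetics

    I(V, t) = gmax * m(V, t)^a * h(V, t)^b * (V - E_rev)
    dm/dt   = (m_inf(V) - m) / tau_m(V)

with Boltzmann steady states ``m_inf(V) = 1 / (1 + exp(-(V - V50)/k))``.  SK is
purely calcium-gated through a fourth-order Hill function of intracellular
calcium.  The sign convention is outward-positive for all membrane currents.

The numerical constants (Boltzmann parameters, time-constant closed forms,
region-specific maximal conductance densities) live in one machine-readable
defaults file, ``data/channels.json``, so that any single value can be audited
or corrected in one place.

Two parameter couplings specific to the A-type current are exposed here:

* kinetics link: activation is 50x faster than inactivation
  (``tau_m = tau_h / 50``) and activation V50 sits 50 mV above inactivation V50;
* voltage-dependence coupling to I_H: ``V50_inact(I_A) = 0.814 * V50_act(I_H)
  + 3.36`` (mV), so the two currents' voltage dependences co-vary.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict

import numpy as np

__all__ = [
    "GateSpec",
    "TimeConstantRule",
    "ChannelSpec",
    "IAKineticsLink",
    "V50Coupling",
    "RegionDensities",
    "steady_state",
    "time_constant",
    "coupled_ia_params",
    "sk_open_fraction",
    "gate_step",
    "channel_current_density",
    "load_channel_defaults",
    "SK_HILL_K",
    "SK_HILL_N",
]

#: Half-activation calcium concentration (mM) and Hill exponent of the SK current.
SK_HILL_K = 0.00019
SK_HILL_N = 4

REGIONS = ("soma_dend", "AIS", "axon")


@dataclass(frozen=True)
class GateSpec:
    """Boltzmann voltage dependence of one activation/inactivation gate.

    ``exponent == 0`` encodes an absent gate (its factor in the current is 1).
    ``slope_k`` is signed: positive for activation-type (opening with
    depolarization), negative for inactivation-type gates.
    """

    v50: float  # mV
    slope_k: float  # mV, signed
    exponent: int  # a or b

    def __post_init__(self) -> None:
        if self.slope_k == 0:
            raise ValueError("gate slope factor must be nonzero")
        if self.exponent < 0 or int(self.exponent) != self.exponent:
            raise ValueError("gate exponent must be a nonnegative integer")


@dataclass(frozen=True)
class TimeConstantRule:
    """A named closed-form rule for a gate time constant (ms).

    Recognized ``rule_id`` values: ``constant`` (params: value), ``na_m``,
    ``na_h``, ``kdr_m``, ``h_m``, ``cal_m`` (no params; printed closed forms)
    and ``ia_linked`` (params: tau_h; evaluates to tau_h / 50).
    """

    rule_id: str
    params: Dict[str, float] = field(default_factory=dict)

    KNOWN = frozenset({"constant", "na_m", "na_h", "kdr_m", "h_m", "cal_m", "ia_linked"})

    def __post_init__(self) -> None:
        if self.rule_id not in self.KNOWN:
            raise ValueError(f"unknown time-constant rule {self.rule_id!r}")


@dataclass(frozen=True)
class ChannelSpec:
    """One voltage-gated conductance: gates, reversal and time-constant rules."""

    name: str
    m_gate: GateSpec
    h_gate: GateSpec
    e_rev: float  # mV
    tau_m: TimeConstantRule
    tau_h: TimeConstantRule


@dataclass(frozen=True)
class IAKineticsLink:
    """Coupling of I_A activation to inactivation: rate ratio and V50 shift."""

    tau_ratio: float = 50.0  # tau_m = tau_h / tau_ratio
    v50_shift: float = 50.0  # v50_act = v50_inact + v50_shift (mV)


@dataclass(frozen=True)
class V50Coupling:
    """Linear coupling of I_A inactivation V50 to I_H activation V50 (mV)."""

    slope: float = 0.814
    intercept: float = 3.36

    def __call__(self, v50_h_act: float) -> float:
        return self.slope * v50_h_act + self.intercept


@dataclass(frozen=True)
class RegionDensities:
    """Per-channel maximal conductance densities (pS/um^2) by region.

    Keys of ``gmax``: channel name -> {soma_dend, AIS, axon}.  The AIS and
    axon carry only Na and KDR (plus leak); all other channels are zero there.
    """

    gmax: Dict[str, Dict[str, float]]

    def __post_init__(self) -> None:
        for chan, per_region in self.gmax.items():
            for region, g in per_region.items():
                if region not in REGIONS:
                    raise ValueError(f"unknown region {region!r} for channel {chan}")
                if g < 0:
                    raise ValueError(f"negative gmax for {chan}/{region}")
            if chan not in ("Na", "KDR", "leak"):
                for region in ("AIS", "axon"):
                    if per_region.get(region, 0.0) != 0.0:
                        raise ValueError(
                            f"channel {chan} must have zero density in {region}"
                        )

    def get(self, channel: str, region: str) -> float:
        return self.gmax[channel][region]


def steady_state(v, gate: GateSpec):
    """Boltzmann steady-state open fraction ``1/(1 + exp(-(v - v50)/k))``.

    Monotone increasing in ``v`` for ``k > 0``, decreasing for ``k < 0``;
    bounded in [0, 1].  Accepts scalars or arrays; rejects non-finite input.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential must be finite")
    if gate.exponent == 0:
        return np.ones_like(v)[()] if v.ndim else 1.0
    out = 1.0 / (1.0 + np.exp(-(v - gate.v50) / gate.slope_k))
    return out[()] if out.ndim == 0 else out


def time_constant(v, rule: TimeConstantRule):
    """Evaluate a time-constant rule at membrane potential ``v`` (ms).

    Implements the model's printed closed forms; strictly positive on
    [-150, +60] mV for every recognized rule.
    """
    v = np.asarray(v, dtype=float)
    rid = rule.rule_id
    if rid == "constant":
        out = np.full_like(v, float(rule.params["value"]))
    elif rid == "ia_linked":
        tau_h = float(rule.params["tau_h"])
        if tau_h <= 0:
            raise ValueError("tau_h must be positive")
        out = np.full_like(v, tau_h / 50.0)
    elif rid == "na_m":
        out = 0.01 + 0.33 / (1.0 + ((v + 20.0) / 30.0) ** 2)
    elif rid == "na_h":
        out = 0.7 + 16.0 / (1.0 + ((v + 50.0) / 8.0) ** 2)
    elif rid == "kdr_m":
        out = 4.0 * np.exp(-0.000729 * (v + 32.0) ** 2) + 4.0
    elif rid == "h_m":
        out = 556.0 + 1100.0 * np.exp(-0.5 * (v / 11.06) ** 2)
    elif rid == "cal_m":
        out = _tau_cal(v)
    else:  # pragma: no cover - guarded by TimeConstantRule
        raise ValueError(f"unknown time-constant rule {rid!r}")
    return out[()] if out.ndim == 0 else out


def _tau_cal(v: np.ndarray) -> np.ndarray:
    # alpha-like term has a removable singularity at v = -39.26 with limit
    # 0.209 * 4.111 (l'Hopital); evaluate it safely.
    x = v + 39.26
    with np.errstate(over="ignore"):
        denom = np.expm1(-x / 4.111)
    near = np.abs(x) < 1e-9
    safe = np.where(near, 1.0, denom)
    alpha = np.where(near, 0.209 * 4.111, -0.209 * x / safe)
    beta = 0.944 * np.exp(-(v + 15.38) / 224.1)
    return 1.0 / (alpha + beta)


def coupled_ia_params(
    v50_h_act: float,
    link: IAKineticsLink | None = None,
    coupling: V50Coupling | None = None,
    tau_h: float = 82.5,
) -> Dict[str, float]:
    """Derive the coupled I_A gating parameters from the I_H activation V50.

    Returns a dict with ``v50_inact``, ``v50_act`` (mV), ``tau_m`` and
    ``tau_h`` (ms).  Values of ``v50_h_act`` outside the model's [-100, -80]
    mV grid are allowed but trigger an extrapolation warning.
    """
    link = link or IAKineticsLink()
    coupling = coupling or V50Coupling()
    if tau_h <= 0:
        raise ValueError("tau_h must be positive")
    if not -100.0 <= v50_h_act <= -80.0:
        warnings.warn(
            f"I_H activation V50 {v50_h_act} mV outside the [-100, -80] mV grid",
            stacklevel=2,
        )
    v50_inact = coupling(v50_h_act)
    return {
        "v50_inact": v50_inact,
        "v50_act": v50_inact + link.v50_shift,
        "tau_m": tau_h / link.tau_ratio,
        "tau_h": tau_h,
    }


def sk_open_fraction(ca_i):
    """SK open fraction: Hill function ``ca^4 / (ca^4 + K^4)``, K = 0.19 uM."""
    ca = np.asarray(ca_i, dtype=float)
    if np.any(ca < 0):
        raise ValueError("calcium concentration must be nonnegative")
    c4 = ca**SK_HILL_N
    out = c4 / (c4 + SK_HILL_K**SK_HILL_N)
    return out[()] if out.ndim == 0 else out


def gate_step(m, v, gate: GateSpec, tau_rule: TimeConstantRule, dt: float):
    """Advance a gate by the exact exponential update at frozen voltage.

    ``m' = m_inf(v) + (m - m_inf(v)) * exp(-dt / tau(v))`` -- the analytic
    solution of the first-order gate ODE over one step of constant ``v``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    m = np.asarray(m, dtype=float)
    if np.any((m < 0) | (m > 1)):
        raise ValueError("gate state must lie in [0, 1]")
    m_inf = steady_state(v, gate)
    tau = time_constant(v, tau_rule)
    out = m_inf + (m - m_inf) * np.exp(-dt / tau)
    return out[()] if out.ndim == 0 else out


def channel_current_density(v, m, h, spec: ChannelSpec, gmax: float):
    """Ohmic current density ``gmax * m^a * h^b * (v - e_rev)``, outward positive.

    Units follow ``gmax``: with gmax in pS/um^2 and v in mV the result is in
    pS/um^2 * mV = 1e-5 mA/cm^2.
    """
    m = np.asarray(m, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any((m < 0) | (m > 1)) or np.any((h < 0) | (h > 1)):
        raise ValueError("gate states must lie in [0, 1]")
    out = (
        gmax
        * m ** spec.m_gate.exponent
        * h ** spec.h_gate.exponent
        * (np.asarray(v, dtype=float) - spec.e_rev)
    )
    return out[()] if np.ndim(out) == 0 else out


def _gate_from_json(d: dict) -> GateSpec:
    return GateSpec(v50=d["v50"], slope_k=d["slope_k"], exponent=d["exponent"])


def load_channel_defaults() -> dict:
    """Load the model's channel/passive/calcium defaults.

    Returns a dict with keys ``channels`` (name -> ChannelSpec for the gated
    channels), ``densities`` (RegionDensities over all seven conductances),
    ``raw`` (the parsed JSON), plus ``passive`` and ``calcium`` sub-dicts.
    """
    raw = json.loads(
        resources.files("kv4pace.data").joinpath("channels.json").read_text()
    )
    chans: Dict[str, ChannelSpec] = {}
    gmax: Dict[str, Dict[str, float]] = {}
    for name, cd in raw["channels"].items():
        gmax[name] = dict(cd["gmax"])
        if name in ("SK", "leak"):
            continue
        chans[name] = ChannelSpec(
            name=name,
            m_gate=_gate_from_json(cd["m_gate"]),
            h_gate=_gate_from_json(cd["h_gate"]),
            e_rev=cd["e_rev"],
            tau_m=TimeConstantRule(cd["tau_m"]["rule_id"], dict(cd["tau_m"]["params"])),
            tau_h=TimeConstantRule(cd["tau_h"]["rule_id"], dict(cd["tau_h"]["params"])),
        )
    return {
        "channels": chans,
        "densities": RegionDensities(gmax=gmax),
        "passive": raw["passive"],
        "calcium": raw["calcium"],
        "raw": raw,
    }
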