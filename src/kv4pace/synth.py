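"""Synthetic data generators.

Everything the analysis pipeline consumes can be generated here without any
recordings: per-neuron biophysics/feature populations for the two genotypes
(wild type and Kv4.3 knock-out), voltage-clamp transient-current trace
families with Boltzmann inactivation and near-mono-exponential decay, and
2x2 immunopositivity count tables.

Population model
----------------
Biophysical variables are drawn from a Gaussian copula: positive, skewed
quantities (ISI, rebound delay, I_A tau, I_A and I_H amplitudes) get
log-normal marginals whose (median, IQR) match the study targets exactly
(median = e^mu, IQR = 2 e^mu sinh(0.6745 sigma)); half-(in)activation
voltages get normal marginals.  The latent correlation couples the I_A
inactivation V50 to the I_H activation V50 (r = 0.658) and log I_A tau
negatively to log I_H amplitude (default r = -0.4).

The firing features (ISI, rebound delay) are generated *from* the biophysics:
the log-feature is a linear combination of the standardized latent biophysical
variables plus Gaussian noise, scaled so the feature's own log-normal
(median, IQR) target is met exactly.  Every generator returns a truth record
carrying all generating parameters, sufficient to score downstream recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "MarginalTarget",
    "PopulationSpec",
    "VCTraceSpec",
    "TABLE_TARGETS",
    "sample_population",
    "generate_vc_family",
    "generate_count_table",
    "boltzmann",
]

BIOPHYS_VARS = ("ia_tau", "ih_amplitude", "ia_amplitude", "v50_a_inact", "v50_h_act")
FEATURE_VARS = ("isi", "rebound_delay")


@dataclass(frozen=True)
class MarginalTarget:
    """Location/scale target for one variable.

    For a log-normal marginal, ``location`` is the median and ``scale`` the
    interquartile range; for a normal marginal they are mean and SD.
    """

    location: float
    scale: float
    family: str = "lognormal"  # or "normal"

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.family not in ("lognormal", "normal"):
            raise ValueError(f"unknown marginal family {self.family!r}")

    @property
    def log_params(self) -> Tuple[float, float]:
        """(mu, sigma) of the underlying normal."""
        if self.family == "normal":
            return self.location, self.scale
        mu = math.log(self.location)
        sigma = math.asinh(self.scale / (2.0 * self.location)) / 0.674489750196082
        return mu, sigma


#: Per-genotype targets: medians/IQRs (log-normal) and means/SDs (normal) of
#: the recorded electrophysiological parameters.
TABLE_TARGETS: Dict[str, Dict[str, MarginalTarget]] = {
    "WT": {
        "isi": MarginalTarget(669.5, 334.5),  # ms
        "rebound_delay": MarginalTarget(256.0, 199.0),  # ms
        "ia_tau": MarginalTarget(30.9, 27.15),  # ms
        "ia_amplitude": MarginalTarget(2.14, 2.79),  # nA
        "ih_amplitude": MarginalTarget(453.0, 212.5),  # pA
        "v50_a_inact": MarginalTarget(-68.91, 5.10, "normal"),  # mV
        "v50_h_act": MarginalTarget(-88.41, 4.24, "normal"),  # mV
    },
    "KO": {
        "isi": MarginalTarget(304.0, 118.0),
        "rebound_delay": MarginalTarget(29.0, 18.0),
        "ia_tau": MarginalTarget(12.9, 6.72),
        "ia_amplitude": MarginalTarget(0.93, 0.64),
        "ih_amplitude": MarginalTarget(575.3, 275.8),
        "v50_a_inact": MarginalTarget(-73.31, 3.84, "normal"),
        "v50_h_act": MarginalTarget(-88.42, 3.81, "normal"),
    },
}


@dataclass(frozen=True)
class PopulationSpec:
    """Synthetic per-neuron population definition."""

    genotype: str = "WT"
    n: int = 100
    seed: int = 0
    targets: Optional[Dict[str, MarginalTarget]] = None  # defaults per genotype
    corr_v50: float = 0.658  # latent corr(v50_a_inact, v50_h_act)
    corr_tau_ih: float = -0.4  # latent corr(log ia_tau, log ih_amplitude)
    # relative weights of the standardized biophysical variables in each
    # log-feature; rescaled so each feature meets its own (median, IQR) target
    feature_weights: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "isi": {"ia_tau": 1.0, "ih_amplitude": -0.5},
            "rebound_delay": {"ia_tau": 1.0, "ih_amplitude": -0.5, "v50_a_inact": 0.5},
        }
    )
    noise_variance_fraction: float = 0.4  # share of log-feature variance from noise

    def resolved_targets(self) -> Dict[str, MarginalTarget]:
        if self.targets is not None:
            return self.targets
        if self.genotype not in TABLE_TARGETS:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        return TABLE_TARGETS[self.genotype]


def _latent_correlation(spec: PopulationSpec) -> np.ndarray:
    k = len(BIOPHYS_VARS)
    R = np.eye(k)
    i_tau = BIOPHYS_VARS.index("ia_tau")
    i_ih = BIOPHYS_VARS.index("ih_amplitude")
    i_va = BIOPHYS_VARS.index("v50_a_inact")
    i_vh = BIOPHYS_VARS.index("v50_h_act")
    R[i_tau, i_ih] = R[i_ih, i_tau] = spec.corr_tau_ih
    R[i_va, i_vh] = R[i_vh, i_va] = spec.corr_v50
    eigvals = np.linalg.eigvalsh(R)
    if eigvals.min() <= 0:
        raise ValueError("correlation target matrix is not positive definite")
    return R


def sample_population(spec: PopulationSpec) -> Tuple[pd.DataFrame, dict]:
    """Draw a per-neuron table and its generating truth record.

    Returns (table, truth): the table has one row per neuron with the five
    biophysical variables and the two firing features; the truth record
    carries the latent correlation matrix, marginal parameters and the exact
    log-feature coefficients (so a noise-free draw can be refitted exactly).
    """
    targets = spec.resolved_targets()
    R = _latent_correlation(spec)
    rng = np.random.default_rng(spec.seed)
    L = np.linalg.cholesky(R)
    z = rng.standard_normal((spec.n, len(BIOPHYS_VARS))) @ L.T

    table = pd.DataFrame({"genotype": [spec.genotype] * spec.n})
    for j, name in enumerate(BIOPHYS_VARS):
        mu, sigma = targets[name].log_params
        x = mu + sigma * z[:, j]
        table[name] = np.exp(x) if targets[name].family == "lognormal" else x

    coefficients: Dict[str, Dict[str, float]] = {}
    noise_sd: Dict[str, float] = {}
    for feat in FEATURE_VARS:
        mu_f, sigma_f = targets[feat].log_params
        w = np.array([spec.feature_weights[feat].get(v, 0.0) for v in BIOPHYS_VARS])
        var_signal = float(w @ R @ w)
        if var_signal == 0:
            raise ValueError(f"feature {feat} has no generating weights")
        f_noise = spec.noise_variance_fraction
        scale = sigma_f * math.sqrt((1.0 - f_noise) / var_signal)
        b = scale * w
        sd_eps = sigma_f * math.sqrt(f_noise)
        log_feat = mu_f + z @ b + sd_eps * rng.standard_normal(spec.n)
        table[feat] = np.exp(log_feat)
        coefficients[feat] = {
            v: float(bj) for v, bj in zip(BIOPHYS_VARS, b) if bj != 0.0
        }
        noise_sd[feat] = sd_eps
    truth = {
        "genotype": spec.genotype,
        "n": spec.n,
        "seed": spec.seed,
        "latent_correlation": R,
        "marginals": {k: v.log_params for k, v in targets.items()},
        "coefficients": coefficients,
        "noise_sd_log": noise_sd,
    }
    return table, truth


def boltzmann(v: np.ndarray, v50: float, k: float) -> np.ndarray:
    """Steady-state Boltzmann ``1/(1 + exp(-(v - v50)/k))``."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, float) - v50) / k))


@dataclass(frozen=True)
class VCTraceSpec:
    """Voltage-clamp transient-current family parameters.

    Emulates the I_A isolation protocol: a 500-ms prestep at graded voltages
    followed by a step to -40 mV; the isolated current rises with tau_m and
    decays with tau_h, scaled by the Boltzmann availability at the prestep.
    """

    amplitude: float = 2.14  # nA, fully available peak-scale current
    tau_m: float = 0.618  # ms (activation; tau_h / 50)
    tau_h: float = 30.9  # ms (inactivation)
    baseline: float = 0.0  # pA
    noise_sd: float = 0.0  # pA
    dt: float = 0.1  # ms
    duration: float = 500.0  # ms
    prestep_voltages: Tuple[float, ...] = (-110.0, -100.0, -90.0, -80.0, -70.0,
                                           -60.0, -50.0, -40.0, -30.0)

    def __post_init__(self) -> None:
        if not self.tau_m < self.tau_h:
            raise ValueError("tau_m must be smaller than tau_h")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def generate_vc_family(
    spec: VCTraceSpec,
    v50_inact: float = -68.91,
    slope: float = -6.0,
    seed: int = 0,
) -> Tuple[List[Tuple[float, np.ndarray, np.ndarray]], dict]:
    """Generate a voltage-clamp family ``I(t) = A h_inf(prestep) (1 -
    exp(-t/tau_m)) exp(-t/tau_h) + baseline + noise`` (pA) per prestep.

    Returns ([(prestep_mV, t_ms, i_pA), ...], truth record).
    """
    if len(spec.prestep_voltages) < 5:
        raise ValueError("at least 5 prestep voltages required")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, spec.duration + spec.dt / 2, spec.dt)
    shape = (1.0 - np.exp(-t / spec.tau_m)) * np.exp(-t / spec.tau_h)
    family = []
    for v_pre in spec.prestep_voltages:
        h = float(boltzmann(v_pre, v50_inact, slope))
        i = spec.amplitude * 1000.0 * h * shape + spec.baseline
        if spec.noise_sd > 0:
            i = i + spec.noise_sd * rng.standard_normal(t.size)
        family.append((float(v_pre), t.copy(), i))
    truth = {
        "amplitude_nA": spec.amplitude,
        "tau_m_ms": spec.tau_m,
        "tau_h_ms": spec.tau_h,
        "v50_inact_mV": v50_inact,
        "slope_mV": slope,
        "baseline_pA": spec.baseline,
        "noise_sd_pA": spec.noise_sd,
        "seed": seed,
    }
    return family, truth


def generate_count_table(
    p1: float, n1: int, p2: float, n2: int, seed: int = 0
) -> np.ndarray:
    """Binomial 2x2 count table ``[[pos1, neg1], [pos2, neg2]]``.

    Defaults of interest: immunopositive proportions ~0.047 of 423 (WT) and
    ~0.05 of 382 (knock-out) cells.
    """
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("proportions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    a = int(rng.binomial(n1, p1))
    c = int(rng.binomial(n2, p2))
    return np.array([[a, n1 - a], [c, n2 - c]], dtype=int)
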