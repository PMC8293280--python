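"""Current- and voltage-clamp feature extraction.

Works on any uniformly sampled trace (simulated, synthetic or imported CSV).

Current-clamp features: spike detection (dV/dt criterion, spike time = AP peak
time), interspike-interval statistics (mean ISI and CV; CV uses the population
standard deviation, divide-by-n), postinhibitory rebound delay (stimulus
offset to first AP peak), AP waveform features (threshold, amplitude,
half-width, AHP trough and latency, rise/decay slopes), hyperpolarization sag
and excitability (gain start/end, spike-frequency adaptation).

Voltage-clamp features: I_A isolation by prestep subtraction, Boltzmann fit of
the inactivation curve, mono-exponential decay fit, 500-ms charge integral,
I_H two-step amplitude and activation V50, and I_KDR current-voltage curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SpikeTrain",
    "ISIStats",
    "APWaveformFeatures",
    "ExcitabilityFeatures",
    "detect_spikes",
    "isi_stats",
    "rebound_delay",
    "ap_features",
    "sag_amplitude",
    "excitability",
    "isolate_ia",
    "fit_boltzmann_inactivation",
    "fit_monoexp_decay",
    "integrate_charge",
    "ih_features",
    "ikdr_iv",
    "FitQualityWarning",
]

#: default spike-detection criterion: upward dV/dt crossing (mV/ms) + refractory (ms)
DVDT_CRITERION = 10.0
REFRACTORY_MS = 2.0
PEAK_SEARCH_MS = 10.0


class FitQualityWarning(UserWarning):
    """A curve fit converged but its quality criterion failed."""


@dataclass
class SpikeTrain:
    """Detected spikes: peak times (ms, strictly increasing) plus metadata."""

    times: np.ndarray  # spike (peak) times, ms
    threshold_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    threshold_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    criterion: float = DVDT_CRITERION

    def __post_init__(self) -> None:
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.times.size)


def _dvdt(time: np.ndarray, v: np.ndarray) -> np.ndarray:
    return np.gradient(v, time)


def detect_spikes(
    time: np.ndarray,
    v: np.ndarray,
    criterion: float = DVDT_CRITERION,
    refractory_ms: float = REFRACTORY_MS,
    min_amplitude: float = 20.0,
) -> SpikeTrain:
    """Detect action potentials from a uniformly sampled voltage trace.

    A spike is an upward crossing of dV/dt through ``criterion`` (mV/ms); the
    spike time is the subsequent voltage peak (searched over the next
    ~10 ms); crossings within the refractory period of the previous one are
    ignored, as are candidates rising less than ``min_amplitude`` mV above
    the crossing voltage (this rejects fast passive transients such as the
    release from a hyperpolarizing step).  Deterministic; an empty train is a
    valid result.
    """
    time = np.asarray(time, float)
    v = np.asarray(v, float)
    dv = _dvdt(time, v)
    above = dv >= criterion
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    dt = time[1] - time[0]
    w = max(1, int(round(PEAK_SEARCH_MS / dt)))
    peaks, th_t, th_v = [], [], []
    last = -np.inf
    for ci in crossings:
        if time[ci] - last < refractory_ms:
            continue
        seg = v[ci : ci + w]
        pi = ci + int(np.argmax(seg))
        if v[pi] - v[ci] < min_amplitude:
            continue
        if pi >= ci + seg.size - 1 and pi + 1 < v.size and v[pi + 1] >= v[pi]:
            continue  # still rising at the search-window edge: not an AP peak
        if peaks and time[pi] <= peaks[-1]:
            continue  # second criterion crossing within the same AP
        peaks.append(time[pi])
        th_t.append(time[ci])
        th_v.append(v[ci])
        last = time[ci]
    return SpikeTrain(
        times=np.array(peaks),
        threshold_times=np.array(th_t),
        threshold_values=np.array(th_v),
        criterion=criterion,
    )


@dataclass(frozen=True)
class ISIStats:
    mean_isi: float  # ms
    cv_percent: float
    n_isi: int
    valid: bool


def isi_stats(
    train: SpikeTrain, analysis_window: Optional[Tuple[float, float]] = None
) -> ISIStats:
    """Mean ISI (ms) and its coefficient of variation (%).

    CV = sample SD / mean * 100 (SD divides by n-1; e.g. ISIs {100, 200} give
    CV = 70.71/150 = 47.14%).  Needs at least 3 spikes in the window,
    otherwise a flagged undefined result.
    """
    t = train.times
    if analysis_window is not None:
        lo, hi = analysis_window
        t = t[(t >= lo) & (t <= hi)]
    if t.size < 3:
        return ISIStats(np.nan, np.nan, max(0, t.size - 1), False)
    isis = np.diff(t)
    mean = float(isis.mean())
    cv = float(isis.std(ddof=1) / mean * 100.0)
    return ISIStats(mean, cv, isis.size, True)


def rebound_delay(
    time: np.ndarray,
    v: np.ndarray,
    pulse_offset_ms: float,
    window_ms: float = 5000.0,
    criterion: float = DVDT_CRITERION,
) -> float:
    """Time (ms) from stimulus offset to the first AP peak after offset.

    Returns ``nan`` (censored) when no spike occurs within the window.
    """
    train = detect_spikes(time, v, criterion=criterion)
    after = train.times[(train.times >= pulse_offset_ms) & (train.times <= pulse_offset_ms + window_ms)]
    if after.size == 0:
        return np.nan
    return float(after[0] - pulse_offset_ms)


@dataclass(frozen=True)
class APWaveformFeatures:
    threshold: float  # mV
    amplitude: float  # mV
    half_width: float  # ms
    ahp_trough: float  # mV
    ahp_latency: float  # ms
    rise_slope: float  # mV/ms
    decay_slope: float  # mV/ms
    n_spikes: int


def ap_features(
    time: np.ndarray, v: np.ndarray, train: Optional[SpikeTrain] = None
) -> APWaveformFeatures:
    """Average AP waveform features over all complete spikes in a trace.

    Threshold = voltage at the dV/dt criterion crossing; amplitude = peak -
    threshold; half-width measured at (threshold + peak)/2; AHP trough = the
    voltage minimum between a peak and the next threshold crossing (or trace
    end); spikes truncated by the trace edges are skipped.
    """
    time = np.asarray(time, float)
    v = np.asarray(v, float)
    if train is None:
        train = detect_spikes(time, v)
    if train.n < 1:
        raise ValueError("at least one spike required")
    dt = time[1] - time[0]
    feats = []
    for k in range(train.n):
        ti = int(round((train.threshold_times[k] - time[0]) / dt))
        pi = int(round((train.times[k] - time[0]) / dt))
        next_th = (
            int(round((train.threshold_times[k + 1] - time[0]) / dt))
            if k + 1 < train.n
            else time.size - 1
        )
        if pi >= time.size - 2 or ti <= 0 or next_th <= pi + 1:
            continue
        thr = v[ti]
        peak = v[pi]
        half = 0.5 * (thr + peak)
        # half-width: crossings of the half level around the peak
        up = pi
        while up > ti and v[up] > half:
            up -= 1
        down = pi
        while down < next_th and v[down] > half:
            down += 1
        if v[up] > half or v[down] > half:
            continue  # truncated waveform
        t_up = np.interp(half, [v[up], v[up + 1]], [time[up], time[up + 1]])
        t_dn = np.interp(half, [v[down], v[down - 1]], [time[down], time[down - 1]])
        trough_i = pi + int(np.argmin(v[pi:next_th + 1]))
        dv = _dvdt(time, v)
        feats.append(
            (
                thr,
                peak - thr,
                t_dn - t_up,
                v[trough_i],
                time[trough_i] - time[pi],
                float(dv[ti:pi + 1].max()),
                float(dv[pi:trough_i + 1].min()) if trough_i > pi else np.nan,
            )
        )
    if not feats:
        raise ValueError("no complete spike waveform in trace")
    arr = np.array(feats)
    mean = np.nanmean(arr, axis=0)
    return APWaveformFeatures(*mean, n_spikes=len(feats))


def sag_amplitude(
    time: np.ndarray, v: np.ndarray, pulse_window: Tuple[float, float]
) -> float:
    """Sag (mV): peak hyperpolarization minus the mean voltage over the last
    10% of a hyperpolarizing pulse; positive by construction."""
    t0, t1 = pulse_window
    time = np.asarray(time, float)
    v = np.asarray(v, float)
    sel = (time >= t0) & (time <= t1)
    if not sel.any():
        raise ValueError("pulse window outside trace")
    v_pulse = v[sel]
    t_pulse = time[sel]
    pre = v[time < t0]
    v_ref = pre[-1] if pre.size else v_pulse[0]
    if v_pulse.min() >= v_ref:
        raise ValueError("sag requires a hyperpolarizing pulse")
    plateau = v_pulse[t_pulse >= t1 - 0.1 * (t1 - t0)].mean()
    return float(plateau - v_pulse.min())


@dataclass(frozen=True)
class ExcitabilityFeatures:
    start_frequency_100pA: float  # Hz
    gain_start: float  # Hz per 100 pA
    gain_end: float  # Hz per 100 pA
    sfa_index: float
    valid: bool


def excitability(responses: Sequence[Tuple[float, SpikeTrain]]) -> ExcitabilityFeatures:
    """Excitability features from graded depolarizing steps.

    ``responses`` is a sequence of (step amplitude pA, SpikeTrain) pairs.
    Start frequency = 1/first ISI, end frequency = 1/mean of the last two
    ISIs; the gains are the least-squares slopes of these frequencies against
    amplitude (per 100 pA); the SFA index is start/end frequency at the
    largest step with at least 3 ISIs.
    """
    amps, f_start, f_end = [], [], []
    for amp, train in sorted(responses, key=lambda r: r[0]):
        if train.n < 2:
            continue
        isis = np.diff(train.times)
        fs = 1000.0 / isis[0]
        fe = 1000.0 / isis[-2:].mean()
        amps.append(amp)
        f_start.append(fs)
        f_end.append(fe)
    if len(amps) < 2:
        return ExcitabilityFeatures(np.nan, np.nan, np.nan, np.nan, False)
    amps_a = np.array(amps)
    gain_s = float(np.polyfit(amps_a, f_start, 1)[0] * 100.0)
    gain_e = float(np.polyfit(amps_a, f_end, 1)[0] * 100.0)
    sfa = f_start[-1] / f_end[-1]
    start_100 = (
        float(f_start[int(np.argmin(np.abs(amps_a - 100.0)))])
        if np.any(np.abs(amps_a - 100.0) < 1e-9)
        else float(np.interp(100.0, amps_a, f_start))
    )
    return ExcitabilityFeatures(start_100, gain_s, gain_e, float(sfa), True)


# ---------------------------------------------------------------------------
# voltage clamp
# ---------------------------------------------------------------------------

def isolate_ia(
    time: np.ndarray,
    i_prestep_minus100: np.ndarray,
    i_prestep_minus40: np.ndarray,
    baseline_frac: float = 0.1,
) -> np.ndarray:
    """Isolate I_A by subtracting the fully inactivated (-40 mV prestep)
    trace, then removing the residual baseline (mean of the last fraction of
    the difference, where the transient has decayed)."""
    time = np.asarray(time, float)
    a = np.asarray(i_prestep_minus100, float)
    b = np.asarray(i_prestep_minus40, float)
    if a.shape != b.shape or a.shape != time.shape:
        raise ValueError("traces must share one time base")
    diff = a - b
    ntail = max(1, int(round(baseline_frac * diff.size)))
    return diff - diff[-ntail:].mean()


def _boltzmann(v, a, v50, k):
    return a / (1.0 + np.exp(-(v - v50) / k))


def fit_boltzmann_inactivation(
    peak_currents: np.ndarray, prestep_voltages: np.ndarray
) -> Tuple[float, float]:
    """Least-squares Boltzmann fit of an inactivation curve.

    Returns (V50, slope k) in mV; k is negative for inactivation.  Emits a
    :class:`FitQualityWarning` when the data do not span the transition
    (unidentifiable) or are non-monotonic beyond a 10% noise tolerance.
    """
    y = np.asarray(peak_currents, float)
    v = np.asarray(prestep_voltages, float)
    if y.size < 5:
        raise ValueError("at least 5 prestep voltages required")
    order = np.argsort(v)
    v, y = v[order], y[order]
    ymax = np.abs(y).max()
    if ymax == 0 or (y.max() - y.min()) < 0.3 * ymax:
        warnings.warn("inactivation curve does not span its transition", FitQualityWarning)
    drops = np.diff(y)
    if np.any(drops > 0.1 * ymax):  # should be non-increasing with voltage
        warnings.warn("non-monotonic inactivation data", FitQualityWarning)
    v50_guess = float(np.interp(0.5 * y.max(), y[::-1], v[::-1]))
    p0 = (float(y.max()), v50_guess, -6.0)
    popt, _ = curve_fit(_boltzmann, v, y, p0=p0, maxfev=10000)
    _, v50, k = popt
    if not v.min() - 10 <= v50 <= v.max() + 10:
        warnings.warn("fitted V50 outside the data range", FitQualityWarning)
    return float(v50), float(k)


def fit_monoexp_decay(
    time: np.ndarray,
    current: np.ndarray,
    residual_warn: float = 0.02,
) -> float:
    """Fit ``I(t) = A exp(-t/tau) + C`` to a decaying segment; returns tau (ms).

    Raises on a non-decaying segment; warns (:class:`FitQualityWarning`) when
    the relative RMS residual exceeds ``residual_warn`` of the fitted
    amplitude, the signature of a multi-exponential decay.
    """
    t = np.asarray(time, float)
    y = np.asarray(current, float)
    n5 = max(1, y.size // 20)
    if abs(y[:n5].mean()) <= abs(y[-n5:].mean()):
        raise ValueError("segment does not decay")
    t0 = t - t[0]
    c0 = y[-n5:].mean()
    a0 = y[0] - c0
    # log-linear tau estimate over the upper part of the decay
    z = (y - c0) / a0
    mask = z > 0.1
    tau0 = -1.0 / np.polyfit(t0[mask], np.log(z[mask]), 1)[0] if mask.sum() > 2 else (t0[-1] / 3)
    popt, _ = curve_fit(
        lambda tt, a, tau, c: a * np.exp(-tt / tau) + c,
        t0,
        y,
        p0=(a0, max(tau0, 1e-3), c0),
        maxfev=10000,
    )
    a, tau, c = popt
    if tau <= 0:
        raise ValueError("fitted tau is non-positive")
    resid = y - (a * np.exp(-t0 / tau) + c)
    if np.sqrt(np.mean(resid**2)) > residual_warn * abs(a):
        warnings.warn("decay deviates from a single exponential", FitQualityWarning)
    return float(tau)


def integrate_charge(
    time: np.ndarray,
    current: np.ndarray,
    window: Tuple[float, float],
    baseline: float = 0.0,
) -> float:
    """Trapezoidal charge integral (pA*s) of a baseline-subtracted current
    (pA) over a window (ms)."""
    t = np.asarray(time, float)
    y = np.asarray(current, float)
    t0, t1 = window
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
        raise ValueError("integration window exceeds trace")
    sel = (t >= t0) & (t <= t1)
    return float(np.trapezoid(y[sel] - baseline, t[sel]) / 1000.0)


@dataclass(frozen=True)
class VCFeaturesIH:
    amplitude: float  # pA, steady-state minus instantaneous at the deepest step
    v50_act: float  # mV
    slope: float  # mV


def ih_features(
    family: Sequence[Tuple[float, np.ndarray, np.ndarray]],
    instant_ms: float = 10.0,
    e_rev: float = -40.0,
) -> VCFeaturesIH:
    """I_H features from a hyperpolarizing two-step family.

    ``family`` holds (step voltage mV, time ms, current pA) per step.  The
    time-dependent amplitude at each step is the steady-state current (last
    10%) minus the instantaneous current (first ``instant_ms`` after onset);
    V50 comes from a Boltzmann fit of the normalized chord conductance
    (amplitude over driving force ``|v - e_rev|``) against step voltage.
    Requires at least 4 steps.
    """
    if len(family) < 4:
        raise ValueError("at least 4 steps required")
    volts, amps, conds = [], [], []
    for v_step, t, i in family:
        t = np.asarray(t, float)
        i = np.asarray(i, float)
        inst = i[t <= t[0] + instant_ms].mean()
        steady = i[t >= t[-1] - 0.1 * (t[-1] - t[0])].mean()
        amp = abs(steady - inst)
        volts.append(v_step)
        amps.append(amp)
        drive = abs(v_step - e_rev)
        conds.append(amp / drive if drive > 1e-9 else np.nan)
    volts_a = np.array(volts)
    amps_a = np.array(amps)
    conds_a = np.array(conds)
    amp_max = float(amps_a[int(np.argmin(volts_a))])
    if amps_a.max() == 0:
        return VCFeaturesIH(0.0, np.nan, np.nan)
    ok = np.isfinite(conds_a)
    norm = conds_a[ok] / np.nanmax(conds_a)
    p0 = (1.0, float(np.median(volts_a)), -7.0)
    popt, _ = curve_fit(_boltzmann, volts_a[ok], norm, p0=p0, maxfev=10000)
    return VCFeaturesIH(amp_max, float(popt[1]), float(popt[2]))


@dataclass(frozen=True)
class IVCurve:
    voltages: np.ndarray  # mV
    peak: np.ndarray  # pA
    steady: np.ndarray  # pA


def ikdr_iv(
    family: Sequence[Tuple[float, np.ndarray, np.ndarray]],
    late_frac: float = 0.1,
) -> IVCurve:
    """Per-step peak and late-window (steady-state) current of a delayed-
    rectifier step family with a -40 mV prestep."""
    volts, peaks, steadies = [], [], []
    for v_step, t, i in sorted(family, key=lambda s: s[0]):
        t = np.asarray(t, float)
        i = np.asarray(i, float)
        volts.append(v_step)
        peaks.append(float(i.max()))
        steadies.append(float(i[t >= t[-1] - late_frac * (t[-1] - t[0])].mean()))
    return IVCurve(np.array(volts), np.array(peaks), np.array(steadies))
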