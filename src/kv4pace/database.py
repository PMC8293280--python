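"""Biophysical parameter-database sweep and dimensional stacking.

The study design: four biophysical parameters of the A-type and H currents
(g_A, g_H, the coupled I_A/I_H half-(in)activation voltage via the I_H
activation V50, and the I_A inactivation time constant) are each given five
equidistributed values over a 10-fold range (20 mV for the voltage
dependence).  The 5^4 = 625 parameter combinations crossed with a morphology
population (22 cells -> 13,750 model specifications) are simulated; mean
post-stabilization ISI and calibrated-pulse rebound delay are measured per
model, averaged over morphologies per combination, and displayed as 25 x 25
dimensionally stacked heatmaps (two parameters nested inside the axes of the
other two, features log-transformed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .features import detect_spikes, isi_stats, rebound_delay
from .morphology import Morphology
from .simulator import (
    BiophysParamSet,
    CalciumModel,
    SimConfig,
    assemble_model,
    calibrate_hyperpolarizing_amplitude,
    integrate,
    run_rebound,
)

__all__ = [
    "PARAM_ORDER",
    "DEFAULT_RANGES",
    "ParameterGrid",
    "ModelSpec",
    "SweepConfig",
    "build_grid",
    "enumerate_models",
    "run_one",
    "run_sweep",
    "average_by_combination",
    "StackLayout",
    "dimensional_stack",
    "unstack",
]

PARAM_ORDER = ("g_A", "g_H", "v50_h_act", "tau_h_A")

DEFAULT_RANGES: Dict[str, Tuple[float, float]] = {
    "g_A": (15.0, 150.0),  # pS/um^2
    "g_H": (0.25, 2.5),  # pS/um^2
    "v50_h_act": (-100.0, -80.0),  # mV
    "tau_h_A": (15.0, 150.0),  # ms
}


@dataclass(frozen=True)
class ParameterGrid:
    """Per-parameter value lists (endpoints included)."""

    values: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, vals in self.values.items():
            if len(vals) < 2:
                raise ValueError(f"parameter {name} needs at least 2 values")

    @property
    def n_combinations(self) -> int:
        return int(np.prod([len(v) for v in self.values.values()]))

    def combinations(self):
        """Iterate (index tuple, parameter dict) lexicographically in the
        canonical parameter order."""
        names = [p for p in PARAM_ORDER if p in self.values]
        for idx in itertools.product(*(range(len(self.values[n])) for n in names)):
            yield idx, {n: float(self.values[n][i]) for n, i in zip(names, idx)}


def build_grid(
    ranges: Optional[Dict[str, Tuple[float, float]]] = None,
    n: int = 5,
    spacing: str = "linear",
) -> ParameterGrid:
    """Five equidistributed values per parameter over the study ranges.

    ``spacing`` may be "linear" (default) or "log" (config switch; the study
    ranges are read as linearly equidistributed).
    """
    if n < 2:
        raise ValueError("need at least 2 grid values per parameter")
    ranges = ranges or DEFAULT_RANGES
    values = {}
    for name, (lo, hi) in ranges.items():
        if spacing == "linear":
            values[name] = np.linspace(lo, hi, n)
        elif spacing == "log":
            if lo <= 0 or hi <= 0:
                raise ValueError(f"log spacing needs positive range for {name}")
            values[name] = np.geomspace(lo, hi, n)
        else:
            raise ValueError(f"unknown spacing {spacing!r}")
    return ParameterGrid(values=values)


@dataclass(frozen=True)
class ModelSpec:
    """One (morphology, grid point) model specification."""

    morphology_id: str
    indices: Tuple[int, ...]  # per PARAM_ORDER
    params: Dict[str, float]

    @property
    def biophys(self) -> BiophysParamSet:
        return BiophysParamSet(**self.params)


def enumerate_models(
    grid: ParameterGrid, morphologies: Sequence[Morphology]
) -> List[ModelSpec]:
    """All grid x morphology specifications, lexicographic in parameter
    indices then morphology id (deterministic and reproducible)."""
    specs = []
    morph_ids = sorted(m.id for m in morphologies)
    for idx, params in grid.combinations():
        for mid in morph_ids:
            specs.append(ModelSpec(morphology_id=mid, indices=idx, params=params))
    return specs


@dataclass(frozen=True)
class SweepConfig:
    """Problem sizes and protocol windows for a sweep (scaled-down runs use
    shorter durations and a coarser calibration step)."""

    dt: float = 0.02  # ms
    pacemaking_duration: float = 8000.0  # ms
    stabilization_spikes: int = 4
    stabilization_ms: float = 3000.0  # pre-pulse pacemaking in rebound runs
    pulse_ms: float = 1000.0
    post_ms: float = 4000.0
    target_peak: float = -120.0  # mV
    peak_tolerance: float = 2.0  # mV
    calibration_dt: Optional[float] = None  # coarser dt for the bisection runs
    calcium: CalciumModel = CalciumModel()


def run_one(spec: ModelSpec, morphology: Morphology, cfg: SweepConfig) -> dict:
    """Simulate one database record: pacemaking ISI + calibrated rebound delay.

    Silent or censored runs are flagged, never dropped; failures are recorded
    in the ``error`` field so a sweep can continue.
    """
    rec: dict = {
        "morphology_id": spec.morphology_id,
        **{f"i_{p}": i for p, i in zip(PARAM_ORDER, spec.indices)},
        **spec.params,
        "isi_mean": np.nan,
        "isi_cv": np.nan,
        "n_spikes": 0,
        "pacemaking": False,
        "rebound_delay": np.nan,
        "rebound_censored": False,
        "pulse_amplitude_pA": np.nan,
        "error": "",
    }
    try:
        model = assemble_model(morphology, biophys=spec.biophys, calcium=cfg.calcium)
        sim_cfg = SimConfig(
            dt=cfg.dt,
            duration=cfg.pacemaking_duration,
            stabilization_spikes=cfg.stabilization_spikes,
            record_sites=("soma",),
        )
        tr = integrate(model, None, sim_cfg)
        train = detect_spikes(tr.time, tr.voltage["soma"])
        rec["n_spikes"] = train.n
        if train.n >= 6:
            stats = isi_stats(
                train, (train.times[cfg.stabilization_spikes], tr.time[-1])
            )
            rec["isi_mean"] = stats.mean_isi
            rec["isi_cv"] = stats.cv_percent
            rec["pacemaking"] = bool(stats.valid)
        if not rec["pacemaking"]:
            return rec  # rebound protocol needs a firing model
        cal_cfg = SimConfig(dt=cfg.calibration_dt or cfg.dt, record_sites=("soma",))
        amp = calibrate_hyperpolarizing_amplitude(
            model,
            target_peak=cfg.target_peak,
            tolerance=cfg.peak_tolerance,
            cfg=cal_cfg,
            stabilization_ms=cfg.stabilization_ms,
            pulse_ms=cfg.pulse_ms,
        )
        rec["pulse_amplitude_pA"] = amp
        reb = run_rebound(
            model,
            amp,
            SimConfig(dt=cfg.dt, record_sites=("soma",)),
            stabilization_ms=cfg.stabilization_ms,
            pulse_ms=cfg.pulse_ms,
            post_ms=cfg.post_ms,
        )
        rd = rebound_delay(
            reb.time, reb.voltage["soma"], reb.meta["pulse_offset_ms"], cfg.post_ms
        )
        rec["rebound_delay"] = rd
        rec["rebound_censored"] = bool(np.isnan(rd))
    except Exception as exc:  # failures are data, the sweep continues
        rec["error"] = f"{type(exc).__name__}: {exc}"
    return rec


def run_sweep(
    specs: Sequence[ModelSpec],
    morphologies: Sequence[Morphology],
    cfg: Optional[SweepConfig] = None,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Run a (subset of a) database sweep; one row per specification.

    Records are computed independently and reassembled in spec order, so the
    result does not depend on how work is partitioned across workers.
    """
    cfg = cfg or SweepConfig()
    by_id = {m.id: m for m in morphologies}
    missing = sorted({s.morphology_id for s in specs} - set(by_id))
    if missing:
        raise KeyError(f"specs reference unknown morphologies: {missing}")
    if n_jobs == 1:
        rows = [run_one(s, by_id[s.morphology_id], cfg) for s in specs]
    else:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(
            delayed(run_one)(s, by_id[s.morphology_id], cfg) for s in specs
        )
    return pd.DataFrame(rows)


def average_by_combination(records: pd.DataFrame) -> pd.DataFrame:
    """Morphology-marginalized table: one row per parameter combination with
    mean ISI / rebound delay over valid (non-flagged) runs and their counts.

    Combinations with zero valid runs keep a row with missing values.
    """
    idx_cols = [f"i_{p}" for p in PARAM_ORDER]
    out = []
    for key, grp in records.groupby(idx_cols, sort=True):
        row = dict(zip(idx_cols, key))
        for p in PARAM_ORDER:
            row[p] = grp[p].iloc[0]
        ok_isi = grp.loc[grp["pacemaking"], "isi_mean"]
        ok_reb = grp.loc[~grp["rebound_delay"].isna(), "rebound_delay"]
        row["isi_mean"] = ok_isi.mean() if len(ok_isi) else np.nan
        row["rebound_delay"] = ok_reb.mean() if len(ok_reb) else np.nan
        row["n_isi"] = int(len(ok_isi))
        row["n_rebound"] = int(len(ok_reb))
        row["n_models"] = int(len(grp))
        out.append(row)
    return pd.DataFrame(out)


@dataclass(frozen=True)
class StackLayout:
    """Dimensional-stacking axis assignment: outer axes hold one parameter
    each, inner axes nest a second parameter inside every outer cell."""

    outer_x: str = "g_A"
    outer_y: str = "v50_h_act"
    inner_x: str = "tau_h_A"
    inner_y: str = "g_H"
    feature: str = "isi_mean"
    log_transform: bool = True

    def __post_init__(self) -> None:
        axes = (self.outer_x, self.outer_y, self.inner_x, self.inner_y)
        if sorted(axes) != sorted(PARAM_ORDER):
            raise ValueError("layout must use each of the four parameters once")


def dimensional_stack(
    table: pd.DataFrame, layout: Optional[StackLayout] = None
) -> Tuple[np.ndarray, pd.DataFrame]:
    """Embed the 625-row combination table into a 25 x 25 matrix.

    Cell (y, x) with ``x = n_inner * i_outer_x + i_inner_x`` and
    ``y = n_inner * i_outer_y + i_inner_y`` holds the (optionally log10)
    feature of exactly one combination: the mapping is a bijection, returned
    alongside as an index map for inversion.  Missing combinations are NaN.
    """
    layout = layout or StackLayout()
    idx = {p: table[f"i_{p}"].to_numpy() for p in PARAM_ORDER}
    n_out_x = int(idx[layout.outer_x].max()) + 1
    n_in_x = int(idx[layout.inner_x].max()) + 1
    n_out_y = int(idx[layout.outer_y].max()) + 1
    n_in_y = int(idx[layout.inner_y].max()) + 1
    x = n_in_x * idx[layout.outer_x] + idx[layout.inner_x]
    y = n_in_y * idx[layout.outer_y] + idx[layout.inner_y]
    flat = y * (n_out_x * n_in_x) + x
    if np.unique(flat).size != flat.size:
        raise ValueError("duplicate parameter combinations in table")
    mat = np.full((n_out_y * n_in_y, n_out_x * n_in_x), np.nan)
    vals = table[layout.feature].to_numpy(dtype=float)
    if layout.log_transform:
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.log10(vals)
    mat[y, x] = vals
    index_map = pd.DataFrame({"row": y, "col": x, **{f"i_{p}": idx[p] for p in PARAM_ORDER}})
    return mat, index_map


def unstack(mat: np.ndarray, index_map: pd.DataFrame, layout: Optional[StackLayout] = None) -> pd.DataFrame:
    """Invert :func:`dimensional_stack` back to a combination table (in the
    transformed feature scale)."""
    layout = layout or StackLayout()
    out = index_map.copy()
    out[layout.feature] = mat[index_map["row"].to_numpy(), index_map["col"].to_numpy()]
    return out
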