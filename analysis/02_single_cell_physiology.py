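"""Single-cell physiology of the default model.

Runs the default (grid-center) model on the first generated morphology:
spontaneous pacemaking (ISI, CV, AP waveform), then the calibrated
hyperpolarizing-pulse protocol (peak ~ -120 mV) for sag and postinhibitory
rebound delay.  Writes a one-row feature table, the somatic traces, and a
two-panel figure under results/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from kv4pace.features import ap_features, detect_spikes, isi_stats, rebound_delay, sag_amplitude
from kv4pace.manifest import RunManifest
from kv4pace.morphology import generate_population
from kv4pace.simulator import (
    SimConfig,
    assemble_model,
    calibrate_hyperpolarizing_amplitude,
    run_pacemaking,
    run_rebound,
)

SEED = 1
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    morph = generate_population(22, seed=SEED)[0]
    model = assemble_model(morph)

    pace = run_pacemaking(model)
    st = pace.meta["spike_times"]
    train = detect_spikes(pace.time, pace.voltage["soma"])
    stats = isi_stats(train, (st[4], pace.time[-1]))
    ap = ap_features(pace.time, pace.voltage["soma"], train)

    amp = calibrate_hyperpolarizing_amplitude(model, cfg=SimConfig(dt=0.05, record_sites=("soma",)))
    reb = run_rebound(model, amp)
    offset = reb.meta["pulse_offset_ms"]
    delay = rebound_delay(reb.time, reb.voltage["soma"], offset)
    sag = sag_amplitude(reb.time, reb.voltage["soma"], (offset - 1000.0, offset))

    row = dict(
        morphology_id=morph.id,
        isi_ms=round(stats.mean_isi, 1),
        cv_isi_percent=round(stats.cv_percent, 2),
        ap_threshold_mV=round(ap.threshold, 2),
        ap_amplitude_mV=round(ap.amplitude, 2),
        ap_half_width_ms=round(ap.half_width, 3),
        ahp_trough_mV=round(ap.ahp_trough, 2),
        sag_mV=round(sag, 2),
        rebound_delay_ms=round(delay, 1),
        pulse_amplitude_pA=round(amp, 1),
    )
    pd.DataFrame([row]).to_csv(OUT / "single_cell_features.csv", index=False)
    print("Default-model single-cell features:")
    for k, v in row.items():
        print(f"  {k}: {v}")

    fig, axes = plt.subplots(1, 2, figsize=(10, 3.2))
    axes[0].plot(pace.time / 1000.0, pace.voltage["soma"], lw=0.5, color="k")
    axes[0].set(xlabel="time (s)", ylabel="Vm (mV)", title="spontaneous pacemaking")
    axes[1].plot(reb.time / 1000.0, reb.voltage["soma"], lw=0.5, color="k")
    axes[1].axvspan((offset - 1000.0) / 1000.0, offset / 1000.0, color="0.9")
    axes[1].set(xlabel="time (s)", title=f"rebound (delay {delay:.0f} ms, pulse {amp:.0f} pA)")
    fig.tight_layout()
    fig.savefig(OUT / "single_cell_physiology.png", dpi=150)

    RunManifest(
        command="analysis/02_single_cell_physiology.py",
        config={"seed": SEED},
        seeds={"population": SEED},
        outputs=[str(OUT / "single_cell_features.csv"), str(OUT / "single_cell_physiology.png")],
    ).write(OUT / "single_cell_manifest.json")


if __name__ == "__main__":
    main()
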