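"""Correlative analysis on synthetic WT and Kv4.3-knock-out populations.

Draws per-neuron populations matched to the recorded medians/IQRs and
correlation structure, then applies the study's statistical pipeline:
normality-gated correlations (FDR-adjusted) between biophysical parameters
and firing features, and best-subset multiple regression with repeated
10-fold cross-validated model selection for ISI and rebound delay.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from kv4pace.manifest import RunManifest
from kv4pace.stats import RegressionSpec, best_subset_cv, correlate_pairs
from kv4pace.synth import BIOPHYS_VARS, PopulationSpec, sample_population

SEED = 1
N_PER_GENOTYPE = 90  # comparable to the recorded samples
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    tables = []
    for genotype in ("WT", "KO"):
        tbl, truth = sample_population(
            PopulationSpec(genotype=genotype, n=N_PER_GENOTYPE, seed=SEED)
        )
        tables.append(tbl)
        (OUT / f"population_truth_{genotype}.json").write_text(
            json.dumps(
                {
                    k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in truth.items()
                },
                indent=1,
                default=str,
            )
        )
    pop = pd.concat(tables, ignore_index=True)
    pop.to_csv(OUT / "synthetic_population.csv", index=False)

    summary = pop.groupby("genotype").median(numeric_only=True).round(2)
    print("per-genotype medians:")
    print(summary.to_string())

    wt = pop[pop.genotype == "WT"]
    pairs = [(v, f) for f in ("isi", "rebound_delay") for v in BIOPHYS_VARS]
    pairs += [("v50_h_act", "v50_a_inact"), ("ia_tau", "ih_amplitude")]
    corr = correlate_pairs(wt, pairs)
    corr.to_csv(OUT / "population_correlations.csv", index=False)
    print("\nWT correlations (FDR-adjusted):")
    print(corr.round(3).to_string(index=False))

    reg_report = {}
    for response in ("isi", "rebound_delay"):
        spec = RegressionSpec(
            response=response,
            predictors=tuple(BIOPHYS_VARS),
            log_columns=(response, "ia_tau", "ih_amplitude", "ia_amplitude"),
        )
        res = best_subset_cv(wt, spec, seed=SEED)
        reg_report[response] = {
            "chosen_predictors": list(res.chosen.predictors),
            "standardized_coefficients": {k: round(v, 3) for k, v in res.chosen.coefficients.items()},
            "r2": round(res.chosen.r2, 3),
            "cv_rmse": {" + ".join(k): round(v, 4) for k, v in res.cv_rmse.items()},
            "vif": {k: round(v, 3) for k, v in res.chosen.vif.items()},
            "vif_ok": res.chosen.vif_ok,
        }
        print(f"\nbest model for log {response}: {res.chosen.predictors} "
              f"(r2={res.chosen.r2:.3f}, VIF ok: {res.chosen.vif_ok})")
    (OUT / "population_regressions.json").write_text(json.dumps(reg_report, indent=1))

    RunManifest(
        command="analysis/04_synthetic_populations.py",
        config={"seed": SEED, "n_per_genotype": N_PER_GENOTYPE},
        seeds={"population": SEED, "cv": SEED},
        outputs=[
            str(OUT / "synthetic_population.csv"),
            str(OUT / "population_correlations.csv"),
            str(OUT / "population_regressions.json"),
        ],
    ).write(OUT / "population_manifest.json")


if __name__ == "__main__":
    main()
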