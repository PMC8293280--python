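"""Generate the stylized SNc DA neuron morphology population.

Produces the 22-cell population used by the model database, writes each cell
as SWC (+ region sidecar) under results/morphologies/, and summarizes the
geometric spread (total membrane area, section counts, compartment counts).
"""

from pathlib import Path

import pandas as pd

from kv4pace.manifest import RunManifest
from kv4pace.morphology import discretize, generate_population, write_swc

SEED = 1
N_CELLS = 22
OUT = Path("results")


def main() -> None:
    out_dir = OUT / "morphologies"
    out_dir.mkdir(parents=True, exist_ok=True)
    pop = generate_population(N_CELLS, seed=SEED)
    rows = []
    for m in pop:
        write_swc(m, out_dir / f"{m.id}.swc")
        comps = discretize(m)
        rows.append(
            dict(
                morphology_id=m.id,
                n_sections=len(m.sections),
                n_compartments=comps.n,
                total_area_um2=round(m.total_area, 1),
                soma_diameter_um=round(m.sections[0].diameter, 2),
                n_dendrites=sum(1 for s in m.sections if s.kind == "dendrite" and s.parent == 0),
            )
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "morphology_summary.csv", index=False)
    spread = summary.total_area_um2.max() / summary.total_area_um2.min()
    print(summary.to_string(index=False))
    print(f"\n{N_CELLS} cells; membrane area spread {spread:.2f}-fold "
          f"({summary.total_area_um2.min():.0f}-{summary.total_area_um2.max():.0f} um^2); "
          f"{summary.n_compartments.min()}-{summary.n_compartments.max()} compartments per cell.")
    RunManifest(
        command="analysis/01_generate_morphologies.py",
        config={"seed": SEED, "n": N_CELLS},
        seeds={"population": SEED},
        outputs=[str(OUT / "morphology_summary.csv"), str(out_dir)],
    ).write(OUT / "morphologies_manifest.json")


if __name__ == "__main__":
    main()
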