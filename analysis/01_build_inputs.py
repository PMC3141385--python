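"""Build and export every model input: parameters, cohort, life table, DRG tables.

Writes the validated base-case parameter file, a 30,000-woman synthetic
cohort (summary + sample to results/, full cohort to scratch/), the synthetic
Gompertz life table, the DRG cost fixtures, and a run manifest.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

import osteosim as o
from osteosim.params import risk_table_to_csv
from osteosim.synthetic import write_manifest

SEED = 7
N = 30_000


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)

    params = o.default_parameters()
    o.save_parameters(params, RESULTS / "params.json")
    risk_table_to_csv(params.risk_table, RESULTS / "fracture_risk_table.csv")
    print(f"base-case parameters -> {RESULTS/'params.json'} "
          f"(hip cost €{params.costs.management_cost[o.Site.HIP]:.0f}, "
          f"discount {params.costs.discount_rate:.0%}, "
          f"generic €{params.costs.drug_price_per_12_weeks}/12wk)")

    spec = o.PopulationSpec()
    pop = o.generate_population(spec, N, seed=SEED)
    pop.to_csv(SCRATCH / "population.csv", index=False)
    pop.head(200).to_csv(RESULTS / "population_sample.csv", index=False)
    print(f"cohort n={N}: mean age {pop['age'].mean():.1f} "
          f"(target {spec.mean_age}), prior-fracture "
          f"{pop['prior_fracture'].mean():.1%} (target {spec.prior_fracture_prevalence:.1%})")

    lt = o.synthetic_life_table()
    lt.to_csv(RESULTS / "life_table.csv")
    print(f"synthetic life table: q(70)={lt.annual_death_probability(70):.4f}, "
          f"q(80)={lt.annual_death_probability(80):.4f} (doubles every ~8 y)")

    for preset in ("vertebra", "hip", "wrist", "toy"):
        t = o.fixture_drg_table(preset)
        t.to_csv(RESULTS / f"drg_{preset}.csv")
        print(f"DRG {preset}: {t.total_stays} stays, "
              f"weighted average €{o.weighted_average_drg_cost(t):,.0f}/stay")

    write_manifest(RESULTS / "manifest_inputs.json", seed=SEED, params=params,
                   n_patients=N, version=o.__version__)


if __name__ == "__main__":
    sys.exit(main())
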