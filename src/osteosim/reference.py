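"""Published reference values of the French cost-of-non-persistence analysis.

These numbers are the printed results of the analysis this package
re-implements.  They are *inputs* for consistency checks and reporting, never
outputs of this code: the simulation's own results depend on synthetic
stand-ins (life table, excess mortality, sampled population) and are not
expected to replicate the stochastic ones exactly.
"""

from .params import Site

#: Persistence column printed alongside the fitted curve (months → %).  The
#: 24-month source datum (41) is a known misfit of the fit (37.7); rows
#: marked by the source as extrapolated are 36, 48 and 60 months.
PERSISTENCE_TABLE = {0: 100, 6: 65, 12: 51, 24: 41, 36: 30, 48: 24, 60: 20}

#: Residual-protection column (treatment months → protection months).
PROTECTION_TABLE = {0: 0, 12: 24, 24: 43, 36: 76}

#: 10-year Monte-Carlo outcomes (30,000 women per alternative).
SIMULATION_OUTCOMES = {
    "no_treatment": {
        Site.VERTEBRA: 8193, Site.HIP: 5534, Site.WRIST: 6674, "total": 20401,
    },
    "real_world": {
        Site.VERTEBRA: 6308, Site.HIP: 4462, Site.WRIST: 5941, "total": 16711,
    },
    "ideal": {
        Site.VERTEBRA: 3912, Site.HIP: 3313, Site.WRIST: 5153, "total": 12378,
    },
}

#: Cost-effectiveness table: mean per-patient costs and effect proportions.
CEA_TABLE = {
    "no_treatment": {
        "mean_cost_discounted": 3402.0,
        "mean_cost_undiscounted": 4428.0,
        "fractured_women_proportion": 0.671,
        "premature_death_proportion": 0.061,
    },
    "real_world": {
        "mean_cost_discounted": 3110.0,
        "mean_cost_undiscounted": 3979.0,
        "fractured_women_proportion": 0.600,
        "premature_death_proportion": 0.049,
    },
    "ideal": {
        "mean_cost_discounted": 2833.0,
        "mean_cost_undiscounted": 3529.0,
        "fractured_women_proportion": 0.491,
        "premature_death_proportion": 0.034,
    },
}

#: Headline budget-impact figures.
COST_OF_NON_PERSISTENCE_PER_PATIENT = 270.0  # € per patient over 10 years
SAVING_PER_10_POINTS = 58.0  # € per patient per ten points of persistence
NATIONAL_POPULATION = 1_130_000  # diagnosed osteoporotic women in France
ANNUAL_NATIONAL_COST_MEUR = 30.5  # € million per year

#: DRG costing cross-check (vertebral case; the printed hip/wrist aggregates
#: are internally inconsistent with their printed unit averages).
VERTEBRA_DRG_AGGREGATE_EUR = 93_325_278
VERTEBRA_DRG_STAYS = 26_490
VERTEBRA_UNIT_COST_EUR = 3_523
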