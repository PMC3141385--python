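"""Pairwise cost-effectiveness, persistence sweep, and national budget impact.

Comparisons follow the published design: incremental cost-effectiveness
ratios (ICERs) between real-world persistence and no treatment, and between
ideal and real-world persistence, on two effectiveness criteria — the
proportion of fractured women and the proportion of premature
(fracture-related) deaths at the 10-year horizon.  An alternative is
*dominant* when it both costs less and produces fewer bad outcomes; the
ratio is then the saving per case avoided.  No QALYs are computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .microsim import AlternativeResult, ArmSummary, run_alternative
from .params import Alternative, ModelParameters, SimulationSettings
from .persistence import persistence_at
from .synthetic import ExcessMortality, LifeTable

EFFECTS = ("fractured_women", "premature_deaths")


@dataclass
class ICERResult:
    """One pairwise comparison b (more persistent) vs a (less persistent)."""

    label_a: str
    label_b: str
    effect: str
    discounted: bool
    delta_cost: float  # mean cost(b) - mean cost(a), € per patient
    delta_effect: float  # proportion(b) - proportion(a)
    #: € per case avoided: Δcost / |Δeffect| (negative = saving per case
    #: avoided, i.e. dominance); None when Δeffect = 0.
    ratio: Optional[float]
    dominant: bool  # cheaper and fewer bad outcomes

    def to_dict(self) -> dict:
        return vars(self).copy()


def _as_summary(arm) -> ArmSummary:
    return arm.summary() if isinstance(arm, AlternativeResult) else arm


def icer(a, b, effect: str = "fractured_women", discounted: bool = True) -> ICERResult:
    """ICER of alternative ``b`` against comparator ``a``.

    Accepts :class:`AlternativeResult` or :class:`ArmSummary` (so published
    table means can be compared directly).  Arms must share cohort size and
    horizon.
    """
    if effect not in EFFECTS:
        raise ValueError(f"effect must be one of {EFFECTS}")
    sa, sb = _as_summary(a), _as_summary(b)
    if (sa.n_patients, sa.n_cycles) != (sb.n_patients, sb.n_cycles):
        raise ValueError("arms have mismatched cohort size or horizon")
    cost_attr = "mean_cost_discounted" if discounted else "mean_cost_undiscounted"
    eff_attr = (
        "fractured_women_proportion"
        if effect == "fractured_women"
        else "premature_death_proportion"
    )
    delta_cost = getattr(sb, cost_attr) - getattr(sa, cost_attr)
    delta_effect = getattr(sb, eff_attr) - getattr(sa, eff_attr)
    dominant = delta_cost < 0 and delta_effect < 0
    ratio = None if delta_effect == 0 else delta_cost / abs(delta_effect)
    return ICERResult(
        label_a=sa.label,
        label_b=sb.label,
        effect=effect,
        discounted=discounted,
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        ratio=ratio,
        dominant=dominant,
    )


@dataclass
class TTest:
    statistic: float
    pvalue: float

    @property
    def significant(self) -> bool:
        return self.pvalue < 0.05


def compare_mean_costs(costs_a: Sequence[float], costs_b: Sequence[float]) -> TTest:
    """Two-sample Student t-test on per-patient cost vectors (α = 0.05)."""
    a = np.asarray(costs_a, dtype=float)
    b = np.asarray(costs_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each cost vector needs at least 2 observations")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return TTest(statistic=0.0, pvalue=1.0)
        raise ValueError("both arms have zero variance with different means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTest(statistic=float(t), pvalue=float(p))


def national_extrapolation(
    per_patient_cost_difference: float, population: int, horizon_years: float
) -> float:
    """Annualized national budget impact: difference × population / horizon (€/yr)."""
    if horizon_years <= 0:
        raise ValueError("horizon must be positive")
    if population <= 0:
        raise ValueError("population must be positive")
    return per_patient_cost_difference * population / horizon_years


@dataclass
class CostDistribution:
    """Summary of per-woman fracture-management costs among fractured women."""

    n: int
    mean: float
    sd: float
    bin_edges: np.ndarray
    counts: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def cost_distribution(costs: Sequence[float], bin_width: float = 1000.0) -> CostDistribution:
    """Mean/SD and histogram of fracture costs over women with ≥1 costed fracture."""
    arr = np.asarray(costs, dtype=float)
    if arr.size == 0:
        raise ValueError("no fractured women in input")
    top = max(bin_width, float(np.ceil(arr.max() / bin_width)) * bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, edges = np.histogram(arr, bins=edges)
    return CostDistribution(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        bin_edges=edges,
        counts=counts,
    )


@dataclass
class PersistenceSweep:
    """Per-patient mean costs along a persistence-improvement grid.

    ``table`` columns: uplift, persistence_12m_pct (the 1-year persistence
    the x-axis uses), mean_drug, mean_fracture, mean_total (discounted €).
    ``slope_per_10_points`` is the least-squares slope of total cost per 10
    percentage points of 1-year persistence (negative = saving).
    """

    table: pd.DataFrame
    slope_per_10_points: float
    results: list[AlternativeResult]


def persistence_sweep(
    params: ModelParameters,
    levels: Sequence[float],
    seed: int,
    population: pd.DataFrame,
    life_table: LifeTable,
    excess: ExcessMortality,
    n_cycles: int = 10,
) -> PersistenceSweep:
    """Run the engine at each persistence uplift λ and fit the cost slope.

    λ = 0 is the real-world curve, λ = 1 ideal persistence; intermediate
    levels mix the curves linearly.  All levels share the seed, so the grid
    is coupled by common random numbers.
    """
    levels = list(levels)
    if not levels:
        raise ValueError("empty persistence grid")
    if any(not 0 <= lam <= 1 for lam in levels):
        raise ValueError("levels must lie in [0, 1]")
    rows = []
    results = []
    for lam in levels:
        settings = SimulationSettings(
            n_patients=len(population),
            n_cycles=n_cycles,
            seed=seed,
            alternative=Alternative.REAL_WORLD,
        )
        res = run_alternative(
            params, settings, population, life_table, excess, uplift=lam
        )
        results.append(res)
        rows.append(
            {
                "uplift": lam,
                "persistence_12m_pct": 100.0 * persistence_at(12.0, params.persistence, uplift=lam),
                "mean_drug": res.discounted.mean_drug,
                "mean_fracture": res.discounted.mean_fracture,
                "mean_total": res.discounted.mean_total,
            }
        )
    table = pd.DataFrame(rows).sort_values("persistence_12m_pct", ignore_index=True)
    if len(table) > 1:
        slope = float(
            np.polyfit(table["persistence_12m_pct"], table["mean_total"], 1)[0]
        )
    else:
        slope = float("nan")
    return PersistenceSweep(table=table, slope_per_10_points=slope * 10.0, results=results)
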