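"""Individual-level Markov engine: annual cycles over four health states.

Each simulated woman starts in the post-menopausal osteoporosis (PMO) state
and moves between the mutually exclusive states PMO / post-vertebral /
post-hip / post-wrist; death may end her path at any cycle.  Within a cycle
the event order is fixed:

1. protection status — from the alternative and the woman's sampled
   discontinuation time (protected in cycle c iff month 12·(c-1) is still
   inside her residual-protection window y(T); ideal ⇒ always, no-treatment
   ⇒ never);
2. independent per-site fracture draws at the age-, state-, history- and
   protection-adjusted annual probability; vertebral events are flagged
   symptomatic with probability 0.23;
3. state update to the most severe new fracture (hip > vertebral > wrist);
4. death draw at the life-table probability times the excess multiplier when
   a hip or symptomatic vertebral fracture lies within the excess window —
   such deaths are flagged fracture-related (premature);
5. ageing by one year; costs accrue via the costing rules with end-of-cycle
   discounting.

The engine is vectorized over patients with a single seeded generator whose
draw order is fixed, so identical (seed, parameters) reproduce identical
results and equal seeds give common-random-number coupling across
alternatives.  ``cohort_expectation`` is the exact deterministic oracle for
reduced instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Optional

import numpy as np
import pandas as pd

from .costing import annual_drug_cost
from .params import (
    Alternative,
    HealthState,
    LIVING_STATES,
    ModelParameters,
    SITES,
    Site,
    SimulationSettings,
)
from .persistence import (
    protected_proportion,
    protection_duration,
    sample_discontinuation_times,
)
from .synthetic import ExcessMortality, LifeTable

_STATE_INDEX = {s: i for i, s in enumerate(LIVING_STATES)}
_PV, _PH, _PW = (
    _STATE_INDEX[HealthState.POST_VERTEBRAL],
    _STATE_INDEX[HealthState.POST_HIP],
    _STATE_INDEX[HealthState.POST_WRIST],
)


def annual_fracture_probability(
    age: float,
    site: Site,
    state: HealthState,
    prior: bool,
    protected: bool,
    params: ModelParameters,
) -> float:
    """One-cycle fracture probability for a living woman.

    base(age, site) × state/history RR × protective multiplier (if
    protected), capped at 1.  In the PMO state the prior-fracture RR applies;
    post-fracture state RRs replace it.
    """
    state = HealthState(state)
    if state is HealthState.DEAD:
        raise ValueError("dead is absorbing; no fracture probability")
    p = params.risk_table.lookup(age, site)
    p *= params.relative_risks.state_rr(state, site, prior)
    if protected:
        p *= params.relative_risks.treatment_multiplier(state, site)
    return min(p, 1.0)


@dataclass
class CostSummary:
    """Per-patient cost moments for one discounting convention."""

    mean_total: float
    sd_total: float
    mean_drug: float
    mean_fracture: float


@dataclass
class ArmSummary:
    """The quantities pairwise cost-effectiveness comparisons need."""

    label: str
    n_patients: int
    n_cycles: int
    mean_cost_discounted: float
    mean_cost_undiscounted: float
    fractured_women_proportion: float
    premature_death_proportion: float


@dataclass
class AlternativeResult:
    """Aggregate outcomes of one simulated alternative.

    Vertebral fractures are tallied twice on purpose: ``vertebra`` counts all
    events (morphometric included) and ``vertebra_symptomatic`` only the
    clinically diagnosed ones; ``fractured_women`` / ``fractured_women_clinical``
    mirror that split.  Costed outcomes only ever involve clinical events.
    """

    label: str
    n_patients: int
    n_cycles: int
    fractures: dict[Site, int]
    vertebra_symptomatic: int
    fractured_women: int
    fractured_women_clinical: int
    deaths: int
    premature_deaths: int
    discounted: CostSummary
    undiscounted: CostSummary
    # per-patient vectors for downstream statistics
    cost_total_discounted: np.ndarray = field(repr=False)
    cost_total_undiscounted: np.ndarray = field(repr=False)
    cost_drug_discounted: np.ndarray = field(repr=False)
    cost_drug_undiscounted: np.ndarray = field(repr=False)
    cost_fracture_discounted: np.ndarray = field(repr=False)
    cost_fracture_undiscounted: np.ndarray = field(repr=False)
    site_counts_per_patient: np.ndarray = field(repr=False)  # (n, 3) in SITES order
    fractured_mask: np.ndarray = field(repr=False)
    clinical_mask: np.ndarray = field(repr=False)
    premature_mask: np.ndarray = field(repr=False)
    death_cycle: np.ndarray = field(repr=False)  # 0 = survived the horizon
    trace: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def total_fractures(self) -> int:
        return sum(self.fractures.values())

    @property
    def total_clinical_fractures(self) -> int:
        return (
            self.vertebra_symptomatic
            + self.fractures[Site.HIP]
            + self.fractures[Site.WRIST]
        )

    @property
    def fractured_women_proportion(self) -> float:
        return self.fractured_women_clinical / self.n_patients

    @property
    def premature_death_proportion(self) -> float:
        return self.premature_deaths / self.n_patients

    def summary(self) -> ArmSummary:
        return ArmSummary(
            label=self.label,
            n_patients=self.n_patients,
            n_cycles=self.n_cycles,
            mean_cost_discounted=self.discounted.mean_total,
            mean_cost_undiscounted=self.undiscounted.mean_total,
            fractured_women_proportion=self.fractured_women_proportion,
            premature_death_proportion=self.premature_death_proportion,
        )

    def to_dict(self) -> dict:
        """JSON-friendly aggregate view (no per-patient arrays)."""
        return {
            "label": self.label,
            "n_patients": self.n_patients,
            "n_cycles": self.n_cycles,
            "fractures": {s.value: int(c) for s, c in self.fractures.items()},
            "vertebra_symptomatic": int(self.vertebra_symptomatic),
            "total_fractures": int(self.total_fractures),
            "total_clinical_fractures": int(self.total_clinical_fractures),
            "fractured_women": int(self.fractured_women),
            "fractured_women_clinical": int(self.fractured_women_clinical),
            "fractured_women_proportion": self.fractured_women_proportion,
            "deaths": int(self.deaths),
            "premature_deaths": int(self.premature_deaths),
            "premature_death_proportion": self.premature_death_proportion,
            "cost_discounted": vars(self.discounted),
            "cost_undiscounted": vars(self.undiscounted),
        }


def _risk_arrays(params: ModelParameters):
    """Precompute (bands×3) base risks and (4×3) RR / multiplier matrices."""
    bands = params.risk_table.bands
    base = np.array([[b.risk(s) for s in SITES] for b in bands])
    band_los = np.array([b.age_lo for b in bands])
    rr = params.relative_risks
    rr_noprior = np.array(
        [[rr.state_rr(st, s, prior=False) for s in SITES] for st in LIVING_STATES]
    )
    rr_prior = np.array(
        [[rr.state_rr(st, s, prior=True) for s in SITES] for st in LIVING_STATES]
    )
    tmult = np.array(
        [[rr.treatment_multiplier(st, s) for s in SITES] for st in LIVING_STATES]
    )
    return base, band_los, rr_noprior, rr_prior, tmult


def run_alternative(
    params: ModelParameters,
    settings: SimulationSettings,
    population: pd.DataFrame,
    life_table: LifeTable,
    excess: ExcessMortality,
    uplift: float = 0.0,
    collect_trace: bool = False,
) -> AlternativeResult:
    """Simulate every patient over the horizon and aggregate the outcomes.

    ``population`` must carry columns ``age`` and ``prior_fracture`` with
    exactly ``settings.n_patients`` rows.  ``uplift`` mixes the real-world
    persistence curve toward ideal (persistence-sweep use); it is ignored by
    the no-treatment and ideal alternatives.
    """
    n = settings.n_patients
    if len(population) != n:
        raise ValueError(f"population has {len(population)} rows, settings expect {n}")
    rng = np.random.default_rng(settings.seed)

    age = population["age"].to_numpy(dtype=float).copy()
    prior = population["prior_fracture"].to_numpy(dtype=bool)
    if np.any(age < params.risk_table.min_age):
        raise ValueError("population contains ages below the risk-table support")

    base, band_los, rr_noprior, rr_prior, tmult = _risk_arrays(params)
    q_hip = params.costs.management_cost[Site.HIP]
    q_wrist = params.costs.management_cost[Site.WRIST]
    q_vert = params.costs.management_cost[Site.VERTEBRA]
    sympt_frac = params.costs.symptomatic_vertebral_fraction
    drug_year = annual_drug_cost(
        params.costs.drug_price_per_12_weeks, params.costs.weeks_per_year
    )
    rate = params.costs.discount_rate

    state = np.zeros(n, dtype=np.int8)
    alive = np.ones(n, dtype=bool)
    death_cycle = np.zeros(n, dtype=np.int16)
    premature = np.zeros(n, dtype=bool)
    frac_any = np.zeros(n, dtype=bool)
    frac_clin = np.zeros(n, dtype=bool)
    site_counts = np.zeros((n, 3), dtype=np.int16)
    sympt_count = 0
    last_excess_cycle = np.full(n, -(10**6), dtype=np.int32)
    stored_mult = np.ones(n)

    drug_disc = np.zeros(n)
    drug_undisc = np.zeros(n)
    fr_disc = np.zeros(n)
    fr_undisc = np.zeros(n)

    # Discontinuation draws happen first in every alternative so the draw
    # stream stays aligned for equal-seed (common-random-number) comparisons.
    u_disc = rng.uniform(size=n)
    alt = settings.alternative
    if alt is Alternative.IDEAL:
        months_on = np.full(n, np.inf)
        protect_until = np.full(n, np.inf)
    elif alt is Alternative.NO_TREATMENT:
        months_on = np.zeros(n)
        protect_until = np.zeros(n)
    else:
        months_on = sample_discontinuation_times(u_disc, params.persistence, uplift=uplift)
        protect_until = protection_duration(months_on, params.residual)

    trace_rows: list[dict] = []

    for c in range(1, settings.n_cycles + 1):
        at_risk = alive.copy()
        if not at_risk.any():
            break
        m0 = 12.0 * (c - 1)
        protected = at_risk & (m0 < protect_until)

        bidx = np.searchsorted(band_los, age, side="right") - 1
        rr = np.where(prior[:, None], rr_prior[state], rr_noprior[state])
        p = base[bidx] * rr
        p = np.where(protected[:, None], p * tmult[state], p)
        np.clip(p, 0.0, 1.0, out=p)

        u = rng.uniform(size=(n, 3))
        ev = at_risk[:, None] & (u < p)
        ev_v, ev_h, ev_w = ev[:, 0], ev[:, 1], ev[:, 2]
        u_s = rng.uniform(size=n)
        sympt = ev_v & (u_s < sympt_frac)

        site_counts += ev
        sympt_count += int(sympt.sum())
        frac_any |= ev.any(axis=1)
        frac_clin |= ev_h | ev_w | sympt

        fcost = ev_h * q_hip + ev_w * q_wrist + sympt * q_vert

        # excess mortality bookkeeping: fracture precedes the death draw
        trig = ev_h | sympt
        new_mult = np.where(ev_h, excess.hip, excess.clinical_vertebral)
        stored_mult = np.where(trig, new_mult, stored_mult)
        last_excess_cycle = np.where(trig, c, last_excess_cycle)
        excess_active = (c - last_excess_cycle) < excess.window_years
        mult = np.where(excess_active, stored_mult, 1.0)

        qd = np.clip(life_table.annual_death_probability(age) * mult, 0.0, 1.0)
        u_d = rng.uniform(size=n)
        die = at_risk & (u_d < qd)
        premature |= die & (mult > 1.0)
        death_cycle[die] = c

        new_state = state.copy()
        new_state[ev_w] = _PW
        new_state[ev_v] = _PV
        new_state[ev_h] = _PH
        state = new_state

        if alt is Alternative.NO_TREATMENT:
            exposure = 0.0
        elif alt is Alternative.IDEAL:
            exposure = at_risk.astype(float)
        else:
            exposure = at_risk * np.clip((months_on - m0) / 12.0, 0.0, 1.0)
        dcost = drug_year * exposure
        factor = (1.0 + rate) ** (-c)
        drug_undisc += dcost
        drug_disc += dcost * factor
        fr_undisc += fcost
        fr_disc += fcost * factor

        if collect_trace:
            for i in np.flatnonzero(ev_v | ev_h | ev_w | die):
                trace_rows.append(
                    {
                        "id": int(population["id"].iloc[i]) if "id" in population else i,
                        "cycle": c,
                        "state": LIVING_STATES[state[i]].value,
                        "vertebra": bool(ev_v[i]),
                        "symptomatic": bool(sympt[i]),
                        "hip": bool(ev_h[i]),
                        "wrist": bool(ev_w[i]),
                        "died": bool(die[i]),
                        "fracture_cost": float(fcost[i]),
                        "drug_cost": float(np.asarray(dcost)[i]) if np.ndim(dcost) else 0.0,
                    }
                )

        alive &= ~die
        age += 1.0

    total_disc = drug_disc + fr_disc
    total_undisc = drug_undisc + fr_undisc

    def _summary(total, drug, frac) -> CostSummary:
        return CostSummary(
            mean_total=float(np.mean(total)),
            sd_total=float(np.std(total, ddof=1)) if n > 1 else 0.0,
            mean_drug=float(np.mean(drug)),
            mean_fracture=float(np.mean(frac)),
        )

    return AlternativeResult(
        label=alt.value if uplift == 0.0 else f"{alt.value}(uplift={uplift:g})",
        n_patients=n,
        n_cycles=settings.n_cycles,
        fractures={s: int(site_counts[:, j].sum()) for j, s in enumerate(SITES)},
        vertebra_symptomatic=sympt_count,
        fractured_women=int(frac_any.sum()),
        fractured_women_clinical=int(frac_clin.sum()),
        deaths=int((death_cycle > 0).sum()),
        premature_deaths=int(premature.sum()),
        discounted=_summary(total_disc, drug_disc, fr_disc),
        undiscounted=_summary(total_undisc, drug_undisc, fr_undisc),
        cost_total_discounted=total_disc,
        cost_total_undiscounted=total_undisc,
        cost_drug_discounted=drug_disc,
        cost_drug_undiscounted=drug_undisc,
        cost_fracture_discounted=fr_disc,
        cost_fracture_undiscounted=fr_undisc,
        site_counts_per_patient=site_counts,
        fractured_mask=frac_any,
        clinical_mask=frac_clin,
        premature_mask=premature,
        death_cycle=death_cycle,
        trace=pd.DataFrame(trace_rows) if collect_trace else None,
    )


@dataclass
class CohortExpectation:
    """Exact per-patient expectations from forward probability propagation."""

    expected_fractures: dict[Site, float]  # events per patient over the run
    expected_deaths: float
    expected_premature_deaths: float
    occupancy: list[dict[str, float]]  # per cycle-end, includes "dead"


def cohort_expectation(
    params: ModelParameters,
    alternative: Alternative,
    start_age: float,
    n_cycles: int,
    life_table: LifeTable,
    excess: ExcessMortality,
    prior_prob: float = 0.597,
    uplift: float = 0.0,
    max_cycles: int = 4,
) -> CohortExpectation:
    """Deterministic oracle: exact state-probability propagation.

    Uses the same transition rules as the engine on a cohort with a single
    start age, with the closed-form protected proportion standing in for the
    per-patient discontinuation draw (exact whenever the protection
    probability is 0 or 1 in every cycle, i.e. for the no-treatment and ideal
    alternatives, and for real-world horizons within the first two cycles
    where everyone is still residually protected).  Refuses instances too
    large for exact enumeration.
    """
    if n_cycles > max_cycles:
        raise ValueError(f"instance too large: {n_cycles} cycles > {max_cycles}")
    if excess.window_years != 1:
        raise ValueError("oracle assumes a one-cycle excess-mortality window")

    alternative = Alternative(alternative)
    sympt_frac = params.costs.symptomatic_vertebral_fraction
    # occupancy over (state index, prior flag); death tracked separately
    occ = {(0, True): prior_prob, (0, False): 1.0 - prior_prob}
    dead = 0.0
    premature = 0.0
    exp_frac = {s: 0.0 for s in SITES}
    occupancy_out: list[dict[str, float]] = []

    for c in range(1, n_cycles + 1):
        age = start_age + (c - 1)
        qb = life_table.annual_death_probability(age)
        if alternative is Alternative.NO_TREATMENT:
            pi = 0.0
        elif alternative is Alternative.IDEAL:
            pi = 1.0
        else:
            pi = protected_proportion(
                12.0 * (c - 1), params.persistence, params.residual, uplift=uplift
            )
        nxt: dict[tuple[int, bool], float] = {}
        for (sidx, prior), w in occ.items():
            if w == 0.0:
                continue
            st = LIVING_STATES[sidx]
            for prot, wp in ((True, pi), (False, 1.0 - pi)):
                if wp == 0.0:
                    continue
                probs = [
                    annual_fracture_probability(age, s, st, prior, prot, params)
                    for s in SITES
                ]
                for ev in product((0, 1), repeat=3):
                    p_ev = w * wp
                    for e, ps in zip(ev, probs):
                        p_ev *= ps if e else (1.0 - ps)
                    if p_ev == 0.0:
                        continue
                    ev_v, ev_h, ev_w = ev
                    for s, e in zip(SITES, ev):
                        exp_frac[s] += p_ev * e
                    # symptomatic split only matters when a vertebral event
                    # occurred and no hip event dominates the multiplier
                    splits = (
                        [(sympt_frac, True), (1.0 - sympt_frac, False)]
                        if ev_v
                        else [(1.0, False)]
                    )
                    for w_s, sympt in splits:
                        p_branch = p_ev * w_s
                        if p_branch == 0.0:
                            continue
                        mult = excess.hip if ev_h else (
                            excess.clinical_vertebral if sympt else 1.0
                        )
                        q = min(1.0, qb * mult)
                        if ev_h:
                            new_sidx = _PH
                        elif ev_v:
                            new_sidx = _PV
                        elif ev_w:
                            new_sidx = _PW
                        else:
                            new_sidx = sidx
                        dead += p_branch * q
                        if mult > 1.0:
                            premature += p_branch * q
                        key = (new_sidx, prior)
                        nxt[key] = nxt.get(key, 0.0) + p_branch * (1.0 - q)
        occ = nxt
        snapshot = {s.value: 0.0 for s in LIVING_STATES}
        for (sidx, _), w in occ.items():
            snapshot[LIVING_STATES[sidx].value] += w
        snapshot["dead"] = dead
        occupancy_out.append(snapshot)

    return CohortExpectation(
        expected_fractures=exp_frac,
        expected_deaths=dead,
        expected_premature_deaths=premature,
        occupancy=occupancy_out,
    )
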