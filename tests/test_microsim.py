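"""Markov engine: transition probabilities, cycle mechanics, aggregation."""

import math

import numpy as np
import pytest

import osteosim as o
from osteosim.params import Alternative, HealthState, Site


def _flat_life_table(q_value: float) -> o.LifeTable:
    ages = np.arange(50, 111)
    q = np.full(ages.shape, float(q_value))
    q[-1] = 1.0
    return o.LifeTable(ages=ages, q=q)


def _zero_risk_params(params):
    p = params.model_copy(deep=True)
    for band in p.risk_table.bands:
        band.vertebra = band.hip = band.wrist = 0.0
    return p


class TestAnnualFractureProbability:
    @pytest.mark.parametrize(
        "state,prior,protected,expected",
        [
            (HealthState.PMO, False, False, 0.0065),
            (HealthState.PMO, True, False, 0.0065 * 2.0),
            (HealthState.POST_VERTEBRAL, False, False, 0.0065 * 2.3),
            (HealthState.PMO, False, True, 0.0065 * 0.672),
            (HealthState.POST_VERTEBRAL, True, True, 0.0065 * 2.3 * 0.620),
        ],
    )
    def test_hip_probability_composition(self, params, state, prior, protected, expected):
        got = o.annual_fracture_probability(72, Site.HIP, state, prior, protected, params)
        assert math.isclose(got, expected)

    def test_post_state_replaces_prior_rr(self, params):
        """After an on-model fracture the state RR replaces the baseline one."""
        with_prior = o.annual_fracture_probability(
            72, Site.VERTEBRA, HealthState.POST_WRIST, True, False, params
        )
        without = o.annual_fracture_probability(
            72, Site.VERTEBRA, HealthState.POST_WRIST, False, False, params
        )
        assert with_prior == without == 0.0556 * 1.7

    def test_capped_at_one(self, params):
        p = params.model_copy(deep=True)
        p.risk_table.bands[-1].vertebra = 0.5
        got = o.annual_fracture_probability(
            99, Site.VERTEBRA, HealthState.POST_VERTEBRAL, False, False, p
        )
        assert got == 1.0

    def test_dead_rejected(self, params):
        with pytest.raises(ValueError):
            o.annual_fracture_probability(72, Site.HIP, HealthState.DEAD, False, False, params)


class TestStepMechanics:
    def test_zero_risks_zero_mortality_nothing_happens(
        self, params, excess, uniform_cohort
    ):
        pop = uniform_cohort(300)
        settings = o.SimulationSettings(
            n_patients=300, n_cycles=10, seed=1, alternative=Alternative.NO_TREATMENT
        )
        res = o.run_alternative(
            _zero_risk_params(params), settings, pop, _flat_life_table(0.0), excess
        )
        assert res.total_fractures == 0
        assert res.deaths == 0
        assert res.fractured_women == 0
        assert (res.cost_total_undiscounted == 0).all()

    def test_certain_death_first_cycle(self, params, excess, uniform_cohort):
        pop = uniform_cohort(200)
        settings = o.SimulationSettings(
            n_patients=200, n_cycles=10, seed=1, alternative=Alternative.NO_TREATMENT
        )
        res = o.run_alternative(params, settings, pop, _flat_life_table(1.0), excess)
        assert res.deaths == 200
        assert (res.death_cycle == 1).all()

    def test_fracture_draw_precedes_death(self, params, excess, uniform_cohort):
        """With q ≡ 1 and certain fracture, the event is still recorded."""
        p = params.model_copy(deep=True)
        for band in p.risk_table.bands:
            band.hip = 1.0
        pop = uniform_cohort(1)
        settings = o.SimulationSettings(
            n_patients=1, n_cycles=10, seed=1, alternative=Alternative.NO_TREATMENT
        )
        res = o.run_alternative(p, settings, pop, _flat_life_table(1.0), excess)
        assert res.fractures[Site.HIP] == 1
        assert res.deaths == 1 and res.premature_deaths == 1

    def test_null_efficacy_makes_arms_identical(self, params, excess, life_table, small_cohort):
        """Treatment multipliers of 1 collapse ideal onto no-treatment."""
        p = params.model_copy(deep=True)
        for row in p.relative_risks.treatment.values():
            for site in list(row):
                row[site] = 1.0
        results = {}
        for alt in (Alternative.IDEAL, Alternative.NO_TREATMENT):
            settings = o.SimulationSettings(
                n_patients=len(small_cohort), n_cycles=10, seed=9, alternative=alt
            )
            results[alt] = o.run_alternative(p, settings, small_cohort, life_table, excess)
        a, b = results[Alternative.IDEAL], results[Alternative.NO_TREATMENT]
        assert a.fractures == b.fractures
        assert a.deaths == b.deaths
        np.testing.assert_allclose(a.cost_fracture_discounted, b.cost_fracture_discounted)


class TestRunAlternative:
    def test_site_counts_sum_to_total(self, run, small_cohort):
        res = run(small_cohort, Alternative.NO_TREATMENT)
        assert res.total_fractures == sum(res.fractures.values())
        assert res.total_clinical_fractures == (
            res.vertebra_symptomatic + res.fractures[Site.HIP] + res.fractures[Site.WRIST]
        )
        assert res.fractured_women_clinical <= res.fractured_women <= len(small_cohort)
        assert res.fractured_women_clinical <= res.total_clinical_fractures

    def test_seed_determinism(self, run, small_cohort):
        r1 = run(small_cohort, Alternative.REAL_WORLD, seed=33)
        r2 = run(small_cohort, Alternative.REAL_WORLD, seed=33)
        assert r1.to_dict() == r2.to_dict()
        np.testing.assert_array_equal(r1.cost_total_discounted, r2.cost_total_discounted)

    @pytest.mark.parametrize("seed", range(10))
    def test_ideal_strictly_fewer_fractures_than_no_treatment(self, run, small_cohort, seed):
        ideal = run(small_cohort, Alternative.IDEAL, seed=seed)
        none = run(small_cohort, Alternative.NO_TREATMENT, seed=seed)
        assert ideal.total_fractures < none.total_fractures

    def test_arm_ordering_of_harms(self, run, cohort_30k):
        """Fractures, fractured women and premature deaths all order
        no-treatment > real-world > ideal (Monte-Carlo ordering at n=30k)."""
        res = {a: run(cohort_30k, a, seed=4) for a in Alternative}
        none, real, ideal = (
            res[Alternative.NO_TREATMENT],
            res[Alternative.REAL_WORLD],
            res[Alternative.IDEAL],
        )
        assert none.total_fractures > real.total_fractures > ideal.total_fractures
        assert (
            none.fractured_women_clinical
            > real.fractured_women_clinical
            > ideal.fractured_women_clinical
        )
        assert none.premature_deaths > real.premature_deaths > ideal.premature_deaths

    def test_absorbing_death_no_events_after_death(self, params, life_table, excess, small_cohort):
        settings = o.SimulationSettings(
            n_patients=len(small_cohort), n_cycles=10, seed=2,
            alternative=Alternative.NO_TREATMENT,
        )
        res = o.run_alternative(
            params, settings, small_cohort, life_table, excess, collect_trace=True
        )
        death_at = res.trace[res.trace["died"]].groupby("id")["cycle"].min()
        last_event = res.trace.groupby("id")["cycle"].max()
        joined = death_at.to_frame("death").join(last_event.to_frame("last"))
        assert (joined["last"] <= joined["death"]).all()

    def test_population_size_mismatch_rejected(self, params, life_table, excess, small_cohort):
        settings = o.SimulationSettings(
            n_patients=77, n_cycles=10, seed=2, alternative=Alternative.NO_TREATMENT
        )
        with pytest.raises(ValueError, match="population"):
            o.run_alternative(params, settings, small_cohort, life_table, excess)


class TestCohortExpectation:
    def test_single_cycle_hip_probability(self, params, life_table, excess):
        """One 72-year-old, one cycle, no treatment: P(hip) is the band risk."""
        exp = o.cohort_expectation(
            params, Alternative.NO_TREATMENT, 72.0, 1, life_table, excess, prior_prob=0.0
        )
        assert math.isclose(exp.expected_fractures[Site.HIP], 0.0065)
        assert math.isclose(exp.expected_fractures[Site.VERTEBRA], 0.0556)

    def test_zero_risk_zero_mortality_stays_pmo(self, params, excess):
        exp = o.cohort_expectation(
            _zero_risk_params(params),
            Alternative.NO_TREATMENT,
            72.0,
            2,
            _flat_life_table(0.0),
            excess,
        )
        assert exp.occupancy[-1]["pmo"] == pytest.approx(1.0)
        assert exp.expected_deaths == 0.0

    def test_occupancy_sums_to_one(self, params, life_table, excess):
        exp = o.cohort_expectation(
            params, Alternative.REAL_WORLD, 72.0, 2, life_table, excess
        )
        for snap in exp.occupancy:
            assert sum(snap.values()) == pytest.approx(1.0)

    def test_refuses_large_instances(self, params, life_table, excess):
        with pytest.raises(ValueError, match="too large"):
            o.cohort_expectation(
                params, Alternative.NO_TREATMENT, 72.0, 8, life_table, excess
            )

    def test_refuses_multi_cycle_excess_window(self, params, life_table):
        with pytest.raises(ValueError, match="window"):
            o.cohort_expectation(
                params,
                Alternative.NO_TREATMENT,
                72.0,
                2,
                life_table,
                o.ExcessMortality(window_years=2.0),
            )
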