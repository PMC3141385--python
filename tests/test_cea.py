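"""ICERs, cost comparison statistics, sweep, extrapolation, distributions."""

import math

import numpy as np
import pytest

import osteosim as o
from osteosim.cea import persistence_sweep
from osteosim.microsim import ArmSummary
from osteosim.params import Alternative
from osteosim.reference import CEA_TABLE


def _summary(label, cost, fractured, premature=0.05, n=30000):
    return ArmSummary(
        label=label,
        n_patients=n,
        n_cycles=10,
        mean_cost_discounted=cost,
        mean_cost_undiscounted=cost,
        fractured_women_proportion=fractured,
        premature_death_proportion=premature,
    )


class TestICER:
    def test_published_means_give_dominance(self):
        """Ideal vs real-world at the published discounted means: dominated
        comparator, incremental cost -€277, ~€2,541 saved per case avoided."""
        real = _summary("real_world", CEA_TABLE["real_world"]["mean_cost_discounted"],
                        CEA_TABLE["real_world"]["fractured_women_proportion"])
        ideal = _summary("ideal", CEA_TABLE["ideal"]["mean_cost_discounted"],
                         CEA_TABLE["ideal"]["fractured_women_proportion"])
        r = o.icer(real, ideal)
        assert r.dominant
        assert math.isclose(r.delta_cost, -277.0)
        assert math.isclose(r.delta_effect, -0.109)
        assert math.isclose(abs(r.ratio), 277 / 0.109, rel_tol=1e-9)

    def test_cost_per_case_avoided_arithmetic(self):
        a = _summary("a", 1000.0, 0.5)
        b = _summary("b", 1100.0, 0.4)
        r = o.icer(a, b)
        assert not r.dominant
        assert math.isclose(r.ratio, 1000.0)  # +€100 / 0.1 cases avoided

    def test_identical_arms_ratio_undefined(self):
        a = _summary("a", 1000.0, 0.5)
        r = o.icer(a, a)
        assert r.delta_cost == 0 and r.ratio is None and not r.dominant

    def test_mismatched_settings_rejected(self):
        a = _summary("a", 1000.0, 0.5)
        b = _summary("b", 900.0, 0.4, n=999)
        with pytest.raises(ValueError, match="mismatch"):
            o.icer(a, b)

    def test_effect_criterion_validated(self):
        a = _summary("a", 1000.0, 0.5)
        with pytest.raises(ValueError, match="effect"):
            o.icer(a, a, effect="qalys")


class TestCompareMeanCosts:
    def test_identical_vectors_null(self):
        r = o.compare_mean_costs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.pvalue == pytest.approx(1.0)

    def test_identical_constants_null(self):
        r = o.compare_mean_costs([5.0, 5.0], [5.0, 5.0])
        assert (r.statistic, r.pvalue) == (0.0, 1.0)

    def test_separated_groups_significant(self):
        r = o.compare_mean_costs([0, 0, 0, 1e-9], [1, 1, 1, 1 + 1e-9])
        assert r.pvalue < 0.05 and r.significant

    def test_hand_computed_fixture(self):
        """{1,2,3} vs {2,4,6}: pooled-variance t = -2/sqrt(5/3)."""
        r = o.compare_mean_costs([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert math.isclose(r.statistic, -2.0 / math.sqrt(5.0 / 3.0), rel_tol=1e-12)
        assert 0.19 < r.pvalue < 0.20  # df=4 reference value ~0.196

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            o.compare_mean_costs([1.0], [2.0, 3.0])
        with pytest.raises(ValueError, match="zero variance"):
            o.compare_mean_costs([1.0, 1.0], [2.0, 2.0])

    def test_engine_arms_differ_significantly(self, run, cohort_30k):
        none = run(cohort_30k, Alternative.NO_TREATMENT)
        ideal = run(cohort_30k, Alternative.IDEAL)
        r = o.compare_mean_costs(
            none.cost_fracture_discounted, ideal.cost_fracture_discounted
        )
        assert r.significant


class TestNationalExtrapolation:
    @pytest.mark.parametrize(
        "diff,pop,horizon,expected",
        [
            (270.0, 1_130_000, 10, 30_510_000.0),
            (0.0, 1_130_000, 10, 0.0),
            (100.0, 10, 10, 100.0),
        ],
    )
    def test_values(self, diff, pop, horizon, expected):
        assert o.national_extrapolation(diff, pop, horizon) == expected

    def test_domain(self):
        with pytest.raises(ValueError):
            o.national_extrapolation(100.0, 1000, 0)
        with pytest.raises(ValueError):
            o.national_extrapolation(100.0, 0, 10)


class TestCostDistribution:
    def test_single_value(self):
        d = o.cost_distribution([5872.0])
        assert d.mean == 5872.0 and d.sd == 0.0 and d.n == 1

    def test_hand_mean(self):
        d = o.cost_distribution([11419.0, 3305.0])
        assert d.mean == pytest.approx(7362.0)
        assert d.counts.sum() == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            o.cost_distribution([])

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_fractured_women_cost_ordering_across_arms(self, run, small_cohort, seed):
        """Mean fracture cost among fractured women: no-treatment > ideal."""
        none = run(small_cohort, Alternative.NO_TREATMENT, seed=seed)
        ideal = run(small_cohort, Alternative.IDEAL, seed=seed)
        d_none = o.cost_distribution(
            none.cost_fracture_undiscounted[none.clinical_mask]
        )
        d_ideal = o.cost_distribution(
            ideal.cost_fracture_undiscounted[ideal.clinical_mask]
        )
        assert d_none.mean > d_ideal.mean


@pytest.fixture(scope="module")
def sweep(params, life_table, excess, small_cohort):
    return persistence_sweep(
        params, [0.0, 0.5, 1.0], seed=21, population=small_cohort,
        life_table=life_table, excess=excess,
    )


class TestPersistenceSweep:
    def test_endpoints_reproduce_independent_arms(
        self, sweep, run, small_cohort
    ):
        real = run(small_cohort, Alternative.REAL_WORLD, seed=21)
        ideal = run(small_cohort, Alternative.IDEAL, seed=21)
        lo = sweep.table.iloc[0]
        hi = sweep.table.iloc[-1]
        assert lo["mean_total"] == pytest.approx(real.discounted.mean_total)
        assert hi["mean_total"] == pytest.approx(ideal.discounted.mean_total)
        assert hi["persistence_12m_pct"] == 100.0

    def test_monotone_cost_components(self, sweep):
        drug = sweep.table["mean_drug"].to_numpy()
        frac = sweep.table["mean_fracture"].to_numpy()
        assert (np.diff(drug) >= 0).all()
        assert (np.diff(frac) <= 0).all()

    def test_axis_is_one_year_persistence(self, sweep):
        assert sweep.table["persistence_12m_pct"].iloc[0] == pytest.approx(51.296, abs=0.01)

    def test_empty_or_invalid_grid_rejected(self, params, life_table, excess, small_cohort):
        with pytest.raises(ValueError):
            persistence_sweep(params, [], seed=1, population=small_cohort,
                              life_table=life_table, excess=excess)
        with pytest.raises(ValueError):
            persistence_sweep(params, [1.5], seed=1, population=small_cohort,
                              life_table=life_table, excess=excess)


class TestDiscountingPattern:
    def test_undiscounted_incrementals_larger_in_magnitude(self, run, cohort_30k):
        """Real-world vs no-treatment: |Δcost| grows when discounting is off."""
        none = run(cohort_30k, Alternative.NO_TREATMENT, seed=6)
        real = run(cohort_30k, Alternative.REAL_WORLD, seed=6)
        disc = o.icer(none, real, discounted=True)
        undisc = o.icer(none, real, discounted=False)
        assert abs(undisc.delta_cost) > abs(disc.delta_cost)
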