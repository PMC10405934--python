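"""Decision tree, transition matrix and cohort recursion."""

import numpy as np
import pytest

from crlm_cea.model import (
    HealthState,
    annual_recurrence_probability,
    combine_mortality,
    evaluate_strategies,
    initial_allocation,
    run_cohort,
    transition_matrix,
)
from crlm_cea.parameters import StrategySpec
from crlm_cea.synthetic import SyntheticSpec, random_parameter_table, synthetic_lifetable


def constant_lifetable(q, age_range=(60, 120)):
    ages = np.arange(age_range[0], age_range[1] + 1)
    from crlm_cea.lifetable import LifeTable

    return LifeTable(ages, np.full(ages.size, float(q)))


class TestInitialAllocation:
    def test_mri_branch_masses(self, basecase):
        table, strategies = basecase
        mri = {s.name: s for s in strategies}["MRI"]
        alloc = initial_allocation(mri, table)
        assert alloc.tp == pytest.approx(0.2333375, abs=5e-7)
        assert alloc.fn == pytest.approx(0.0416625, abs=5e-7)
        assert alloc.tn == pytest.approx(0.6673625, abs=5e-7)
        assert alloc.fp == pytest.approx(0.0576375, abs=5e-7)
        assert alloc.tp + alloc.fn + alloc.tn + alloc.fp == pytest.approx(1.0)

    def test_perfect_test(self, basecase):
        table, _ = basecase
        perfect = StrategySpec("perfect", 1.0, 1.0, 100.0)
        alloc = initial_allocation(perfect, table)
        assert alloc.tp == pytest.approx(table["p_metastases"])
        assert alloc.tn == pytest.approx(1.0 - table["p_metastases"])
        assert alloc.fn == alloc.fp == 0.0

    def test_no_disease_all_negative_side(self, basecase):
        table, strategies = basecase
        table0 = table.replace_values(p_metastases=0.0)
        alloc = initial_allocation(strategies[0], table0)
        assert alloc.tp == alloc.fn == 0.0
        assert alloc.tn + alloc.fp == pytest.approx(1.0)

    def test_upfront_cost_components(self, basecase):
        table, strategies = basecase
        mri = {s.name: s for s in strategies}["MRI"]
        alloc = initial_allocation(mri, table)
        expected = (
            mri.imaging_cost
            + alloc.tp * table["overall_resection_cost"]
            + alloc.fp * table["fp_workup_cost"]
        )
        assert alloc.upfront_cost == pytest.approx(expected)

    def test_occupancy_splits_tp_by_treatment_success(self, basecase):
        table, strategies = basecase
        alloc = initial_allocation(strategies[1], table)
        v = alloc.occupancy()
        assert v.sum() == pytest.approx(1.0)
        assert v[HealthState.RESECTED] == pytest.approx(alloc.tp * 0.70)
        assert v[HealthState.RECURRENCE] == pytest.approx(alloc.tp * 0.30)


class TestTransitionMatrix:
    def test_rows_stochastic_and_death_absorbing(self, basecase, lifetable):
        table, _ = basecase
        for age in (68, 75, 99, 105):
            M = transition_matrix(table, lifetable, age)
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
            assert M[HealthState.DEATH, HealthState.DEATH] == 1.0
            assert np.all(M >= 0)

    def test_disease_and_background_mortality_combine(self, basecase):
        # independent competing risks: 1 - (1-0.2417)(1-0.02)
        table, _ = basecase
        M = transition_matrix(table, constant_lifetable(0.02), 70)
        assert M[HealthState.UNDIAGNOSED_TUMOR, HealthState.DEATH] == pytest.approx(
            0.256866, abs=1e-9
        )
        assert combine_mortality(0.2417, 0.02) == pytest.approx(0.256866, abs=1e-9)

    def test_recurrence_annualisation(self):
        # 62% cumulative over 5 years -> 1 - 0.38^(1/5) per year
        annual = annual_recurrence_probability(0.62, "cumulative_5y")
        assert annual == pytest.approx(1.0 - 0.38 ** 0.2, abs=1e-12)
        assert annual == pytest.approx(0.17594401, abs=1e-7)
        assert annual_recurrence_probability(0.62, "annual") == 0.62

    def test_resected_to_recurrence_uses_annualised_rate(self, basecase):
        table, _ = basecase
        M = transition_matrix(table, constant_lifetable(0.0), 70)
        assert M[HealthState.RESECTED, HealthState.RECURRENCE] == pytest.approx(
            1.0 - 0.38 ** 0.2
        )

    def test_past_lifetable_everyone_dies(self, basecase, lifetable):
        table, _ = basecase
        M = transition_matrix(table, lifetable, 120)
        np.testing.assert_allclose(M[:, HealthState.DEATH], 1.0)


class TestCohortRun:
    def test_conservation_five_qalys(self, basecase):
        # no mortality, utilities 1, no discounting -> exactly horizon QALYs
        table, strategies = basecase
        t = table.with_settings(discount_rate=0.0, horizon=5).replace_values(
            u_post_resection=1.0,
            u_recurrence=1.0,
            u_undetected=1.0,
            p_death_untreated=0.0,
            p_death_recurrence=0.0,
        )
        for strat in strategies:
            _, res = run_cohort(strat, t, constant_lifetable(0.0))
            assert res.qaly == pytest.approx(5.0, abs=1e-12)

    def test_discounted_cost_closed_form(self, basecase):
        # cohort pinned in one state costing 100/cycle: 100 + 100/1.03
        table, _ = basecase
        t = table.with_settings(horizon=2, discount_rate=0.03).replace_values(
            p_metastases=1.0,
            p_treatment_success=0.0,
            annual_crlm_cost=100.0,
            overall_resection_cost=0.0,
            p_death_recurrence=0.0,
        )
        strat = StrategySpec("unit", 1.0, 1.0, 0.0)
        _, res = run_cohort(strat, t, constant_lifetable(0.0))
        assert res.cost == pytest.approx(100.0 + 100.0 / 1.03, abs=1e-9)

    def test_dominance_sanity_identical_strategies(self, basecase, lifetable):
        table, _ = basecase
        t = table
        for slug in ("cect", "petct"):
            t = t.replace_values(
                **{
                    f"sens_{slug}": table["sens_mri"],
                    f"spec_{slug}": table["spec_mri"],
                    f"cost_{slug}": table["cost_mri"],
                }
            )
        results = evaluate_strategies(t, lifetable)
        assert len({round(r.cost, 9) for r in results}) == 1
        assert len({round(r.qaly, 9) for r in results}) == 1

    def test_cost_and_utility_monotonicity(self, calibrated, lifetable):
        base = evaluate_strategies(calibrated, lifetable)
        up_cost = evaluate_strategies(
            calibrated.replace_values(annual_crlm_cost=calibrated["annual_crlm_cost"] * 2),
            lifetable,
        )
        up_util = evaluate_strategies(
            calibrated.replace_values(u_recurrence=0.9), lifetable
        )
        for b, c, u in zip(base, up_cost, up_util):
            assert c.cost >= b.cost
            assert c.qaly == pytest.approx(b.qaly)
            assert u.qaly >= b.qaly

    def test_trace_invariants(self, calibrated, lifetable):
        strat = calibrated.strategy_specs()[1]
        trace, res = run_cohort(strat, calibrated, lifetable)
        occ = trace.occupancy
        np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-12)
        death = occ[:, HealthState.DEATH]
        assert np.all(np.diff(death) >= -1e-15)
        df = trace.to_frame()
        assert df["cum_cost"].iloc[-1] == pytest.approx(res.cost)
        assert df["cum_qaly"].iloc[-1] == pytest.approx(res.qaly)

    def test_discounting_never_exceeds_undiscounted(self, calibrated, lifetable):
        strat = calibrated.strategy_specs()[0]
        _, disc = run_cohort(strat, calibrated, lifetable)
        _, undisc = run_cohort(strat, calibrated.with_settings(discount_rate=0.0), lifetable)
        assert disc.cost <= undisc.cost
        assert disc.qaly <= undisc.qaly

    def test_discount_limit_continuity(self, basecase):
        # as the discount rate -> 0 totals converge to the undiscounted sums
        table, _ = basecase
        t = table.with_settings(horizon=4).replace_values(
            p_metastases=1.0,
            p_treatment_success=0.0,
            annual_crlm_cost=100.0,
            overall_resection_cost=0.0,
            p_death_recurrence=0.0,
        )
        strat = StrategySpec("unit", 1.0, 1.0, 0.0)
        lt = constant_lifetable(0.0)
        _, res0 = run_cohort(strat, t.with_settings(discount_rate=0.0), lt)
        _, res_eps = run_cohort(strat, t.with_settings(discount_rate=1e-10), lt)
        assert res0.cost == pytest.approx(400.0, abs=1e-9)
        assert res_eps.cost == pytest.approx(res0.cost, abs=1e-6)

    def test_conservation_on_random_tables(self):
        for seed in range(25):
            table = random_parameter_table(SyntheticSpec(seed=seed))
            lt = synthetic_lifetable(0.01, 0.09, (60, 110))
            for strat in table.strategy_specs():
                trace, _ = run_cohort(strat, table, lt)
                np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
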