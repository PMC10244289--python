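import dataclasses

import numpy as np
import pytest

from gdmcea import ModelConfig
from gdmcea import cohort_engine as ce
from gdmcea import health_economics as he
from gdmcea.model_inputs import AgeBandedCost, Uncertain


def test_intervention_unit_cost_from_salary_and_caseload():
    # one coach: AU$82,600 salary, 15% on-costs, 20% fixed allowance, 500 women/yr
    assert round(he.intervention_unit_cost()) == 228
    assert he.intervention_unit_cost() == pytest.approx(82_600 * 1.15 * 1.20 / 500)


class TestPerinatalCosts:
    def test_toy_antenatal_only(self, params):
        cohort = dataclasses.replace(params.cohorts[0], n_births=100.0,
                                     preexisting_dm_prevalence=0.0, gdm_prevalence=0.1)
        costs = dataclasses.replace(
            params.costs, antenatal_gdm_cost=Uncertain(1000.0),
            caesarean_cost=Uncertain(0.0), induction_cost=Uncertain(0.0))
        w = ce.pregnancy_branching(cohort, "usual_care", 0.67, costs=costs)
        frag = he.perinatal_costs(w, cohort, costs, include_nicu=False)
        assert frag.pregnancy == pytest.approx(10_000.0)
        assert frag.nicu_scn == 0.0

    def test_zero_gdm_prevalence_equalises_arms(self, params):
        cohort = dataclasses.replace(params.cohorts[0], gdm_prevalence=0.0)
        frags = []
        for arm in ("usual_care", "intervention"):
            w = ce.pregnancy_branching(cohort, arm, 0.67, costs=params.costs)
            frags.append(he.perinatal_costs(w, cohort, params.costs, include_nicu=True))
        assert frags[0].pregnancy == pytest.approx(frags[1].pregnancy)
        assert frags[0].nicu_scn == pytest.approx(frags[1].nicu_scn)

    def test_nicu_toggle(self, params):
        cohort = params.cohorts[3]
        w = ce.pregnancy_branching(cohort, "usual_care", 0.67, costs=params.costs)
        off = he.perinatal_costs(w, cohort, params.costs, include_nicu=False)
        on = he.perinatal_costs(w, cohort, params.costs, include_nicu=True)
        assert off.nicu_scn == 0.0 and on.nicu_scn > 0.0


def one_case_year_trace(cfg):
    """Everyone converts in cycle 1, nobody dies: 1 T2DM case-year per cycle."""
    sched = ce.TransitionSchedule(branch="gdm", representative_age=32,
                                  ages=np.array([33]), p_to_t2dm=np.array([1.0]),
                                  p_death_no_t2dm=np.zeros(1), p_death_t2dm=np.zeros(1))
    return ce.run_markov_trace(sched, cfg)


class TestChronicCosts:
    def test_one_case_year_discounted(self, params):
        cfg = ModelConfig(half_cycle_correction=False)
        tr = one_case_year_trace(cfg)
        costs = dataclasses.replace(params.costs, t2dm_annual_cost_by_age=(
            AgeBandedCost(15, 85, 1000.0),))
        assert he.chronic_costs(tr, costs, "base", cfg) == pytest.approx(1000 / 1.05)
        assert he.chronic_costs(tr, costs, "base", cfg) == pytest.approx(952.38, abs=0.01)

    def test_no_t2dm_occupancy_no_cost(self, params, config):
        sched = ce.build_transition_schedule("never_gdm", params, config, 32)
        sched = dataclasses.replace(sched, p_to_t2dm=np.zeros(sched.n_cycles))
        tr = ce.run_markov_trace(sched, config)
        assert he.chronic_costs(tr, params.costs, "base", config) == 0.0

    def test_microcosting_with_equal_rates_matches_flat_costing(self, params):
        cfg = ModelConfig(half_cycle_correction=False)
        sched = ce.build_transition_schedule("gdm", params, cfg, 32)
        tr = ce.run_markov_trace(sched, cfg)
        costs = dataclasses.replace(
            params.costs,
            t2dm_annual_cost_by_age=(AgeBandedCost(15, 85, 1234.0),),
            microcost_first_year=Uncertain(1234.0),
            microcost_subsequent_year=Uncertain(1234.0))
        flat = he.chronic_costs(tr, costs, "base", cfg)
        micro = he.chronic_costs(tr, costs, "s3_microcost_health", cfg)
        assert micro == pytest.approx(flat, rel=1e-12)


class TestQalys:
    def test_unit_utilities_reduce_to_discounted_life_years(self, params, config,
                                                            flat_utilities):
        sched = ce.build_transition_schedule("gdm", params, config, 27)
        tr = ce.run_markov_trace(sched, config)
        q = he.discounted_qalys(tr, flat_utilities, 27, config)
        assert q == pytest.approx(float(tr.life_years @ tr.discount), rel=1e-12)

    def test_multiplicative_adjustment_anchored_at_reference_band(self, params):
        # at age 30 the healthy utility equals the 0.95 anchor, so the T2DM
        # state utility is exactly the published 0.785
        u = params.utilities
        assert u.t2dm_at(np.array([30]))[0] == pytest.approx(0.95 * (0.785 / 0.95))
        assert u.t2dm_at(np.array([30]))[0] == pytest.approx(0.785)
        # elsewhere it scales with the age-specific healthy score
        assert u.t2dm_at(np.array([60]))[0] == pytest.approx(0.88 * 0.785 / 0.95)

    def test_zero_t2dm_utility_counts_healthy_years_only(self, params, config):
        utils = dataclasses.replace(params.utilities, t2dm_utility=Uncertain(0.0))
        sched = ce.build_transition_schedule("gdm", params, config, 27)
        tr = ce.run_markov_trace(sched, config)
        q = he.discounted_qalys(tr, utils, 27, config)
        expected = float((tr.healthy_years * utils.healthy_at(tr.ages)) @ tr.discount)
        assert q == pytest.approx(expected, rel=1e-12)


class TestIcer:
    @pytest.mark.parametrize("dc, dq, expected", [
        (-50.0, 0.035, he.DOMINANT),
        (100.0, 0.02, 5000.0),
        (100.0, -0.01, he.DOMINATED),
        (-100.0, -0.05, 2000.0),
        (100.0, 0.0, he.NO_QALY_DIFFERENCE),
    ])
    def test_labels_and_ratios(self, dc, dq, expected):
        assert he.compute_icer(dc, dq) == expected


class TestRoi:
    def test_published_base_case_arithmetic(self):
        inc = he.CostBreakdown(intervention=69_904_575, pregnancy=-25_187_141,
                               t2dm_management=-60_108_916)
        assert round(he.compute_roi(inc), 2) == 1.22
        inc_nicu = dataclasses.replace(inc, nicu_scn=-24_264_341)
        assert round(he.compute_roi(inc_nicu, include_nicu=True), 2) == 1.57

    def test_zero_savings(self):
        assert he.compute_roi(he.CostBreakdown(intervention=1000.0)) == 0.0

    def test_undefined_without_investment(self):
        with pytest.raises(ValueError):
            he.compute_roi(he.CostBreakdown(intervention=0.0))

    def test_decreasing_in_intervention_cost(self):
        inc = he.CostBreakdown(intervention=1e6, pregnancy=-5e5, t2dm_management=-7e5)
        rois = [he.compute_roi(dataclasses.replace(inc, intervention=c))
                for c in (1e6, 2e6, 4e6)]
        assert rois[0] > rois[1] > rois[2]


class TestEfficiencyFrontier:
    def test_strict_dominance(self):
        out = he.efficiency_frontier([(100.0, 1.0), (50.0, 2.0)])
        assert out["labels"] == ["dominated", "frontier"]

    def test_collinear_middle_stays_on_frontier(self):
        out = he.efficiency_frontier([(0.0, 0.0), (50.0, 1.0), (100.0, 2.0)])
        assert out["labels"] == ["frontier"] * 3

    def test_extended_dominance_textbook_triple(self):
        # incremental ICER 0->B is 100/1; segment B->C is 50/0.1 = 500: B stays.
        out = he.efficiency_frontier([(0.0, 0.0), (100.0, 1.0), (150.0, 1.1)])
        assert out["labels"] == ["frontier"] * 3
        # raise B's cost so its incremental ICER exceeds the next segment's
        out2 = he.efficiency_frontier([(0.0, 0.0), (140.0, 1.0), (150.0, 1.1)])
        assert out2["labels"][1] == "extendedly dominated"

    def test_total_healthcare_excludes_societal_addons(self):
        cb = he.CostBreakdown(intervention=1.0, pregnancy=2.0, nicu_scn=3.0,
                              t2dm_management=4.0, societal_addons=100.0)
        assert cb.total_healthcare == 10.0
        assert cb.total == 110.0
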