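import dataclasses

import numpy as np
import pytest

from gdmcea import ModelConfig
from gdmcea import cohort_engine as ce
from gdmcea.model_inputs import Uncertain
from gdmcea.synthetic_inputs import SynthSpec, generate_synthetic_bundle


def make_schedule(p_inc, p_dh=None, p_dd=None, rep_age=32):
    p_inc = np.asarray(p_inc, dtype=float)
    T = len(p_inc)
    z = np.zeros(T)
    return ce.TransitionSchedule(
        branch="gdm", representative_age=rep_age,
        ages=rep_age + np.arange(1, T + 1),
        p_to_t2dm=p_inc,
        p_death_no_t2dm=z if p_dh is None else np.asarray(p_dh, dtype=float),
        p_death_t2dm=z if p_dd is None else np.asarray(p_dd, dtype=float))


class TestPregnancyBranching:
    def test_intervention_splits_averted_fraction(self, params):
        cohort = dataclasses.replace(params.cohorts[0], gdm_prevalence=0.15)
        w = ce.pregnancy_branching(cohort, "intervention", 0.67).weights
        assert w["gdm"] == pytest.approx(0.1005)
        assert w["avoided_gdm"] == pytest.approx(0.0495)
        assert w["never_gdm"] == pytest.approx(0.85)

    def test_null_intervention_equals_usual_care(self, params):
        cohort = params.cohorts[2]
        wu = ce.pregnancy_branching(cohort, "usual_care", 0.67).weights
        wi = ce.pregnancy_branching(cohort, "intervention", 1.0).weights
        assert wi == pytest.approx(wu)
        assert wi["avoided_gdm"] == 0.0

    def test_zero_prevalence_all_never(self, params):
        cohort = dataclasses.replace(params.cohorts[0], gdm_prevalence=0.0)
        for arm in ("usual_care", "intervention"):
            w = ce.pregnancy_branching(cohort, arm, 0.67).weights
            assert w == {"gdm": 0.0, "avoided_gdm": 0.0, "never_gdm": 1.0}


class TestTransitionSchedule:
    def test_gdm_vs_never_rate_ratio_is_rr_original(self, params, config):
        g = ce.build_transition_schedule("gdm", params, config, 32)
        n = ce.build_transition_schedule("never_gdm", params, config, 32)
        rate_g = -np.log1p(-g.p_to_t2dm)
        rate_n = -np.log1p(-n.p_to_t2dm)
        assert rate_g / rate_n == pytest.approx(np.full(len(rate_g), 9.51), rel=1e-9)

    def test_scenario1_reverts_to_population_rate_after_10_years(self, params):
        cfg = ModelConfig(scenario="s1_10yr")
        g = ce.build_transition_schedule("gdm", params, cfg, 32)
        base = ce.build_transition_schedule("gdm", params, ModelConfig(), 32)
        i_total_12 = params.epi.at("t2dm_incidence_total", np.array([32 + 12]))[0]
        assert -np.log1p(-g.p_to_t2dm[11]) == pytest.approx(i_total_12, rel=1e-12)
        assert np.array_equal(g.p_to_t2dm[:10], base.p_to_t2dm[:10])
        assert (g.p_to_t2dm[10:] < base.p_to_t2dm[10:]).all()

    def test_avoided_branch_with_unit_rr_matches_never_gdm(self, params, config):
        a = ce.build_transition_schedule("avoided_gdm", params, config, 27)
        n = ce.build_transition_schedule("never_gdm", params, config, 27)
        assert np.array_equal(a.p_to_t2dm, n.p_to_t2dm)

    def test_branch_ordering_of_progression_risk(self, params, config):
        p2 = dataclasses.replace(params, rrs=dataclasses.replace(
            params.rrs, rr_t2dm_avoided_gdm=Uncertain(3.0)))
        scheds = {b: ce.build_transition_schedule(b, p2, config, 37) for b in ce.BRANCHES}
        assert (scheds["gdm"].p_to_t2dm >= scheds["avoided_gdm"].p_to_t2dm).all()
        assert (scheds["avoided_gdm"].p_to_t2dm >= scheds["never_gdm"].p_to_t2dm).all()


class TestMarkovTrace:
    def test_single_cycle_hand_computation(self, config):
        tr = ce.run_markov_trace(make_schedule([0.1]), config)
        assert tr.healthy[1] == pytest.approx(0.9)
        assert tr.t2dm[1] == pytest.approx(0.1)
        assert tr.dead[1] == pytest.approx(0.0)
        assert tr.new_t2dm_cases[0] == pytest.approx(0.1)

    def test_zero_probabilities_preserve_cohort(self):
        cfg = ModelConfig(half_cycle_correction=False, discount_rate=0.0)
        tr = ce.run_markov_trace(make_schedule(np.zeros(20)), cfg)
        assert tr.healthy[-1] == 1.0
        assert tr.life_years.sum() == pytest.approx(20.0)

    def test_occupancy_conservation_and_absorbing_death_random_schedules(self):
        rng = np.random.default_rng(42)
        cfg = ModelConfig()
        for _ in range(200):
            T = int(rng.integers(1, 70))
            tr = ce.run_markov_trace(make_schedule(
                rng.uniform(0, 1, T), rng.uniform(0, 1, T), rng.uniform(0, 1, T)), cfg)
            total = tr.healthy + tr.t2dm + tr.dead
            assert np.abs(total - 1.0).max() < 1e-12
            assert (np.diff(tr.dead) >= -1e-15).all()
            assert (tr.new_t2dm_cases >= 0).all()

    def test_probabilities_outside_unit_interval_rejected(self, config):
        with pytest.raises(ValueError):
            ce.run_markov_trace(make_schedule([1.2]), config)


class TestLifetimeOutcomes:
    def test_unit_utilities_make_qalys_equal_life_years(self, params, flat_utilities):
        cfg = ModelConfig(discount_rate=0.0)
        cohort = params.cohorts[3]
        sched = ce.build_transition_schedule("gdm", params, cfg, cohort.representative_age)
        traces = {b: ce.run_markov_trace(sched, cfg) for b in ce.BRANCHES}
        w = ce.pregnancy_branching(cohort, "usual_care", 0.67)
        out = ce.lifetime_outcomes(traces, w, cohort, flat_utilities, cfg)
        assert out.qalys == pytest.approx(out.years_of_life, rel=1e-12)
        assert out.qalys_disc == pytest.approx(out.years_of_life_disc, rel=1e-12)

    def test_two_cycle_discounting_geometric_sum(self, params, flat_utilities):
        cfg = ModelConfig(discount_rate=0.05, half_cycle_correction=False)
        cohort = dataclasses.replace(params.cohorts[0], n_births=1.0,
                                     preexisting_dm_prevalence=0.0, gdm_prevalence=0.0)
        tr = ce.run_markov_trace(make_schedule(np.zeros(2)), cfg)
        w = ce.pregnancy_branching(cohort, "usual_care", 0.67)
        out = ce.lifetime_outcomes({b: tr for b in ce.BRANCHES}, w, cohort,
                                   flat_utilities, cfg)
        assert out.years_of_life_disc == pytest.approx(1 / 1.05 + 1 / 1.05 ** 2, abs=1e-6)
        assert out.years_of_life_disc == pytest.approx(1.85941, abs=1e-5)

    def test_outcomes_linear_in_births(self, params, config):
        cohort = params.cohorts[2]
        double = dataclasses.replace(cohort, n_births=2 * cohort.n_births)
        sched = {b: ce.run_markov_trace(
            ce.build_transition_schedule(b, params, config, cohort.representative_age),
            config) for b in ce.BRANCHES}
        for arm in ("usual_care", "intervention"):
            w1 = ce.pregnancy_branching(cohort, arm, 0.67, costs=params.costs)
            o1 = ce.lifetime_outcomes(sched, w1, cohort, params.utilities, config)
            o2 = ce.lifetime_outcomes(sched, w1, double, params.utilities, config)
            for f in ("cases_gdm", "cases_t2dm", "qalys_disc", "years_of_life",
                      "nicu_scn_admissions"):
                assert getattr(o2, f) == pytest.approx(2 * getattr(o1, f), rel=1e-12)


class TestRunComparison:
    def test_null_intervention_with_zero_cost_gives_zero_increments(self, params, config):
        rrs = dataclasses.replace(params.rrs, rr_gdm_by_subgroup={
            **params.rrs.rr_gdm_by_subgroup, "base": Uncertain(1.0)})
        costs = dataclasses.replace(params.costs, intervention_cost_per_woman={
            **params.costs.intervention_cost_per_woman, "base": Uncertain(0.0)})
        res = ce.run_comparison(dataclasses.replace(params, rrs=rrs, costs=costs), config)
        assert res.delta_cost_total == 0.0
        assert res.delta_qalys == 0.0
        assert res.delta_cases_t2dm == 0.0

    def test_null_effect_with_positive_cost_charges_every_woman(self, params, config):
        rrs = dataclasses.replace(params.rrs, rr_gdm_by_subgroup={
            **params.rrs.rr_gdm_by_subgroup, "base": Uncertain(1.0)})
        res = ce.run_comparison(dataclasses.replace(params, rrs=rrs), config)
        assert res.delta_qalys == 0.0
        assert res.delta_cost_total == pytest.approx(228.0 * params.total_included_births,
                                                     rel=1e-12)

    def test_intervention_prevents_cases_on_synthetic_bundle(self):
        params = generate_synthetic_bundle(SynthSpec(rng_seed=7))
        res = ce.run_comparison(params, ModelConfig())
        uc = res.arms["usual_care"].outcomes
        iv = res.arms["intervention"].outcomes
        assert iv.cases_t2dm < uc.cases_t2dm
        assert iv.cases_gdm < uc.cases_gdm
        assert iv.qalys_disc > uc.qalys_disc

    def test_discounted_totals_bounded_by_undiscounted(self, params, config):
        res = ce.run_comparison(params, config)
        for arm in res.arms.values():
            assert arm.outcomes.years_of_life_disc < arm.outcomes.years_of_life
            assert arm.outcomes.qalys_disc < arm.outcomes.qalys
            assert arm.outcomes.qalys_disc <= arm.outcomes.years_of_life_disc
            assert arm.outcomes.years_with_t2dm_disc <= arm.outcomes.years_of_life_disc
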