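"""Decision tree and Markov cohort engine.

Each maternal age cohort passes through a decision node (usual care vs
intervention) and a pregnancy chance node that splits the cohort into three
branches: women who develop GDM, women whose GDM was averted by the
intervention, and women who never develop GDM. After birth every branch runs
a three-state Markov process (no T2DM / T2DM / dead) in one-year cycles
until age ``max_age``.

Cycle timing convention: pregnancy and birth events happen at t = 0 and are
not discounted; Markov cycle t (t = 1, 2, ...) spans attained ages
``representative_age + t - 1`` to ``representative_age + t`` and is
discounted by ``(1 + r)^-t``. Within a cycle, death is applied to the
no-T2DM state first and progression to T2DM is then applied to the
survivors; new T2DM cases are not exposed to the T2DM mortality rate in
their cycle of onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import health_economics, risk_engine
from .model_inputs import (MaternalCohort, ModelConfig, ParameterSet, UtilitySet,
                           validate_config)

__all__ = [
    "BRANCHES",
    "BranchWeights",
    "TransitionSchedule",
    "MarkovTrace",
    "CohortOutcomes",
    "DerivedRates",
    "derive_rates",
    "pregnancy_branching",
    "build_transition_schedule",
    "run_markov_trace",
    "lifetime_outcomes",
    "run_comparison",
]

BRANCHES = ("gdm", "avoided_gdm", "never_gdm")

#: scenario 1 — number of post-birth years the elevated GDM-group T2DM risk persists
S1_ELEVATED_RISK_YEARS = 10


@dataclass(frozen=True)
class BranchWeights:
    """Chance-node weights and perinatal event probabilities for one arm."""

    arm: str
    weights: dict[str, float]
    event_probs: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"branch weights sum to {total}, expected 1")
        if any(w < -1e-12 for w in self.weights.values()):
            raise ValueError("branch weights must be non-negative")


@dataclass(frozen=True)
class TransitionSchedule:
    """Per-cycle transition probabilities for one branch of one cohort."""

    branch: str
    representative_age: int
    ages: np.ndarray          # attained age at the end of each cycle, length T
    p_to_t2dm: np.ndarray
    p_death_no_t2dm: np.ndarray
    p_death_t2dm: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.ages)


@dataclass(frozen=True)
class MarkovTrace:
    """State occupancy and flows for a branch cohort of size 1.

    Occupancy arrays have length T+1 (index 0 = entry at birth); flow and
    person-year arrays have length T, indexed by cycle 1..T.
    """

    schedule: TransitionSchedule
    healthy: np.ndarray
    t2dm: np.ndarray
    dead: np.ndarray
    new_t2dm_cases: np.ndarray
    life_years: np.ndarray
    healthy_years: np.ndarray
    t2dm_years: np.ndarray
    discount: np.ndarray

    @property
    def ages(self) -> np.ndarray:
        return self.schedule.ages


@dataclass
class CohortOutcomes:
    """Birth-count-scaled, branch-weighted outcomes for one cohort and arm."""

    cases_gdm: float = 0.0
    cases_t2dm: float = 0.0
    years_of_life: float = 0.0
    years_of_life_disc: float = 0.0
    years_with_t2dm: float = 0.0
    years_with_t2dm_disc: float = 0.0
    qalys: float = 0.0
    qalys_disc: float = 0.0
    nicu_scn_admissions: float = 0.0

    def __iadd__(self, other: "CohortOutcomes") -> "CohortOutcomes":
        for f in self.__dataclass_fields__:
            setattr(self, f, getattr(self, f) + getattr(other, f))
        return self


@dataclass(frozen=True)
class DerivedRates:
    """Single-year rate schedules shared by every cohort in one model run."""

    ages: np.ndarray
    i_total: np.ndarray
    i_gdm: np.ndarray
    i_no_gdm: np.ndarray
    m_no_t2dm: np.ndarray
    m_t2dm: np.ndarray

    def at(self, name: str, ages: np.ndarray) -> np.ndarray:
        idx = np.clip(np.asarray(ages) - self.ages[0], 0, len(self.ages) - 1)
        return getattr(self, name)[idx]


def derive_rates(params: ParameterSet) -> DerivedRates:
    """Derive group incidences and state-specific mortality from the epi table."""
    epi = params.epi
    rr = params.rrs.rr_t2dm_after_gdm.mean
    i_gdm, i_no_gdm = risk_engine.split_t2dm_incidence(
        epi.t2dm_incidence_total, epi.gdm_prevalence_population, rr)

    ages = epi.ages
    young = ages < risk_engine.T2DM_MORTALITY_MIN_AGE
    prev = epi.t2dm_prevalence
    # counts per capita: all-cause deaths minus T2DM deaths over the non-T2DM pool
    num = epi.all_cause_mortality - epi.t2dm_mortality * prev
    if np.any(num[~young] < 0):
        bad = ages[~young][num[~young] < 0]
        raise ValueError(f"T2DM deaths exceed all-cause deaths at ages {bad.tolist()}")
    with np.errstate(divide="ignore", invalid="ignore"):
        m_no = np.where(young, epi.all_cause_mortality, num / (1.0 - prev))
    m_t2dm = np.where(young, epi.all_cause_mortality, epi.t2dm_mortality)
    return DerivedRates(ages=ages, i_total=epi.t2dm_incidence_total, i_gdm=i_gdm,
                        i_no_gdm=i_no_gdm, m_no_t2dm=m_no, m_t2dm=m_t2dm)


def pregnancy_branching(cohort: MaternalCohort, arm: str, rr_gdm_intervention: float,
                        costs=None) -> BranchWeights:
    """Chance-node weights for one cohort and arm.

    Under usual care a fraction ``q`` (the cohort GDM prevalence) develops
    GDM. Under intervention the GDM probability becomes ``q * rr``; the
    remainder ``q * (1 - rr)`` are women whose GDM was averted.
    """
    if arm not in ("usual_care", "intervention"):
        raise ValueError(f"unknown arm {arm!r}")
    q = cohort.gdm_prevalence
    rr = float(rr_gdm_intervention)
    if not 0.0 < rr <= 1.5:
        raise ValueError(f"rr_gdm_intervention={rr} outside (0, 1.5]")
    if arm == "usual_care":
        weights = {"gdm": q, "avoided_gdm": 0.0, "never_gdm": 1.0 - q}
    else:
        if q * rr > 1.0:
            raise ValueError("q * rr exceeds 1")
        weights = {"gdm": q * rr, "avoided_gdm": q * max(1.0 - rr, 0.0),
                   "never_gdm": 1.0 - q * rr - q * max(1.0 - rr, 0.0)}
    event_probs = {}
    if costs is not None:
        for b in BRANCHES:
            status = "gdm" if b == "gdm" else "no_gdm"
            event_probs[b] = {"caesarean": costs.p_caesarean[status],
                              "induction": costs.p_induction[status],
                              "nicu_scn": costs.p_nicu_scn[status]}
    return BranchWeights(arm=arm, weights=weights, event_probs=event_probs)


def build_transition_schedule(branch: str, params: ParameterSet, config: ModelConfig,
                              representative_age: int,
                              derived: DerivedRates | None = None) -> TransitionSchedule:
    """Per-cycle probabilities for one branch from birth to ``max_age``."""
    if branch not in BRANCHES:
        raise ValueError(f"unknown branch {branch!r}")
    if derived is None:
        derived = derive_rates(params)
    T = config.max_age - representative_age
    if T <= 0:
        raise ValueError("representative_age must be below max_age")
    cycles = np.arange(1, T + 1)
    ages = representative_age + cycles

    if branch == "gdm":
        inc = derived.at("i_gdm", ages).copy()
        if config.scenario == "s1_10yr":
            # elevated risk persists 10 years post-birth, then reverts to the
            # general female population rate
            inc[cycles > S1_ELEVATED_RISK_YEARS] = \
                derived.at("i_total", ages)[cycles > S1_ELEVATED_RISK_YEARS]
    elif branch == "never_gdm":
        inc = derived.at("i_no_gdm", ages)
    else:  # avoided_gdm
        inc = params.rrs.rr_t2dm_avoided_gdm.mean * derived.at("i_no_gdm", ages)

    dt = config.cycle_length
    return TransitionSchedule(
        branch=branch, representative_age=representative_age, ages=ages,
        p_to_t2dm=risk_engine.rate_to_probability(inc, dt),
        p_death_no_t2dm=risk_engine.rate_to_probability(derived.at("m_no_t2dm", ages), dt),
        p_death_t2dm=risk_engine.rate_to_probability(derived.at("m_t2dm", ages), dt),
    )


def run_markov_trace(schedule: TransitionSchedule, config: ModelConfig) -> MarkovTrace:
    """Run the three-state occupancy recursion for one branch cohort of size 1."""
    p_inc, p_dh, p_dd = schedule.p_to_t2dm, schedule.p_death_no_t2dm, schedule.p_death_t2dm
    for name, p in (("p_to_t2dm", p_inc), ("p_death_no_t2dm", p_dh), ("p_death_t2dm", p_dd)):
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError(f"{name} outside [0,1]")
    T = schedule.n_cycles

    # healthy state: survive death then escape progression, each cycle
    stay_healthy = (1.0 - p_dh) * (1.0 - p_inc)
    healthy = np.concatenate(([1.0], np.cumprod(stay_healthy)))
    new_cases = healthy[:-1] * (1.0 - p_dh) * p_inc

    # T2DM state: survivors of previous cycles plus this cycle's entrants.
    # Entrants in cycle s face T2DM mortality from cycle s+1 onward, so with
    # C[t] = prod_{u<=t}(1 - p_dd[u]): t2dm[t] = sum_{s<=t} new_cases[s] * C[t]/C[s]
    C = np.cumprod(1.0 - p_dd)
    if C[-1] > 1e-250:
        t2dm = C * np.cumsum(new_cases / C)
    else:  # a p_death_t2dm at (or numerically near) 1: explicit recursion
        t2dm = np.empty(T)
        prev = 0.0
        for t in range(T):
            prev = prev * (1.0 - p_dd[t]) + new_cases[t]
            t2dm[t] = prev
    dead = 1.0 - healthy[1:] - t2dm

    healthy_full = healthy
    t2dm_full = np.concatenate(([0.0], t2dm))
    dead_full = np.concatenate(([0.0], dead))

    if config.half_cycle_correction:
        healthy_years = 0.5 * (healthy_full[:-1] + healthy_full[1:])
        t2dm_years = 0.5 * (t2dm_full[:-1] + t2dm_full[1:])
    else:
        healthy_years = healthy_full[1:].copy()
        t2dm_years = t2dm_full[1:].copy()
    life_years = healthy_years + t2dm_years
    discount = (1.0 + config.discount_rate) ** -np.arange(1, T + 1, dtype=float)

    return MarkovTrace(schedule=schedule, healthy=healthy_full, t2dm=t2dm_full,
                       dead=dead_full, new_t2dm_cases=new_cases, life_years=life_years,
                       healthy_years=healthy_years, t2dm_years=t2dm_years,
                       discount=discount)


def lifetime_outcomes(traces: dict[str, MarkovTrace], weights: BranchWeights,
                      cohort: MaternalCohort, utilities: UtilitySet,
                      config: ModelConfig) -> CohortOutcomes:
    """Branch-weighted, birth-count-scaled health outcomes for one cohort/arm."""
    n = cohort.included_births
    out = CohortOutcomes()
    out.cases_gdm = n * weights.weights["gdm"]
    for branch, w in weights.weights.items():
        if w == 0.0:
            continue
        tr = traces[branch]
        scale = n * w
        disc = tr.discount
        u_h = utilities.healthy_at(tr.ages)
        u_d = utilities.t2dm_at(tr.ages)
        qaly_cycle = tr.healthy_years * u_h + tr.t2dm_years * u_d
        out.cases_t2dm += scale * tr.new_t2dm_cases.sum()
        out.years_of_life += scale * tr.life_years.sum()
        out.years_of_life_disc += scale * float(tr.life_years @ disc)
        out.years_with_t2dm += scale * tr.t2dm_years.sum()
        out.years_with_t2dm_disc += scale * float(tr.t2dm_years @ disc)
        out.qalys += scale * qaly_cycle.sum()
        out.qalys_disc += scale * float(qaly_cycle @ disc)
        if weights.event_probs:
            out.nicu_scn_admissions += scale * weights.event_probs[branch]["nicu_scn"]
    return out


def run_comparison(params: ParameterSet, config: ModelConfig
                   ) -> "health_economics.ComparisonResult":
    """Run both arms over all cohorts and assemble incremental results."""
    bad = validate_config(config)
    if bad:
        raise ValueError("invalid config:\n  " + "\n  ".join(bad))
    derived = derive_rates(params)
    rr_gdm = params.rrs.rr_gdm_by_subgroup[config.subgroup].mean
    rr_avoided = params.rrs.rr_t2dm_avoided_gdm.mean

    arm_outcomes = {a: CohortOutcomes() for a in ("usual_care", "intervention")}
    arm_costs = {a: health_economics.CostBreakdown() for a in ("usual_care", "intervention")}

    for cohort in params.cohorts:
        traces = {}
        traces["gdm"] = run_markov_trace(
            build_transition_schedule("gdm", params, config, cohort.representative_age, derived),
            config)
        traces["never_gdm"] = run_markov_trace(
            build_transition_schedule("never_gdm", params, config, cohort.representative_age,
                                      derived), config)
        if rr_avoided == 1.0:
            traces["avoided_gdm"] = traces["never_gdm"]
        else:
            traces["avoided_gdm"] = run_markov_trace(
                build_transition_schedule("avoided_gdm", params, config,
                                          cohort.representative_age, derived), config)
        chronic_per_branch = {
            b: health_economics.chronic_costs(traces[b], params.costs, config.scenario, config)
            for b in BRANCHES}
        societal_per_branch = {
            b: health_economics.societal_addon_costs(traces[b], params.costs, config)
            for b in BRANCHES} if config.scenario == "s4_microcost_societal" else None

        for arm in ("usual_care", "intervention"):
            w = pregnancy_branching(cohort, arm, rr_gdm, costs=params.costs)
            arm_outcomes[arm] += lifetime_outcomes(traces, w, cohort, params.utilities, config)
            cb = health_economics.perinatal_costs(w, cohort, params.costs,
                                                  config.include_nicu_scn)
            n = cohort.included_births
            cb.t2dm_management = n * sum(w.weights[b] * chronic_per_branch[b] for b in BRANCHES)
            if societal_per_branch is not None:
                cb.societal_addons = n * sum(w.weights[b] * societal_per_branch[b]
                                             for b in BRANCHES)
            if arm == "intervention":
                cb.intervention = n * params.costs.intervention_cost_per_woman[config.subgroup].mean
            arm_costs[arm] += cb

    return health_economics.assemble_comparison(
        arm_outcomes, arm_costs, n_women=params.total_included_births, config=config)
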