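"""Costing, QALYs, ICER/dominance, ROI and the efficiency frontier.

All monetary quantities are AU$ in a single price year. Perinatal costs are
incurred at t = 0 and are not discounted; chronic T2DM management costs and
QALYs accrue over Markov cycles and are discounted at the configured annual
rate. Two cost perspectives are supported: healthcare (base case and
scenarios 1-3) and societal (scenario 4, which adds direct non-health costs
and government income subsidies per T2DM case-year).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_inputs import CostSet, MaternalCohort, ModelConfig, UtilitySet

__all__ = [
    "CostBreakdown",
    "ComparisonResult",
    "ArmResult",
    "intervention_unit_cost",
    "perinatal_costs",
    "chronic_costs",
    "societal_addon_costs",
    "discounted_qalys",
    "compute_icer",
    "compute_roi",
    "efficiency_frontier",
    "assemble_comparison",
    "DOMINANT",
    "DOMINATED",
    "NO_QALY_DIFFERENCE",
]

DOMINANT = "Dominant"
DOMINATED = "Dominated"
NO_QALY_DIFFERENCE = "no QALY difference"


def intervention_unit_cost(annual_salary: float = 82_600.0, oncost_rate: float = 0.15,
                           fixed_cost_rate: float = 0.20, caseload: float = 500.0) -> float:
    """Per-woman cost of delivering the intervention.

    One health coach on ``annual_salary`` with salary on-costs and a fixed
    cost allowance (training, facilities, IT, administration), spread over an
    annual caseload. The default inputs give AU$228 per woman.
    """
    if caseload <= 0:
        raise ValueError("caseload must be positive")
    return annual_salary * (1.0 + oncost_rate) * (1.0 + fixed_cost_rate) / caseload


@dataclass
class CostBreakdown:
    """Discounted AU$ totals by category for one arm (or increments)."""

    intervention: float = 0.0
    pregnancy: float = 0.0
    nicu_scn: float = 0.0
    t2dm_management: float = 0.0
    societal_addons: float = 0.0

    @property
    def total_healthcare(self) -> float:
        """Healthcare-perspective total (societal add-ons excluded)."""
        return self.intervention + self.pregnancy + self.nicu_scn + self.t2dm_management

    @property
    def total(self) -> float:
        return self.total_healthcare + self.societal_addons

    def __iadd__(self, other: "CostBreakdown") -> "CostBreakdown":
        for f in self.__dataclass_fields__:
            setattr(self, f, getattr(self, f) + getattr(other, f))
        return self

    def __sub__(self, other: "CostBreakdown") -> "CostBreakdown":
        return CostBreakdown(**{f: getattr(self, f) - getattr(other, f)
                                for f in self.__dataclass_fields__})


def perinatal_costs(weights, cohort: MaternalCohort, costs: CostSet,
                    include_nicu: bool) -> CostBreakdown:
    """Expected pregnancy/birth costs for one cohort and arm (t = 0, undiscounted).

    The GDM branch incurs GDM antenatal care plus GDM-specific birth-event
    probabilities; the averted-GDM and never-GDM branches use normoglycaemic
    probabilities.
    """
    n = cohort.included_births
    out = CostBreakdown()
    for branch, w in weights.weights.items():
        if w == 0.0:
            continue
        status = "gdm" if branch == "gdm" else "no_gdm"
        events = (costs.p_caesarean[status] * costs.caesarean_cost.mean
                  + costs.p_induction[status] * costs.induction_cost.mean)
        antenatal = costs.antenatal_gdm_cost.mean if branch == "gdm" else 0.0
        out.pregnancy += n * w * (antenatal + events)
        if include_nicu:
            out.nicu_scn += n * w * costs.p_nicu_scn[status] * costs.nicu_admission_cost.mean
    return out


def chronic_costs(trace, costs: CostSet, scenario: str, config: ModelConfig) -> float:
    """Discounted lifetime T2DM management cost per woman in one branch.

    Base case (and scenarios 1-2): the age-specific attributed annual cost is
    applied to T2DM state-years. Micro-costing scenarios 3-4: new cases incur
    the newly-diagnosed annual cost in their cycle of onset and prevalent
    cases the known-diabetes cost thereafter.
    """
    disc = trace.discount
    if scenario in ("s3_microcost_health", "s4_microcost_societal"):
        prevalent = trace.t2dm[1:] - trace.new_t2dm_cases  # continuing cases at cycle end
        per_cycle = (trace.new_t2dm_cases * costs.microcost_first_year.mean
                     + prevalent * costs.microcost_subsequent_year.mean)
    else:
        per_cycle = trace.t2dm_years * costs.t2dm_annual_cost_at(trace.ages)
    return float(per_cycle @ disc)


def societal_addon_costs(trace, costs: CostSet, config: ModelConfig) -> float:
    """Discounted societal add-on cost per woman (scenario 4 only)."""
    rate = costs.societal_direct_nonhealth.mean + costs.societal_income_subsidy.mean
    return float((trace.t2dm_years * rate) @ trace.discount)


def discounted_qalys(trace, utilities: UtilitySet, representative_age: int,
                     config: ModelConfig) -> float:
    """Discounted QALYs per woman in one branch."""
    u_h = utilities.healthy_at(trace.ages)
    u_d = utilities.t2dm_at(trace.ages)
    per_cycle = trace.healthy_years * u_h + trace.t2dm_years * u_d
    return float(per_cycle @ trace.discount)


def compute_icer(delta_cost: float, delta_qaly: float) -> float | str:
    """ICER value or dominance label for an (incremental cost, incremental QALY) pair."""
    if delta_qaly == 0.0:
        return NO_QALY_DIFFERENCE
    if delta_cost < 0.0 and delta_qaly > 0.0:
        return DOMINANT
    if delta_cost > 0.0 and delta_qaly < 0.0:
        return DOMINATED
    return delta_cost / delta_qaly


def compute_roi(increments: CostBreakdown, include_nicu: bool = False,
                include_societal: bool = False) -> float:
    """Return on investment: non-intervention cost savings per intervention dollar.

    Savings are the negated incremental category costs (pregnancy, T2DM
    management, optionally NICU/SCN and societal add-ons).
    """
    invested = increments.intervention
    if invested <= 0.0:
        raise ValueError("ROI undefined without a positive intervention cost")
    savings = -(increments.pregnancy + increments.t2dm_management)
    if include_nicu:
        savings += -increments.nicu_scn
    if include_societal:
        savings += -increments.societal_addons
    return savings / invested


def efficiency_frontier(strategies: list[tuple[float, float]]) -> dict:
    """Dominance classification of strategies given (Δcost, ΔQALY) vs a comparator.

    Returns ``{"labels": [...], "frontier": [indices in increasing QALY order]}``
    where each label is ``"frontier"``, ``"dominated"`` or
    ``"extendedly dominated"``.
    """
    if len(strategies) < 2:
        raise ValueError("need at least 2 strategies")
    n = len(strategies)
    labels = ["frontier"] * n
    # strict dominance: another strategy is at least as effective and cheaper,
    # or more effective and no more costly
    for i, (ci, qi) in enumerate(strategies):
        for j, (cj, qj) in enumerate(strategies):
            if i == j:
                continue
            if (qj >= qi and cj < ci) or (qj > qi and cj <= ci):
                labels[i] = "dominated"
                break
    # extended dominance: on the remaining set ordered by QALY, remove points
    # whose incremental ICER exceeds that of the next segment
    def _frontier(cands):
        cands = sorted(cands, key=lambda i: (strategies[i][1], strategies[i][0]))
        changed = True
        while changed and len(cands) > 2:
            changed = False
            for k in range(1, len(cands) - 1):
                a, b, c = cands[k - 1], cands[k], cands[k + 1]
                (ca, qa), (cb, qb), (cc, qc) = (strategies[i] for i in (a, b, c))
                icer_ab = (cb - ca) / (qb - qa) if qb != qa else np.inf
                icer_bc = (cc - cb) / (qc - qb) if qc != qb else np.inf
                if icer_ab > icer_bc:
                    labels[b] = "extendedly dominated"
                    cands.pop(k)
                    changed = True
                    break
        return cands

    remaining = [i for i in range(n) if labels[i] == "frontier"]
    frontier = _frontier(remaining)
    return {"labels": labels, "frontier": frontier}


@dataclass
class ArmResult:
    outcomes: "object"
    costs: CostBreakdown


@dataclass
class ComparisonResult:
    """Arm-level and incremental lifetime outcomes for one model configuration."""

    arms: dict[str, ArmResult]
    n_women: float
    config: ModelConfig
    delta: CostBreakdown = field(default_factory=CostBreakdown)
    delta_qalys: float = 0.0
    delta_cases_gdm: float = 0.0
    delta_cases_t2dm: float = 0.0
    delta_years_of_life_disc: float = 0.0
    delta_years_with_t2dm_disc: float = 0.0
    delta_nicu_admissions: float = 0.0
    icer: float | str = NO_QALY_DIFFERENCE
    roi: float = float("nan")

    @property
    def delta_cost_total(self) -> float:
        return self.delta.total_healthcare if not self._societal else self.delta.total

    @property
    def _societal(self) -> bool:
        return self.config.scenario == "s4_microcost_societal"

    @property
    def delta_cost_per_woman(self) -> float:
        return self.delta_cost_total / self.n_women

    @property
    def delta_qalys_per_woman(self) -> float:
        return self.delta_qalys / self.n_women


def assemble_comparison(arm_outcomes: dict, arm_costs: dict, n_women: float,
                        config: ModelConfig) -> ComparisonResult:
    """Combine per-arm outcomes and costs into incremental results."""
    res = ComparisonResult(
        arms={a: ArmResult(arm_outcomes[a], arm_costs[a]) for a in arm_outcomes},
        n_women=n_women, config=config)
    oi, ou = arm_outcomes["intervention"], arm_outcomes["usual_care"]
    res.delta = arm_costs["intervention"] - arm_costs["usual_care"]
    res.delta_qalys = oi.qalys_disc - ou.qalys_disc
    res.delta_cases_gdm = oi.cases_gdm - ou.cases_gdm
    res.delta_cases_t2dm = oi.cases_t2dm - ou.cases_t2dm
    res.delta_years_of_life_disc = oi.years_of_life_disc - ou.years_of_life_disc
    res.delta_years_with_t2dm_disc = oi.years_with_t2dm_disc - ou.years_with_t2dm_disc
    res.delta_nicu_admissions = oi.nicu_scn_admissions - ou.nicu_scn_admissions
    res.icer = compute_icer(res.delta_cost_total, res.delta_qalys)
    if res.delta.intervention > 0:
        res.roi = compute_roi(res.delta, include_nicu=config.include_nicu_scn,
                              include_societal=res._societal)
    return res
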