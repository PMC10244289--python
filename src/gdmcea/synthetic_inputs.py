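"""Reference parameter fixture and synthetic bundle generation.

:func:`load_reference_fixture` returns the packaged base-case parameter set:
the published point estimates and intervals (relative risks, utilities, the
AU$228 intervention unit cost, the 0.65% population GDM prevalence) verbatim,
with the remaining schedules — age-banded births, GDM prevalence by maternal
age, single-year T2DM incidence, mortality and cost schedules — filled by
synthetic stand-ins that reproduce the statistical shape of the Australian
registry sources (age-increasing GDM prevalence and T2DM incidence,
Gompertz-like mortality) at realistic magnitudes. Per-table provenance is
recorded on the returned :class:`~gdmcea.model_inputs.ParameterSet`.

:func:`generate_synthetic_bundle` draws randomised variants of those
schedules for testing, under a seed so every bundle is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .model_inputs import (AgeBandedCost, CostSet, EpiTable, MaternalCohort,
                           ParameterSet, RelativeRiskSet, Uncertain, UtilityBand,
                           UtilitySet, validate_parameters)

__all__ = ["SynthSpec", "generate_synthetic_bundle", "load_reference_fixture",
           "reference_bundle_path"]

AGE_MIN, AGE_MAX = 15, 85

_COHORT_BANDS = ((15, 19), (20, 24), (25, 29), (30, 34), (35, 39), (40, 44), (45, 49))
_BIRTH_SHARES = (0.025, 0.120, 0.270, 0.346, 0.190, 0.045, 0.004)
_GDM_PREVALENCE = (0.060, 0.080, 0.100, 0.130, 0.170, 0.215, 0.250)
_PREEXISTING_DM = (0.002, 0.004, 0.007, 0.010, 0.015, 0.025, 0.035)

_UTILITY_BANDS = (("18-24", 18, 24, 0.95, 0.92, 0.98),
                  ("25-34", 25, 34, 0.95, 0.90, 0.99),
                  ("35-44", 35, 44, 0.91, 0.86, 0.96),
                  ("45-54", 45, 54, 0.87, 0.81, 0.93),
                  ("55-64", 55, 64, 0.88, 0.82, 0.94),
                  ("65-74", 65, 74, 0.87, 0.80, 0.94),
                  ("75+", 75, 120, 0.82, 0.74, 0.90))


@dataclass(frozen=True)
class IncidenceShape:
    """Logistic-in-age T2DM incidence: plateau / (1 + exp(-slope*(age - midpoint)))."""

    plateau: float = 0.012
    midpoint: float = 58.0
    slope: float = 0.09

    def at(self, ages: np.ndarray) -> np.ndarray:
        return self.plateau / (1.0 + np.exp(-self.slope * (np.asarray(ages) - self.midpoint)))


@dataclass(frozen=True)
class MortalityShape:
    """Gompertz all-cause female mortality with a proportional T2DM excess."""

    baseline: float = 1.2e-4     # rate at the anchor age
    age_slope: float = 0.0946    # log-rate increase per year of age
    anchor_age: float = 15.0
    t2dm_excess: float = 1.8     # hazard ratio for prevalent T2DM, ages >= 40

    def all_cause(self, ages: np.ndarray) -> np.ndarray:
        if self.baseline <= 0 or self.age_slope < 0:
            raise ValueError("Gompertz baseline must be > 0 and slope >= 0")
        return self.baseline * np.exp(self.age_slope * (np.asarray(ages) - self.anchor_age))


@dataclass(frozen=True)
class SynthSpec:
    rng_seed: int = 0
    total_births: float = 306_600.0
    gdm_prevalence_curve: tuple[float, ...] = _GDM_PREVALENCE
    incidence_shape: IncidenceShape = field(default_factory=IncidenceShape)
    mortality_shape: MortalityShape = field(default_factory=MortalityShape)
    cost_scales: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.05


def _reference_rrs() -> RelativeRiskSet:
    return RelativeRiskSet(
        rr_t2dm_after_gdm=Uncertain(9.51, 7.14, 12.67, "lognormal"),
        rr_gdm_by_subgroup={
            "base": Uncertain(0.67, 0.58, 0.77, "lognormal"),
            "diet": Uncertain(0.66, 0.50, 0.85, "lognormal"),
            "pa": Uncertain(0.62, 0.50, 0.77, "lognormal"),
            "diet_pa": Uncertain(0.75, 0.58, 0.97, "lognormal"),
        },
        rr_t2dm_avoided_gdm=Uncertain(1.0),
    )


def _reference_utilities() -> UtilitySet:
    bands = tuple(UtilityBand(label, lo, hi, Uncertain(m, l, u, "beta"))
                  for label, lo, hi, m, l, u in _UTILITY_BANDS)
    return UtilitySet(healthy_by_band=bands,
                      t2dm_utility=Uncertain(0.785, 0.68, 0.89, "beta"),
                      adjustment_mode="multiplicative",
                      reference_healthy_utility=0.95)


def _reference_costs(scales: dict[str, float] | None = None) -> CostSet:
    s = {"perinatal": 1.0, "t2dm": 1.0, "intervention": 1.0, **(scales or {})}
    g = "gamma"
    return CostSet(
        intervention_cost_per_woman={
            "base": Uncertain(228.0 * s["intervention"], family=g),
            "diet": Uncertain(177.0 * s["intervention"], family=g),
            "pa": Uncertain(197.0 * s["intervention"], family=g),
            "diet_pa": Uncertain(228.0 * s["intervention"], family=g),
        },
        antenatal_gdm_cost=Uncertain(1200.0 * s["perinatal"], family=g),
        caesarean_cost=Uncertain(14_000.0 * s["perinatal"], family=g),
        induction_cost=Uncertain(4_000.0 * s["perinatal"], family=g),
        nicu_admission_cost=Uncertain(14_000.0 * s["perinatal"], family=g),
        p_caesarean={"gdm": 0.37, "no_gdm": 0.33},
        p_induction={"gdm": 0.44, "no_gdm": 0.38},
        p_nicu_scn={"gdm": 0.306, "no_gdm": 0.17},
        t2dm_annual_cost_by_age=tuple(
            AgeBandedCost(lo, hi, c * s["t2dm"]) for lo, hi, c in
            ((15, 39, 950.0), (40, 49, 1100.0), (50, 59, 1250.0),
             (60, 69, 1400.0), (70, 79, 1550.0), (80, 85, 1650.0))),
        microcost_first_year=Uncertain(3300.0 * s["t2dm"], family=g),
        microcost_subsequent_year=Uncertain(1900.0 * s["t2dm"], family=g),
        societal_direct_nonhealth=Uncertain(1650.0 * s["t2dm"], family=g),
        societal_income_subsidy=Uncertain(2500.0 * s["t2dm"], family=g),
    )


def _build_epi(incidence: IncidenceShape, mortality: MortalityShape) -> EpiTable:
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    m_all = mortality.all_cause(ages)
    t2dm_prev = 0.16 / (1.0 + np.exp(-0.10 * (ages - 60)))
    m_t2dm = np.where(ages >= 40, mortality.t2dm_excess * m_all, m_all)
    # population: a cohort of 160k women per single year of age thinned by
    # cumulative all-cause mortality
    surv = np.exp(-np.concatenate(([0.0], np.cumsum(m_all[:-1]))))
    return EpiTable(age_min=AGE_MIN, age_max=AGE_MAX,
                    t2dm_incidence_total=incidence.at(ages),
                    all_cause_mortality=m_all, t2dm_mortality=m_t2dm,
                    t2dm_prevalence=t2dm_prev,
                    population=np.round(160_000.0 * surv),
                    gdm_prevalence_population=0.0065)


def _build_cohorts(total_births: float, gdm_curve, shares=_BIRTH_SHARES,
                   preexisting=_PREEXISTING_DM) -> tuple[MaternalCohort, ...]:
    if len(gdm_curve) != len(_COHORT_BANDS):
        raise ValueError(f"gdm_prevalence_curve must have {len(_COHORT_BANDS)} values")
    cohorts = []
    for (lo, hi), share, q, pre in zip(_COHORT_BANDS, shares, gdm_curve, preexisting):
        cohorts.append(MaternalCohort(
            band_label=f"{lo}-{hi}", age_low=lo, age_high=hi,
            representative_age=(lo + hi) // 2, n_births=float(round(total_births * share)),
            gdm_prevalence=float(q), preexisting_dm_prevalence=pre))
    return tuple(cohorts)


def load_reference_fixture() -> ParameterSet:
    """The packaged base-case parameter set (see module docstring)."""
    params = ParameterSet(
        cohorts=_build_cohorts(306_600.0, _GDM_PREVALENCE),
        epi=_build_epi(IncidenceShape(), MortalityShape()),
        rrs=_reference_rrs(),
        utilities=_reference_utilities(),
        costs=_reference_costs(),
        provenance={
            "cohorts": "synthetic",
            "epi": "synthetic",
            "relative_risks": "fixture",
            "utilities": "fixture",
            "costs.intervention_cost_base": "fixture",
            "costs.other": "synthetic",
        },
    )
    violations = validate_parameters(params)
    if violations:  # pragma: no cover - fixture is static
        raise RuntimeError("reference fixture invalid: " + "; ".join(violations))
    return params


def reference_bundle_path() -> str:
    """Filesystem path of the packaged reference bundle directory."""
    return str(resources.files("gdmcea").joinpath("data", "reference"))


def generate_synthetic_bundle(spec: SynthSpec) -> ParameterSet:
    """Draw a randomised but structurally valid parameter bundle.

    Noise is applied multiplicatively (log-normal, relative SD ``noise_sd``)
    in ways that preserve the qualitative structure the model assumes: GDM
    prevalence stays strictly increasing over maternal age bands (noise on
    the band-to-band increments), and incidence/mortality curves stay
    monotone over ages 40-85 (noise on the shape parameters, not per age).
    """
    if spec.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(spec.rng_seed)
    sd = spec.noise_sd

    def jitter(n=None):
        if sd == 0.0:
            return 1.0 if n is None else np.ones(n)
        return np.exp(rng.normal(-0.5 * sd ** 2, sd, size=n))

    curve = np.asarray(spec.gdm_prevalence_curve, dtype=float)
    if np.any(curve <= 0) or np.any(np.diff(curve) <= 0):
        raise ValueError("gdm_prevalence_curve must be positive and strictly increasing")
    increments = np.diff(np.concatenate(([0.0], curve))) * jitter(len(curve))
    gdm_curve = np.minimum(np.cumsum(increments), 0.95)

    shares = np.asarray(_BIRTH_SHARES) * jitter(len(_BIRTH_SHARES))
    shares /= shares.sum()

    inc = spec.incidence_shape
    inc = replace(inc, plateau=inc.plateau * float(jitter()),
                  slope=inc.slope * float(jitter()))
    mort = spec.mortality_shape
    if mort.baseline <= 0:
        raise ValueError("Gompertz baseline must be positive")
    mort = replace(mort, baseline=mort.baseline * float(jitter()),
                   age_slope=mort.age_slope * float(jitter()))

    scales = dict(spec.cost_scales)
    for key in ("perinatal", "t2dm", "intervention"):
        scales[key] = scales.get(key, 1.0) * float(jitter())

    params = ParameterSet(
        cohorts=_build_cohorts(spec.total_births, gdm_curve, shares),
        epi=_build_epi(inc, mort),
        rrs=_reference_rrs(),
        utilities=_reference_utilities(),
        costs=_reference_costs(scales),
        provenance={"cohorts": "synthetic", "epi": "synthetic",
                    "relative_risks": "fixture", "utilities": "fixture",
                    "costs": "synthetic"},
    )
    violations = validate_parameters(params)
    if violations:
        raise ValueError("generated bundle invalid: " + "; ".join(violations))
    return params
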