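"""Input data model for the antenatal-intervention cost-effectiveness pipeline.

Everything downstream (risk derivation, Markov cohort engine, economics,
sensitivity analysis) consumes a single validated :class:`ParameterSet`.
Parameter bundles live on disk as a directory of plain CSV tables plus a
``settings.json`` for scalar fields, so they are diffable and editable with
any spreadsheet tool.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Uncertain",
    "MaternalCohort",
    "EpiTable",
    "RelativeRiskSet",
    "UtilitySet",
    "CostSet",
    "ModelConfig",
    "ParameterSet",
    "load_parameter_bundle",
    "write_parameter_bundle",
    "validate_parameters",
    "load_model_config",
    "BundleError",
]

SUBGROUPS = ("base", "diet", "pa", "diet_pa")
SCENARIOS = ("base", "s1_10yr", "s2_rr_sweep", "s3_microcost_health", "s4_microcost_societal")

BUNDLE_FILES = ("cohorts.csv", "epi.csv", "relative_risks.csv", "utilities.csv",
                "costs.csv", "settings.json")


class BundleError(ValueError):
    """Raised when a parameter bundle is missing, malformed or invalid."""


@dataclass(frozen=True)
class Uncertain:
    """A point estimate with an optional 95% interval and sampling family.

    ``family`` is one of ``beta``, ``lognormal``, ``gamma`` or ``None`` for
    parameters held fixed in sensitivity analysis.
    """

    mean: float
    lower95: float | None = None
    upper95: float | None = None
    family: str | None = None

    def with_value(self, value: float) -> "Uncertain":
        """Copy with a new point value; the CI is dropped (it no longer
        describes the replaced value, e.g. a sensitivity-analysis draw)."""
        return Uncertain(float(value), family=self.family)


@dataclass(frozen=True)
class MaternalCohort:
    """One maternal age band of the delivering population."""

    band_label: str
    age_low: int
    age_high: int
    representative_age: int
    n_births: float
    gdm_prevalence: float
    preexisting_dm_prevalence: float = 0.0

    @property
    def included_births(self) -> float:
        """Births entering the model (pre-existing diabetes excluded)."""
        return self.n_births * (1.0 - self.preexisting_dm_prevalence)


@dataclass(frozen=True)
class EpiTable:
    """Single-year female epidemiology over ages ``age_min``..``age_max``.

    Rates are events per person-year. ``t2dm_mortality`` is the all-cause
    mortality among prevalent T2DM cases and is only meaningful from age 40;
    below 40 the model uses the all-cause rate for both health states.
    """

    age_min: int
    age_max: int
    t2dm_incidence_total: np.ndarray
    all_cause_mortality: np.ndarray
    t2dm_mortality: np.ndarray
    t2dm_prevalence: np.ndarray
    population: np.ndarray
    gdm_prevalence_population: float = 0.0065

    def __post_init__(self):
        n = self.age_max - self.age_min + 1
        for name in ("t2dm_incidence_total", "all_cause_mortality", "t2dm_mortality",
                     "t2dm_prevalence", "population"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (n,):
                raise BundleError(f"epi.{name}: expected {n} rows (ages "
                                  f"{self.age_min}-{self.age_max}), got {arr.shape}")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.age_min, self.age_max + 1)

    def at(self, field_name: str, ages: np.ndarray) -> np.ndarray:
        """Values of one rate column at the given ages (clipped to table range)."""
        idx = np.clip(np.asarray(ages) - self.age_min, 0, self.age_max - self.age_min)
        return getattr(self, field_name)[idx]


@dataclass(frozen=True)
class RelativeRiskSet:
    rr_t2dm_after_gdm: Uncertain
    rr_gdm_by_subgroup: dict[str, Uncertain]
    #: scenario-2 parameter: T2DM risk (vs never-GDM) for women whose GDM was
    #: averted by the intervention; 1 in the base case.
    rr_t2dm_avoided_gdm: Uncertain = Uncertain(1.0)


@dataclass(frozen=True)
class UtilityBand:
    band_label: str
    age_low: int
    age_high: int
    utility: Uncertain


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utilities.

    ``adjustment_mode`` controls how the T2DM utility tracks age:
    ``multiplicative`` scales the age-specific healthy utility by
    ``t2dm_utility / reference_healthy_utility``; ``absolute-decrement``
    subtracts ``reference_healthy_utility − t2dm_utility``.
    """

    healthy_by_band: tuple[UtilityBand, ...]
    t2dm_utility: Uncertain
    adjustment_mode: str = "multiplicative"
    reference_healthy_utility: float = 0.95

    def healthy_at(self, ages: np.ndarray) -> np.ndarray:
        ages = np.asarray(ages)
        out = np.empty(ages.shape, dtype=float)
        out[:] = np.nan
        lows = np.array([b.age_low for b in self.healthy_by_band])
        first = self.healthy_by_band[int(np.argmin(lows))]
        for b in self.healthy_by_band:
            out[(ages >= b.age_low) & (ages <= b.age_high)] = b.utility.mean
        out[ages < lows.min()] = first.utility.mean  # ages below youngest band
        last = self.healthy_by_band[int(np.argmax(lows))]
        out[ages > last.age_high] = last.utility.mean
        return out

    def t2dm_at(self, ages: np.ndarray) -> np.ndarray:
        h = self.healthy_at(ages)
        if self.adjustment_mode == "multiplicative":
            return h * (self.t2dm_utility.mean / self.reference_healthy_utility)
        if self.adjustment_mode == "absolute-decrement":
            return np.maximum(h - (self.reference_healthy_utility - self.t2dm_utility.mean), 0.0)
        raise BundleError(f"unknown adjustment_mode {self.adjustment_mode!r}")


@dataclass(frozen=True)
class AgeBandedCost:
    age_low: int
    age_high: int
    annual_cost: float


@dataclass(frozen=True)
class CostSet:
    """All unit costs (AU$, one price year) and perinatal event probabilities."""

    intervention_cost_per_woman: dict[str, Uncertain]
    antenatal_gdm_cost: Uncertain
    caesarean_cost: Uncertain
    induction_cost: Uncertain
    nicu_admission_cost: Uncertain
    p_caesarean: dict[str, float]           # keys: gdm, no_gdm
    p_induction: dict[str, float]
    p_nicu_scn: dict[str, float]
    t2dm_annual_cost_by_age: tuple[AgeBandedCost, ...]
    microcost_first_year: Uncertain
    microcost_subsequent_year: Uncertain
    societal_direct_nonhealth: Uncertain
    societal_income_subsidy: Uncertain
    #: sensitivity-analysis multiplier on the attributed T2DM cost schedule
    t2dm_cost_scale: float = 1.0

    def t2dm_annual_cost_at(self, ages: np.ndarray) -> np.ndarray:
        ages = np.asarray(ages)
        out = np.zeros(ages.shape, dtype=float)
        for band in self.t2dm_annual_cost_by_age:
            out[(ages >= band.age_low) & (ages <= band.age_high)] = band.annual_cost
        last = max(self.t2dm_annual_cost_by_age, key=lambda b: b.age_high)
        out[ages > last.age_high] = last.annual_cost
        first = min(self.t2dm_annual_cost_by_age, key=lambda b: b.age_low)
        out[ages < first.age_low] = first.annual_cost
        return out * self.t2dm_cost_scale


@dataclass(frozen=True)
class ModelConfig:
    cycle_length: float = 1.0
    max_age: int = 85
    discount_rate: float = 0.05
    wtp_threshold: float = 50_000.0
    half_cycle_correction: bool = True
    include_nicu_scn: bool = False
    scenario: str = "base"
    subgroup: str = "base"
    rng_seed: int = 0
    psa_iterations: int = 10_000


@dataclass(frozen=True)
class ParameterSet:
    cohorts: tuple[MaternalCohort, ...]
    epi: EpiTable
    rrs: RelativeRiskSet
    utilities: UtilitySet
    costs: CostSet
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def total_included_births(self) -> float:
        return float(sum(c.included_births for c in self.cohorts))


# ---------------------------------------------------------------------------
# validation

def _check(violations: list[str], ok: bool, msg: str) -> None:
    if not ok:
        violations.append(msg)


def validate_parameters(params: ParameterSet) -> list[str]:
    """Return the list of invariant violations (empty list means valid)."""
    v: list[str] = []
    prev_high = None
    for c in params.cohorts:
        where = f"cohorts[{c.band_label}]"
        _check(v, 0.0 <= c.gdm_prevalence <= 1.0, f"{where}.gdm_prevalence={c.gdm_prevalence} outside [0,1]")
        _check(v, 0.0 <= c.preexisting_dm_prevalence <= 1.0,
               f"{where}.preexisting_dm_prevalence outside [0,1]")
        _check(v, c.n_births >= 0, f"{where}.n_births negative")
        _check(v, c.age_low <= c.representative_age <= c.age_high,
               f"{where}.representative_age outside band")
        if prev_high is not None:
            _check(v, c.age_low == prev_high + 1,
                   f"{where}: bands must tile without gaps/overlap (previous ended {prev_high})")
        prev_high = c.age_high
    if params.cohorts:
        _check(v, params.cohorts[0].age_low == 15 and params.cohorts[-1].age_high == 49,
               "cohorts must tile ages 15-49")

    epi = params.epi
    for name in ("t2dm_incidence_total", "all_cause_mortality", "t2dm_mortality", "t2dm_prevalence"):
        arr = getattr(epi, name)
        _check(v, bool(np.all(np.isfinite(arr))), f"epi.{name} contains non-finite values")
        _check(v, bool(np.all(arr >= 0)), f"epi.{name} contains negative values")
    _check(v, bool(np.all(epi.t2dm_prevalence <= 1.0)), "epi.t2dm_prevalence exceeds 1")
    _check(v, bool(np.all(epi.population > 0)), "epi.population must be positive")
    _check(v, 0.0 < epi.gdm_prevalence_population < 1.0,
           f"epi.gdm_prevalence_population={epi.gdm_prevalence_population} outside (0,1)")
    # the derived no-T2DM mortality rate must be non-negative at every age
    num = epi.all_cause_mortality * epi.population - epi.t2dm_mortality * epi.t2dm_prevalence * epi.population
    _check(v, bool(np.all(num >= -1e-9)),
           "epi: T2DM deaths exceed all-cause deaths at some age (negative derived rate)")

    def _chk_unc(u: Uncertain, name: str, lo=0.0, hi=math.inf, positive=False):
        _check(v, math.isfinite(u.mean), f"{name}.mean is not finite")
        if positive:
            _check(v, u.mean > 0, f"{name}.mean must be > 0")
        else:
            _check(v, lo <= u.mean <= hi, f"{name}.mean={u.mean} outside [{lo},{hi}]")
        if u.lower95 is not None and u.upper95 is not None:
            _check(v, u.lower95 <= u.mean <= u.upper95,
                   f"{name}: CI ({u.lower95},{u.upper95}) does not bracket mean {u.mean}")

    _chk_unc(params.rrs.rr_t2dm_after_gdm, "rrs.rr_t2dm_after_gdm", positive=True)
    _chk_unc(params.rrs.rr_t2dm_avoided_gdm, "rrs.rr_t2dm_avoided_gdm", positive=True)
    for sg in SUBGROUPS:
        _check(v, sg in params.rrs.rr_gdm_by_subgroup, f"rrs.rr_gdm_by_subgroup missing {sg!r}")
    for sg, u in params.rrs.rr_gdm_by_subgroup.items():
        _chk_unc(u, f"rrs.rr_gdm_by_subgroup[{sg}]", positive=True)

    for b in params.utilities.healthy_by_band:
        _chk_unc(b.utility, f"utilities[{b.band_label}]", 0.0, 1.0)
    _chk_unc(params.utilities.t2dm_utility, "utilities.t2dm", 0.0, 1.0)
    _check(v, params.utilities.adjustment_mode in ("multiplicative", "absolute-decrement"),
           f"utilities.adjustment_mode={params.utilities.adjustment_mode!r} unknown")
    if not v:
        ages = np.arange(15, 86)
        _check(v, bool(np.all(params.utilities.t2dm_at(ages) <= params.utilities.healthy_at(ages) + 1e-12)),
               "utilities: adjusted T2DM utility exceeds healthy utility at some age")

    costs = params.costs
    for sg in SUBGROUPS:
        _check(v, sg in costs.intervention_cost_per_woman,
               f"costs.intervention_cost_per_woman missing {sg!r}")
    for sg, u in costs.intervention_cost_per_woman.items():
        _chk_unc(u, f"costs.intervention_cost_per_woman[{sg}]")
    for name in ("antenatal_gdm_cost", "caesarean_cost", "induction_cost", "nicu_admission_cost",
                 "microcost_first_year", "microcost_subsequent_year",
                 "societal_direct_nonhealth", "societal_income_subsidy"):
        _chk_unc(getattr(costs, name), f"costs.{name}")
    for pname in ("p_caesarean", "p_induction", "p_nicu_scn"):
        d = getattr(costs, pname)
        for k in ("gdm", "no_gdm"):
            _check(v, k in d, f"costs.{pname} missing key {k!r}")
            if k in d:
                _check(v, 0.0 <= d[k] <= 1.0, f"costs.{pname}[{k}]={d[k]} outside [0,1]")
    for band in costs.t2dm_annual_cost_by_age:
        _check(v, band.annual_cost >= 0 and math.isfinite(band.annual_cost),
               f"costs.t2dm_annual_cost[{band.age_low}-{band.age_high}] invalid")
    return v


def validate_config(config: ModelConfig) -> list[str]:
    v: list[str] = []
    _check(v, config.discount_rate >= 0, f"config.discount_rate={config.discount_rate} negative")
    _check(v, config.max_age > 49, "config.max_age must exceed 49")
    _check(v, config.psa_iterations >= 1, "config.psa_iterations must be >= 1")
    _check(v, config.scenario in SCENARIOS, f"config.scenario={config.scenario!r} unknown")
    _check(v, config.subgroup in SUBGROUPS, f"config.subgroup={config.subgroup!r} unknown")
    return v


# ---------------------------------------------------------------------------
# serialisation

def _unc_cols(u: Uncertain) -> dict:
    return {"mean": u.mean, "lower95": u.lower95, "upper95": u.upper95,
            "distribution": u.family}


def _unc_from_row(row) -> Uncertain:
    def _f(x):
        return None if x is None or (isinstance(x, float) and math.isnan(x)) or x == "" else float(x)
    fam = row.get("distribution")
    if fam is not None and (fam != fam or fam == ""):  # NaN or empty
        fam = None
    return Uncertain(float(row["mean"]), _f(row.get("lower95")), _f(row.get("upper95")), fam)


def write_parameter_bundle(params: ParameterSet, path: str) -> None:
    """Write a ParameterSet as a bundle directory (deterministic byte layout)."""
    violations = validate_parameters(params)
    if violations:
        raise BundleError("refusing to write invalid ParameterSet:\n  " + "\n  ".join(violations))
    os.makedirs(path, exist_ok=True)

    pd.DataFrame([{
        "band_label": c.band_label, "age_low": c.age_low, "age_high": c.age_high,
        "representative_age": c.representative_age, "n_births": c.n_births,
        "gdm_prevalence": c.gdm_prevalence,
        "preexisting_dm_prevalence": c.preexisting_dm_prevalence,
    } for c in params.cohorts]).to_csv(os.path.join(path, "cohorts.csv"), index=False)

    epi = params.epi
    pd.DataFrame({
        "age": epi.ages, "t2dm_incidence_total": epi.t2dm_incidence_total,
        "all_cause_mortality": epi.all_cause_mortality, "t2dm_mortality": epi.t2dm_mortality,
        "t2dm_prevalence": epi.t2dm_prevalence, "population": epi.population,
    }).to_csv(os.path.join(path, "epi.csv"), index=False)

    rr_rows = [{"parameter": "rr_t2dm_after_gdm", **_unc_cols(params.rrs.rr_t2dm_after_gdm)}]
    for sg in SUBGROUPS:
        rr_rows.append({"parameter": f"rr_gdm_{sg}", **_unc_cols(params.rrs.rr_gdm_by_subgroup[sg])})
    rr_rows.append({"parameter": "rr_t2dm_avoided_gdm", **_unc_cols(params.rrs.rr_t2dm_avoided_gdm)})
    pd.DataFrame(rr_rows).to_csv(os.path.join(path, "relative_risks.csv"), index=False)

    util_rows = [{"band_label": b.band_label, "age_low": b.age_low, "age_high": b.age_high,
                  **_unc_cols(b.utility)} for b in params.utilities.healthy_by_band]
    util_rows.append({"band_label": "t2dm", "age_low": None, "age_high": None,
                      **_unc_cols(params.utilities.t2dm_utility)})
    pd.DataFrame(util_rows).to_csv(os.path.join(path, "utilities.csv"), index=False)

    cost_rows = []
    for sg in SUBGROUPS:
        cost_rows.append({"item": f"intervention_cost_{sg}", "age_low": None, "age_high": None,
                          **_unc_cols(params.costs.intervention_cost_per_woman[sg])})
    for name in ("antenatal_gdm_cost", "caesarean_cost", "induction_cost", "nicu_admission_cost",
                 "microcost_first_year", "microcost_subsequent_year",
                 "societal_direct_nonhealth", "societal_income_subsidy"):
        cost_rows.append({"item": name, "age_low": None, "age_high": None,
                          **_unc_cols(getattr(params.costs, name))})
    for pname in ("p_caesarean", "p_induction", "p_nicu_scn"):
        for k in ("gdm", "no_gdm"):
            cost_rows.append({"item": f"{pname}_{k}", "age_low": None, "age_high": None,
                              "mean": getattr(params.costs, pname)[k],
                              "lower95": None, "upper95": None, "distribution": None})
    for band in params.costs.t2dm_annual_cost_by_age:
        cost_rows.append({"item": "t2dm_annual_cost", "age_low": band.age_low,
                          "age_high": band.age_high, "mean": band.annual_cost,
                          "lower95": None, "upper95": None, "distribution": None})
    pd.DataFrame(cost_rows).to_csv(os.path.join(path, "costs.csv"), index=False)

    settings = {
        "gdm_prevalence_population": epi.gdm_prevalence_population,
        "utility_adjustment_mode": params.utilities.adjustment_mode,
        "reference_healthy_utility": params.utilities.reference_healthy_utility,
        "t2dm_cost_scale": params.costs.t2dm_cost_scale,
        "provenance": dict(sorted(params.provenance.items())),
    }
    with open(os.path.join(path, "settings.json"), "w") as fh:
        json.dump(settings, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_parameter_bundle(path: str) -> ParameterSet:
    """Load and validate a bundle directory written by :func:`write_parameter_bundle`."""
    missing = [f for f in BUNDLE_FILES if not os.path.exists(os.path.join(path, f))]
    if missing:
        raise BundleError(f"parameter bundle at {path!r} is missing: {', '.join(missing)}")

    def _read(name):
        try:
            # round_trip parsing: reloaded floats are bit-identical to the
            # shortest-repr values the writer emitted
            return pd.read_csv(os.path.join(path, name), float_precision="round_trip")
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise BundleError(f"could not parse {name}: {exc}") from exc

    with open(os.path.join(path, "settings.json")) as fh:
        settings = json.load(fh)

    cdf = _read("cohorts.csv")
    _require_columns(cdf, "cohorts.csv", ["band_label", "age_low", "age_high",
                                          "representative_age", "n_births", "gdm_prevalence"])
    cohorts = tuple(MaternalCohort(
        band_label=str(r.band_label), age_low=int(r.age_low), age_high=int(r.age_high),
        representative_age=int(r.representative_age), n_births=float(r.n_births),
        gdm_prevalence=float(r.gdm_prevalence),
        preexisting_dm_prevalence=float(getattr(r, "preexisting_dm_prevalence", 0.0)),
    ) for r in cdf.itertuples())

    edf = _read("epi.csv").sort_values("age")
    _require_columns(edf, "epi.csv", ["age", "t2dm_incidence_total", "all_cause_mortality",
                                      "t2dm_mortality", "t2dm_prevalence", "population"])
    ages = edf["age"].to_numpy(dtype=int)
    if not np.array_equal(ages, np.arange(ages.min(), ages.max() + 1)):
        raise BundleError("epi.csv: ages must be consecutive single years")
    epi = EpiTable(
        age_min=int(ages.min()), age_max=int(ages.max()),
        t2dm_incidence_total=edf["t2dm_incidence_total"].to_numpy(),
        all_cause_mortality=edf["all_cause_mortality"].to_numpy(),
        t2dm_mortality=edf["t2dm_mortality"].to_numpy(),
        t2dm_prevalence=edf["t2dm_prevalence"].to_numpy(),
        population=edf["population"].to_numpy(),
        gdm_prevalence_population=float(settings["gdm_prevalence_population"]),
    )

    rdf = _read("relative_risks.csv").set_index("parameter")
    rr_map = {name: _unc_from_row(row) for name, row in rdf.iterrows()}
    try:
        rrs = RelativeRiskSet(
            rr_t2dm_after_gdm=rr_map["rr_t2dm_after_gdm"],
            rr_gdm_by_subgroup={sg: rr_map[f"rr_gdm_{sg}"] for sg in SUBGROUPS},
            rr_t2dm_avoided_gdm=rr_map.get("rr_t2dm_avoided_gdm", Uncertain(1.0)),
        )
    except KeyError as exc:
        raise BundleError(f"relative_risks.csv missing row {exc}") from exc

    udf = _read("utilities.csv")
    bands, t2dm_u = [], None
    for _, row in udf.iterrows():
        if str(row["band_label"]) == "t2dm":
            t2dm_u = _unc_from_row(row)
        else:
            bands.append(UtilityBand(str(row["band_label"]), int(row["age_low"]),
                                     int(row["age_high"]), _unc_from_row(row)))
    if t2dm_u is None:
        raise BundleError("utilities.csv: missing 't2dm' row")
    utilities = UtilitySet(tuple(bands), t2dm_u,
                           adjustment_mode=settings.get("utility_adjustment_mode", "multiplicative"),
                           reference_healthy_utility=float(settings.get("reference_healthy_utility", 0.95)))

    kdf = _read("costs.csv")
    items: dict[str, Uncertain] = {}
    t2dm_bands = []
    probs: dict[str, dict[str, float]] = {"p_caesarean": {}, "p_induction": {}, "p_nicu_scn": {}}
    for _, row in kdf.iterrows():
        item = str(row["item"])
        if item == "t2dm_annual_cost":
            t2dm_bands.append(AgeBandedCost(int(row["age_low"]), int(row["age_high"]),
                                            float(row["mean"])))
        else:
            matched = False
            for pname in probs:
                for k in ("gdm", "no_gdm"):
                    if item == f"{pname}_{k}":
                        probs[pname][k] = float(row["mean"])
                        matched = True
            if not matched:
                items[item] = _unc_from_row(row)
    try:
        costs = CostSet(
            intervention_cost_per_woman={sg: items[f"intervention_cost_{sg}"] for sg in SUBGROUPS},
            antenatal_gdm_cost=items["antenatal_gdm_cost"],
            caesarean_cost=items["caesarean_cost"],
            induction_cost=items["induction_cost"],
            nicu_admission_cost=items["nicu_admission_cost"],
            p_caesarean=probs["p_caesarean"], p_induction=probs["p_induction"],
            p_nicu_scn=probs["p_nicu_scn"],
            t2dm_annual_cost_by_age=tuple(t2dm_bands),
            microcost_first_year=items["microcost_first_year"],
            microcost_subsequent_year=items["microcost_subsequent_year"],
            societal_direct_nonhealth=items["societal_direct_nonhealth"],
            societal_income_subsidy=items["societal_income_subsidy"],
            t2dm_cost_scale=float(settings.get("t2dm_cost_scale", 1.0)),
        )
    except KeyError as exc:
        raise BundleError(f"costs.csv missing item {exc}") from exc

    params = ParameterSet(cohorts=cohorts, epi=epi, rrs=rrs, utilities=utilities,
                          costs=costs, provenance=dict(settings.get("provenance", {})))
    violations = validate_parameters(params)
    if violations:
        raise BundleError("invalid parameter bundle:\n  " + "\n  ".join(violations))
    return params


def _require_columns(df: pd.DataFrame, fname: str, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise BundleError(f"{fname}: missing column(s) {', '.join(missing)}")


def load_model_config(path: str) -> ModelConfig:
    """Read a ModelConfig from a YAML/JSON document."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(ModelConfig)}
    unknown = set(doc) - known
    if unknown:
        raise BundleError(f"unknown config field(s): {', '.join(sorted(unknown))}")
    config = ModelConfig(**doc)
    violations = validate_config(config)
    if violations:
        raise BundleError("invalid config:\n  " + "\n  ".join(violations))
    return config
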