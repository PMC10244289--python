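"""Epidemiological rate derivations.

The national T2DM incidence series mixes women with and without a history of
gestational diabetes, while the relative risk of progression from the
literature contrasts those two groups directly. This module carries out the
standard corrections needed before the Markov engine can use the rates:

* prevalence adjustment of the relative risk,
* decomposition of total incidence into GDM / non-GDM group incidence,
* subtraction of T2DM deaths to obtain background (no-T2DM) mortality,
* restricted-cubic-spline Poisson smoothing of age-banded rates to single
  years of age, and
* exponential conversion of rates to per-cycle transition probabilities.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm

__all__ = [
    "adjust_relative_risk",
    "split_t2dm_incidence",
    "derive_no_t2dm_mortality",
    "smooth_single_year_rates",
    "rate_to_probability",
    "rcs_basis",
]

#: age below which T2DM deaths are too few to separate from background mortality
T2DM_MORTALITY_MIN_AGE = 40


def adjust_relative_risk(rr_original: float, gdm_prevalence_population: float) -> float:
    """Correct a group-vs-group RR for use against a total-population rate.

    ``rr_original`` is the incidence in the GDM group divided by the incidence
    in the non-GDM group; multiplying the returned adjusted RR by the
    *total-population* incidence gives the GDM-group incidence:

        RR_adj = RR / (p * RR + (1 - p))

    where ``p`` is the GDM prevalence in the total female population.
    """
    rr = float(rr_original)
    p = float(gdm_prevalence_population)
    if rr <= 0:
        raise ValueError(f"rr_original must be > 0, got {rr}")
    if not 0.0 <= p < 1.0:
        if p == 1.0 and rr != 1.0:
            raise ValueError("prevalence = 1 with rr != 1 leaves no reference group")
        raise ValueError(f"prevalence must lie in [0,1), got {p}")
    return rr / (p * rr + (1.0 - p))


def split_t2dm_incidence(i_total, gdm_prevalence_population: float, rr_original: float):
    """Decompose total-population T2DM incidence into group incidences.

    Returns ``(i_gdm, i_no_gdm)`` satisfying both the mixture identity
    ``p*i_gdm + (1-p)*i_no_gdm = i_total`` and the ratio identity
    ``i_gdm / i_no_gdm = rr_original``. Accepts scalars or arrays.
    """
    i_total = np.asarray(i_total, dtype=float)
    if np.any(i_total < 0):
        raise ValueError("incidence must be non-negative")
    rr_adj = adjust_relative_risk(rr_original, gdm_prevalence_population)
    i_gdm = rr_adj * i_total
    i_no_gdm = i_gdm / rr_original
    if i_total.ndim == 0:
        return float(i_gdm), float(i_no_gdm)
    return i_gdm, i_no_gdm


def derive_no_t2dm_mortality(age: int, all_cause_deaths: float, population: float,
                             t2dm_deaths: float, t2dm_prevalent: float) -> float:
    """Background mortality rate for the no-T2DM state at one age.

    From age 40, T2DM deaths and the prevalent T2DM population are removed
    from the numerator and denominator respectively; below 40 the all-cause
    rate is used unchanged for both health states.
    """
    if min(all_cause_deaths, population, t2dm_deaths, t2dm_prevalent) < 0:
        raise ValueError("counts must be non-negative")
    if population <= 0:
        raise ValueError("population must be positive")
    if age < T2DM_MORTALITY_MIN_AGE:
        return all_cause_deaths / population
    if t2dm_prevalent >= population:
        raise ValueError("prevalent T2DM population must be below total population")
    num = all_cause_deaths - t2dm_deaths
    if num < 0:
        raise ValueError(f"age {age}: T2DM deaths ({t2dm_deaths}) exceed all-cause "
                         f"deaths ({all_cause_deaths}); inputs inconsistent")
    return num / (population - t2dm_prevalent)


def rate_to_probability(rate, dt: float = 1.0):
    """Constant-hazard conversion of an annual rate to a per-cycle probability."""
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate must be non-negative")
    p = -np.expm1(-rate * dt)
    return float(p) if p.ndim == 0 else p


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted (natural) cubic spline basis, Harrell parameterisation.

    Returns an (n, K-1) design without intercept: a linear column plus K-2
    nonlinear columns that are linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(knots, dtype=float)
    K = len(k)
    if K < 3:
        raise ValueError("need at least 3 knots")
    norm = (k[-1] - k[0]) ** 2

    def _pos3(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(K - 2):
        term = (_pos3(x - k[j])
                - _pos3(x - k[-2]) * (k[-1] - k[j]) / (k[-1] - k[-2])
                + _pos3(x - k[-1]) * (k[-2] - k[j]) / (k[-1] - k[-2]))
        cols.append(term / norm)
    return np.column_stack(cols)


def smooth_single_year_rates(banded_rates: dict, exposures: dict, *,
                             n_knots: int = 4) -> dict:
    """Smooth age-banded rates to single years of age.

    Fits a Poisson GLM with a restricted cubic spline in age (knots at
    exposure-weighted quantiles of band midpoints) to per-band event counts
    with a log-exposure offset, then evaluates the fitted rate at every
    integer age covered by the bands.

    Parameters
    ----------
    banded_rates : mapping ``(age_low, age_high) -> rate`` (events/person-year)
    exposures : mapping ``(age_low, age_high) -> person-years``

    Returns
    -------
    dict mapping single-year age -> fitted rate.
    """
    bands = sorted(banded_rates)
    if len(bands) < n_knots:
        raise ValueError(f"need at least {n_knots} bands for {n_knots} knots, got {len(bands)}")
    if set(exposures) != set(banded_rates):
        raise ValueError("banded_rates and exposures must cover the same bands")

    mids = np.array([(lo + hi) / 2.0 for lo, hi in bands])
    expo = np.array([exposures[b] for b in bands], dtype=float)
    rates = np.array([banded_rates[b] for b in bands], dtype=float)
    if np.any(rates < 0) or np.any(expo <= 0):
        raise ValueError("rates must be >= 0 and exposures > 0")
    events = rates * expo

    qs = np.linspace(0.05, 0.95, n_knots)
    order = np.argsort(mids)
    cum = np.cumsum(expo[order]) / expo.sum()
    knots = np.interp(qs, cum, mids[order])
    knots = np.unique(knots)
    if len(knots) < 3:
        knots = np.linspace(mids.min(), mids.max(), 3)

    X = sm.add_constant(rcs_basis(mids, knots))
    model = sm.GLM(events, X, family=sm.families.Poisson(), exposure=expo)
    res = model.fit()

    ages = np.arange(bands[0][0], bands[-1][1] + 1)
    Xa = sm.add_constant(rcs_basis(ages.astype(float), knots), has_constant="add")
    fitted = np.asarray(res.predict(Xa, exposure=np.ones(len(ages))))
    return {int(a): float(r) for a, r in zip(ages, fitted)}
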