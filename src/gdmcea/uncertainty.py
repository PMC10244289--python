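"""Deterministic and probabilistic sensitivity analysis and threshold searches.

The sampled/varied quantities are always drawn from the single
:class:`~gdmcea.model_inputs.ParameterSet`; every evaluation re-runs the full
two-arm comparison via :func:`gdmcea.cohort_engine.run_comparison`. Sampling
families follow common cost-effectiveness practice: beta for utilities
(method of moments from the published 95% CI), log-normal for relative risks
(log-scale SD from the CI), gamma for costs with SE assumed to be 10% of the
mean. Parameters are sampled independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import cohort_engine
from .model_inputs import ModelConfig, ParameterSet, Uncertain

__all__ = [
    "DistributionSpec",
    "fit_distribution",
    "TornadoEntry",
    "one_way_dsa",
    "PsaSummary",
    "run_psa",
    "intervention_cost_threshold",
    "scenario2_sweep",
    "Scenario2Sweep",
]

Z95 = 3.92  # width of a 95% normal interval in SD units (2 * 1.96)


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted sampling distribution for one parameter."""

    family: str          # beta | lognormal | gamma | degenerate
    mean: float
    lower95: float | None
    upper95: float | None
    shape: dict

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "degenerate":
            return self.mean if size is None else np.full(size, self.mean)
        if self.family == "beta":
            return rng.beta(self.shape["alpha"], self.shape["beta"], size=size)
        if self.family == "lognormal":
            return rng.lognormal(self.shape["mu"], self.shape["sigma"], size=size)
        if self.family == "gamma":
            return rng.gamma(self.shape["k"], self.shape["theta"], size=size)
        raise ValueError(f"unknown family {self.family!r}")


def fit_distribution(family: str, mean: float, lower95: float | None = None,
                     upper95: float | None = None, se: float | None = None) -> DistributionSpec:
    """Fit a two-parameter sampling distribution from a mean and 95% CI (or SE).

    beta: method of moments with SE = (upper - lower) / 3.92;
    lognormal: log-scale location ln(mean), SD (ln upper - ln lower) / 3.92;
    gamma: method of moments from mean and SE (costs use SE = 10% of mean).
    A zero SE yields a degenerate (point-mass) distribution.
    """
    if se is None:
        if lower95 is None or upper95 is None:
            raise ValueError(f"{family}: need a 95% CI or an SE")
        if not lower95 <= mean <= upper95:
            raise ValueError(f"CI ({lower95}, {upper95}) does not bracket mean {mean}")
        if family == "lognormal":
            if lower95 <= 0:
                raise ValueError("lognormal CI must be positive")
            se = None  # handled on the log scale below
        else:
            se = (upper95 - lower95) / Z95

    if family == "lognormal":
        if mean <= 0:
            raise ValueError("lognormal mean must be positive")
        sigma = (se / mean) if se is not None else (math.log(upper95) - math.log(lower95)) / Z95
        if sigma == 0.0:
            return DistributionSpec("degenerate", mean, lower95, upper95, {})
        return DistributionSpec("lognormal", mean, lower95, upper95,
                                {"mu": math.log(mean), "sigma": sigma})

    if se == 0.0:
        return DistributionSpec("degenerate", mean, lower95, upper95, {})

    if family == "beta":
        if not 0.0 < mean < 1.0:
            raise ValueError("beta mean must lie in (0,1)")
        var = se ** 2
        if var >= mean * (1.0 - mean):
            raise ValueError(f"beta: variance {var:.4g} >= m(1-m) = {mean * (1 - mean):.4g}")
        nu = mean * (1.0 - mean) / var - 1.0
        return DistributionSpec("beta", mean, lower95, upper95,
                                {"alpha": mean * nu, "beta": (1.0 - mean) * nu})
    if family == "gamma":
        if mean <= 0:
            raise ValueError("gamma mean must be positive")
        k = (mean / se) ** 2
        return DistributionSpec("gamma", mean, lower95, upper95,
                                {"k": k, "theta": se ** 2 / mean})
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# parameter plumbing: a flat key -> (get, set) view over the nested ParameterSet

def _set_param(params: ParameterSet, key: str, value: float) -> ParameterSet:
    parts = key.split(".")
    if parts[0] == "rr_t2dm_after_gdm":
        return replace(params, rrs=replace(params.rrs,
                       rr_t2dm_after_gdm=params.rrs.rr_t2dm_after_gdm.with_value(value)))
    if parts[0] == "rr_t2dm_avoided_gdm":
        return replace(params, rrs=replace(params.rrs,
                       rr_t2dm_avoided_gdm=params.rrs.rr_t2dm_avoided_gdm.with_value(value)))
    if parts[0] == "rr_gdm":
        d = dict(params.rrs.rr_gdm_by_subgroup)
        d[parts[1]] = d[parts[1]].with_value(value)
        return replace(params, rrs=replace(params.rrs, rr_gdm_by_subgroup=d))
    if parts[0] == "utility":
        u = params.utilities
        if parts[1] == "t2dm":
            return replace(params, utilities=replace(u, t2dm_utility=u.t2dm_utility.with_value(value)))
        bands = tuple(replace(b, utility=b.utility.with_value(value))
                      if b.band_label == parts[1] else b for b in u.healthy_by_band)
        return replace(params, utilities=replace(u, healthy_by_band=bands))
    if parts[0] == "cost":
        c = params.costs
        if parts[1] == "intervention":
            d = dict(c.intervention_cost_per_woman)
            d[parts[2]] = d[parts[2]].with_value(value)
            return replace(params, costs=replace(c, intervention_cost_per_woman=d))
        if parts[1] == "t2dm_scale":
            return replace(params, costs=replace(c, t2dm_cost_scale=float(value)))
        return replace(params, costs=replace(c, **{parts[1]: getattr(c, parts[1]).with_value(value)}))
    raise KeyError(key)


def _get_param(params: ParameterSet, key: str) -> Uncertain:
    parts = key.split(".")
    if parts[0] == "rr_t2dm_after_gdm":
        return params.rrs.rr_t2dm_after_gdm
    if parts[0] == "rr_t2dm_avoided_gdm":
        return params.rrs.rr_t2dm_avoided_gdm
    if parts[0] == "rr_gdm":
        return params.rrs.rr_gdm_by_subgroup[parts[1]]
    if parts[0] == "utility":
        if parts[1] == "t2dm":
            return params.utilities.t2dm_utility
        for b in params.utilities.healthy_by_band:
            if b.band_label == parts[1]:
                return b.utility
    if parts[0] == "cost":
        if parts[1] == "intervention":
            return params.costs.intervention_cost_per_woman[parts[2]]
        if parts[1] == "t2dm_scale":
            return Uncertain(params.costs.t2dm_cost_scale, family="gamma")
        return getattr(params.costs, parts[1])
    raise KeyError(key)


_COST_KEYS = ("cost.antenatal_gdm_cost", "cost.caesarean_cost", "cost.induction_cost",
              "cost.nicu_admission_cost", "cost.microcost_first_year",
              "cost.microcost_subsequent_year", "cost.societal_direct_nonhealth",
              "cost.societal_income_subsidy", "cost.t2dm_scale")


def _default_keys(params: ParameterSet, config: ModelConfig) -> list[str]:
    keys = ["rr_t2dm_after_gdm", f"rr_gdm.{config.subgroup}", "utility.t2dm"]
    keys += [f"utility.{b.band_label}" for b in params.utilities.healthy_by_band]
    keys += [f"cost.intervention.{config.subgroup}"]
    keys += list(_COST_KEYS)
    return keys


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity analysis

@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_input: float
    high_input: float
    low_result: dict
    high_result: dict

    @property
    def span(self) -> float:
        """Width of the incremental-cost-per-woman range across the two bounds."""
        return abs(self.high_result["delta_cost_per_woman"]
                   - self.low_result["delta_cost_per_woman"])


def _summarise(res) -> dict:
    icer = res.icer
    return {"delta_cost_per_woman": res.delta_cost_per_woman,
            "delta_qalys_per_woman": res.delta_qalys_per_woman,
            "icer": icer, "roi": res.roi}


def one_way_dsa(params: ParameterSet, config: ModelConfig,
                parameters: list[tuple[str, float, float]] | None = None,
                cost_se_fraction: float = 0.10) -> list[TornadoEntry]:
    """One-way DSA: re-run the model at each parameter's bounds.

    ``parameters`` is a list of ``(key, low, high)``; when omitted, the
    published 95% CIs are used for relative risks and utilities and
    ``mean ± 1.96 * SE`` (SE = ``cost_se_fraction`` of the mean) for costs.
    Entries are returned sorted by decreasing width of the incremental-cost
    range.
    """
    if parameters is None:
        parameters = []
        for key in _default_keys(params, config):
            u = _get_param(params, key)
            if key.startswith("cost."):
                half = 1.96 * cost_se_fraction * u.mean
                parameters.append((key, u.mean - half, u.mean + half))
            elif u.lower95 is not None and u.upper95 is not None:
                parameters.append((key, u.lower95, u.upper95))

    entries = []
    for key, lo, hi in parameters:
        res_lo = cohort_engine.run_comparison(_set_param(params, key, lo), config)
        res_hi = cohort_engine.run_comparison(_set_param(params, key, hi), config)
        entries.append(TornadoEntry(key, lo, hi, _summarise(res_lo), _summarise(res_hi)))
    return sorted(entries, key=lambda e: e.span, reverse=True)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

@dataclass
class PsaSummary:
    n_iterations: int
    seed: int
    delta_cost_per_woman: np.ndarray
    delta_qalys_per_woman: np.ndarray
    roi: np.ndarray
    quadrant_fractions: dict
    ci95: dict
    n_resampled: int = 0

    @property
    def mean_delta_cost_per_woman(self) -> float:
        return float(self.delta_cost_per_woman.mean())

    @property
    def mean_delta_qalys_per_woman(self) -> float:
        return float(self.delta_qalys_per_woman.mean())

    @property
    def fraction_cost_saving(self) -> float:
        return self.quadrant_fractions["cost_saving"]


def _psa_distributions(params: ParameterSet, config: ModelConfig,
                       cost_se_fraction: float) -> dict[str, DistributionSpec]:
    dists = {}
    for key in _default_keys(params, config):
        u = _get_param(params, key)
        if key.startswith("cost."):
            dists[key] = fit_distribution("gamma", u.mean, se=cost_se_fraction * u.mean) \
                if u.mean > 0 else DistributionSpec("degenerate", u.mean, None, None, {})
        elif u.lower95 is not None and u.upper95 is not None:
            family = u.family or ("beta" if key.startswith("utility") else "lognormal")
            dists[key] = fit_distribution(family, u.mean, u.lower95, u.upper95)
    return dists


def run_psa(params: ParameterSet, config: ModelConfig, n_iterations: int | None = None,
            seed: int | None = None, cost_se_fraction: float = 0.10) -> PsaSummary:
    """Probabilistic sensitivity analysis over costs, utilities and relative risks.

    Seeded and reproducible: the same seed yields identical draws and
    summaries. Draws producing an invalid parameter set (for example a
    sampled T2DM utility above the healthy reference) are rejected and
    redrawn; the count is reported on the summary.
    """
    from .model_inputs import validate_parameters

    n = n_iterations if n_iterations is not None else config.psa_iterations
    if n < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    dists = _psa_distributions(params, config, cost_se_fraction)

    d_cost = np.empty(n)
    d_qaly = np.empty(n)
    roi = np.empty(n)
    n_resampled = 0
    for i in range(n):
        for _attempt in range(100):
            trial = params
            for key, dist in dists.items():
                trial = _set_param(trial, key, float(dist.sample(rng)))
            if not validate_parameters(trial):
                break
            n_resampled += 1
        else:
            raise RuntimeError("PSA: 100 consecutive invalid draws")
        res = cohort_engine.run_comparison(trial, config)
        d_cost[i] = res.delta_cost_per_woman
        d_qaly[i] = res.delta_qalys_per_woman
        roi[i] = res.roi

    quadrants = {
        "cost_saving": float(np.mean((d_qaly >= 0) & (d_cost < 0))),
        "more_effective_more_costly": float(np.mean((d_qaly >= 0) & (d_cost >= 0))),
        "less_effective_less_costly": float(np.mean((d_qaly < 0) & (d_cost < 0))),
        "less_effective_more_costly": float(np.mean((d_qaly < 0) & (d_cost >= 0))),
    }
    ci = {name: (float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5)))
          for name, arr in (("delta_cost_per_woman", d_cost),
                            ("delta_qalys_per_woman", d_qaly), ("roi", roi))}
    return PsaSummary(n_iterations=n, seed=config.rng_seed if seed is None else seed,
                      delta_cost_per_woman=d_cost, delta_qalys_per_woman=d_qaly, roi=roi,
                      quadrant_fractions=quadrants, ci95=ci, n_resampled=n_resampled)


# ---------------------------------------------------------------------------
# threshold searches

def _delta_metrics_at_cost(params: ParameterSet, config: ModelConfig, cost: float):
    trial = _set_param(params, f"cost.intervention.{config.subgroup}", cost)
    res = cohort_engine.run_comparison(trial, config)
    return res.delta_cost_total, res.delta_qalys


def intervention_cost_threshold(params: ParameterSet, config: ModelConfig,
                                wtp: float | None = None, bracket: tuple[float, float] = (0.0, 50_000.0),
                                tol: float = 1.0) -> float:
    """Per-participant intervention cost at which the ICER reaches ``wtp``.

    Bisection on net monetary benefit (Δcost - wtp * ΔQALY), which is
    increasing in the intervention cost, to an AU$ ``tol`` tolerance.
    """
    wtp = config.wtp_threshold if wtp is None else wtp
    lo, hi = bracket
    if math.isinf(wtp):
        return hi

    def f(c: float) -> float:
        d_cost, d_qaly = _delta_metrics_at_cost(params, config, c)
        return d_cost - wtp * d_qaly

    f_lo, f_hi = f(lo), f(hi)
    if not (f_lo < 0.0 <= f_hi):
        raise ValueError(f"no ICER = WTP crossing in bracket {bracket}: "
                         f"f({lo})={f_lo:.3g}, f({hi})={f_hi:.3g}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class Scenario2Sweep:
    rr: np.ndarray
    roi: np.ndarray
    icer: np.ndarray
    rr_roi_equals_1: float | None
    rr_icer_equals_wtp: float | None


def scenario2_sweep(params: ParameterSet, config: ModelConfig,
                    rr_grid=None, wtp: float | None = None,
                    tol: float = 1e-3) -> Scenario2Sweep:
    """Vary the T2DM relative risk of women whose GDM was averted.

    The grid spans [1, 9.5]: 1 means averted-GDM women share the never-GDM
    risk (base case); the top of the range means aversion confers no long-term
    benefit. Returns the (rr, ROI, ICER) curve plus bisection roots for
    ROI = 1 and ICER = WTP (None where the curve does not cross).
    """
    wtp = config.wtp_threshold if wtp is None else wtp
    grid = np.linspace(1.0, 9.5, 18) if rr_grid is None else np.asarray(rr_grid, dtype=float)
    if grid.min() < 1.0 or grid.max() > 9.5:
        raise ValueError("rr grid must lie within [1, 9.5]")

    def evaluate(rr: float):
        trial = _set_param(params, "rr_t2dm_avoided_gdm", rr)
        res = cohort_engine.run_comparison(trial, config)
        d_cost, d_qaly = res.delta_cost_total, res.delta_qalys
        icer = d_cost / d_qaly if d_qaly > 0 else math.inf
        return res.roi, icer, d_cost, d_qaly

    roi = np.empty(len(grid))
    icer = np.empty(len(grid))
    for i, rr in enumerate(grid):
        roi[i], icer[i], _, _ = evaluate(float(rr))

    def bisect(g, lo, hi):
        # g is increasing in rr for both targets (cost rises, QALY gain shrinks)
        g_lo, g_hi = g(lo), g(hi)
        if not (g_lo <= 0.0 <= g_hi):
            return None
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if g(mid) < 0.0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    root_roi = bisect(lambda rr: 1.0 - evaluate(rr)[0], float(grid.min()), float(grid.max()))
    root_icer = bisect(lambda rr: (lambda d_cost, d_qaly: d_cost - wtp * d_qaly)
                       (*evaluate(rr)[2:]), float(grid.min()), float(grid.max()))
    return Scenario2Sweep(rr=grid, roi=roi, icer=icer,
                          rr_roi_equals_1=root_roi, rr_icer_equals_wtp=root_icer)
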