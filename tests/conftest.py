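import dataclasses

import numpy as np
import pytest

from gdmcea import ModelConfig, load_reference_fixture
from gdmcea.model_inputs import Uncertain, UtilityBand, UtilitySet


@pytest.fixture(scope="session")
def params():
    return load_reference_fixture()


@pytest.fixture()
def config():
    return ModelConfig()


@pytest.fixture(scope="session")
def flat_utilities():
    """Utility 1 everywhere (QALYs reduce to life-years)."""
    return UtilitySet(
        healthy_by_band=(UtilityBand("all", 0, 120, Uncertain(1.0)),),
        t2dm_utility=Uncertain(1.0),
        adjustment_mode="multiplicative",
        reference_healthy_utility=1.0,
    )


def collapse_uncertainty(params):
    """Collapse every 95% CI onto the point estimate (degenerate distributions)."""
    def point(u):
        return Uncertain(u.mean, u.mean, u.mean, u.family)

    rrs = dataclasses.replace(
        params.rrs,
        rr_t2dm_after_gdm=point(params.rrs.rr_t2dm_after_gdm),
        rr_gdm_by_subgroup={k: point(v) for k, v in params.rrs.rr_gdm_by_subgroup.items()},
    )
    utilities = dataclasses.replace(
        params.utilities,
        healthy_by_band=tuple(dataclasses.replace(b, utility=point(b.utility))
                              for b in params.utilities.healthy_by_band),
        t2dm_utility=point(params.utilities.t2dm_utility),
    )
    return dataclasses.replace(params, rrs=rrs, utilities=utilities)


def microsimulate_branch(schedule, utilities, config, n_women, seed):
    """Individual-level Monte Carlo oracle for one branch schedule.

    Simulates ``n_women`` independent life courses under the same per-cycle
    probabilities and timing conventions as the cohort recursion (death
    applied to the no-T2DM state before progression; entrants not exposed to
    T2DM mortality in the onset cycle; half-cycle-corrected person-years).
    Returns per-woman arrays (t2dm_case, life_years, qalys_discounted).
    """
    rng = np.random.default_rng(seed)
    T = schedule.n_cycles
    healthy = np.ones(n_women, dtype=bool)
    t2dm = np.zeros(n_women, dtype=bool)
    cases = np.zeros(n_women)
    life_years = np.zeros(n_women)
    qalys = np.zeros(n_women)
    u_h = utilities.healthy_at(schedule.ages)
    u_d = utilities.t2dm_at(schedule.ages)
    disc = (1.0 + config.discount_rate) ** -np.arange(1, T + 1, dtype=float)

    for t in range(T):
        h_prev = healthy.astype(float)
        d_prev = t2dm.astype(float)
        # prevalent T2DM face T2DM mortality
        t2dm &= rng.random(n_women) >= schedule.p_death_t2dm[t]
        # healthy face background mortality, then progression
        healthy &= rng.random(n_women) >= schedule.p_death_no_t2dm[t]
        converts = healthy & (rng.random(n_women) < schedule.p_to_t2dm[t])
        healthy &= ~converts
        t2dm |= converts
        cases += converts
        if config.half_cycle_correction:
            hy = 0.5 * (h_prev + healthy.astype(float))
            dy = 0.5 * (d_prev + t2dm.astype(float))
        else:
            hy = healthy.astype(float)
            dy = t2dm.astype(float)
        life_years += hy + dy
        qalys += (hy * u_h[t] + dy * u_d[t]) * disc[t]
    return cases, life_years, qalys
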