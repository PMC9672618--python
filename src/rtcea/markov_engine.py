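"""Cohort simulation: lifetime discounted costs and QALYs for one arm.

The cohort starts alive and disease free at the subgroup's start age and is
followed for the model horizon (50 annual cycles by default). Per-cycle state
payoffs (costs and utility-weighted life years) are accumulated with a
trapezoidal half-cycle correction — the first and last cycle's payoffs get
weight 0.5 — and discounted at 3.5% per annum with end-of-cycle timing
(cycle ``t`` discounted by ``(1 + r)^-t``). The one-off treatment-period
costs (radiotherapy delivery and acute skin-reaction management) fall at
model entry, undiscounted and outside the half-cycle correction.

The recursion is vectorised over a leading "draw" axis: every numeric input
may be a scalar or an ``(n_draws,)`` array, which is how the probabilistic
sensitivity analysis runs 10,000 cohorts at once. ``run_cohort`` is the
single-draw case and additionally returns the full cohort trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import Arm, EconSettings, InvalidParameterError, ParameterSet, Subgroup
from .rt_costing import expected_acute_skin_cost, rt_delivery_cost
from .synthetic_inputs import AgeUtilityIndex, LifeTable, make_age_utility_index
from .transition_model import (
    ADF, DEAD, DR, LRR_POST, LRR_Y1, N_STATES, STATES,
    arm_hazard_ratio, check_eligibility, competing_risk_probs,
)


def discounted_sum(values, rate: float, half_cycle: bool) -> np.ndarray | float:
    """Discounted total of a per-cycle payoff stream.

    ``values`` holds payoffs indexed t = 0..T along the last axis; each is
    discounted by (1 + rate)^-t. With ``half_cycle`` the first and last
    entries are weighted 0.5 (trapezoidal correction for events occurring
    mid-cycle).
    """
    v = np.asarray(values, dtype=float)
    t = np.arange(v.shape[-1])
    w = np.ones(v.shape[-1])
    if half_cycle and v.shape[-1] > 1:
        w[0] = w[-1] = 0.5
    d = (1.0 + rate) ** (-t.astype(float))
    out = (v * w * d).sum(axis=-1)
    return float(out) if out.ndim == 0 else out


@dataclass
class ArmResult:
    """Expected lifetime outcomes for one subgroup/arm (per cohort member)."""

    cost: float
    qalys: float
    life_years: float
    cost_undiscounted: float
    qalys_undiscounted: float
    life_years_undiscounted: float
    oneoff_cost: float


@dataclass
class CohortTrace:
    """Cycle-by-cycle cohort record for one subgroup/arm."""

    ages: np.ndarray                 # attained age at each cycle boundary
    occupancy: np.ndarray            # (horizon+1, 5) state occupancy
    cost_payoffs: np.ndarray         # undiscounted per-cycle state costs
    qaly_payoffs: np.ndarray         # undiscounted per-cycle utility payoffs
    discount_factors: np.ndarray
    weights: np.ndarray              # half-cycle weights

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(len(self.ages)))
        df["cost"] = self.cost_payoffs
        df["qaly"] = self.qaly_payoffs
        df["discount_factor"] = self.discount_factors
        return df


def _numeric_inputs(subgroup: Subgroup, arm: Arm, params: ParameterSet) -> dict:
    """Scalar numeric bundle for the vectorised core, from a ParameterSet."""
    c, u, e, r = params.costs, params.utilities, params.effects, params.rates
    addon = c.adf_annual[subgroup] if c.unrelated_addon_policy == "adf_equivalent" else 0.0
    u_adf = u.u_adf(subgroup)
    oneoff = rt_delivery_cost(arm, params.rt_cost_inputs) + \
        expected_acute_skin_cost(arm.n_fractions, params.skin_model)
    qaly_ded = u_adf * arm.treatment_weeks / 52.0 if u.zero_treatment_utility else 0.0
    return {
        "r_lrr": r.r_adf_lrr[subgroup],
        "r_dr": r.r_adf_dr[subgroup],
        "r_lrr_dr": r.r_lrr_dr,
        "r_dr_death": r.r_dr_death[subgroup],
        "dr_background_mortality": r.dr_background_mortality,
        "hr_lrr": arm_hazard_ratio(arm, e, "lrr"),
        "hr_dr": arm_hazard_ratio(arm, e, "dr"),
        "waning_horizon": e.waning_horizon,
        "time_varying": r.time_varying,
        "c_adf": c.adf_annual[subgroup],
        "c_first_add": c.adf_first_year_add,
        "c_lrr1": c.lrr_y1_treatment + c.lrr_y1_supportive + addon,
        "c_lrr_post": c.lrr_post_annual + addon,
        "c_dr": c.dr_annual + addon,
        "u_adf": u_adf,
        "u_dr": np.clip(u_adf - u.dr_decrement, 0.0, 1.0),
        "oneoff_cost": oneoff,
        "qaly_deduction": qaly_ded,
    }


def _simulate(
    nums: dict,
    start_age: int,
    settings: EconSettings,
    life_table: LifeTable,
    age_index: AgeUtilityIndex,
) -> dict:
    """Vectorised cohort recursion. Every numeric entry of ``nums`` may be a
    scalar or an (n,) array; returns occupancy (n, T+1, 5) and outcome arrays."""
    T = int(round(settings.horizon / settings.cycle_length))
    L = settings.cycle_length
    if start_age + T - 1 > life_table.max_age:
        raise InvalidParameterError("life table does not cover the model horizon")
    sizes = [np.size(v) for v in nums.values() if isinstance(v, np.ndarray)]
    n = max(sizes) if sizes else 1

    def arr(key):
        return np.broadcast_to(np.asarray(nums[key], dtype=float), (n,)).astype(float)

    r_lrr_dr, r_dr_death = arr("r_lrr_dr"), arr("r_dr_death")
    hr_lrr, hr_dr = arr("hr_lrr"), arr("hr_dr")
    waning = nums["waning_horizon"]
    tv = nums.get("time_varying") or {}

    occ = np.zeros((n, T + 1, N_STATES))
    occ[:, 0, ADF] = 1.0
    mort_t = life_table.net_hazard(start_age + np.arange(T))

    for t in range(1, T + 1):
        years_since = (t - 1) * L
        m = mort_t[t - 1]
        base_lrr = tv["lrr"](years_since) if "lrr" in tv else nums["r_lrr"]
        base_dr = tv["dr"](years_since) if "dr" in tv else nums["r_dr"]
        base_lrr = np.broadcast_to(np.asarray(base_lrr, dtype=float), (n,))
        base_dr = np.broadcast_to(np.asarray(base_dr, dtype=float), (n,))
        active = waning is None or years_since < waning
        eff_lrr = base_lrr * hr_lrr if active else base_lrr
        eff_dr = base_dr * hr_dr if active else base_dr

        p_adf, stay_adf = competing_risk_probs(
            np.stack([eff_lrr, eff_dr, np.full(n, m)], axis=-1), L)
        p_lrr, stay_lrr = competing_risk_probs(
            np.stack([r_lrr_dr, np.full(n, m)], axis=-1), L)
        rd = r_dr_death + m if nums["dr_background_mortality"] else r_dr_death
        p_dr, stay_dr = competing_risk_probs(rd[:, None], L)

        prev = occ[:, t - 1, :]
        occ[:, t, ADF] = prev[:, ADF] * stay_adf
        occ[:, t, LRR_Y1] = prev[:, ADF] * p_adf[:, 0]
        occ[:, t, LRR_POST] = (prev[:, LRR_Y1] + prev[:, LRR_POST]) * stay_lrr
        occ[:, t, DR] = (prev[:, ADF] * p_adf[:, 1]
                         + (prev[:, LRR_Y1] + prev[:, LRR_POST]) * p_lrr[:, 0]
                         + prev[:, DR] * stay_dr)
        occ[:, t, DEAD] = (prev[:, DEAD] + prev[:, ADF] * p_adf[:, 2]
                           + (prev[:, LRR_Y1] + prev[:, LRR_POST]) * p_lrr[:, 1]
                           + prev[:, DR] * p_dr[:, 0])

    # Per-cycle payoffs at cycle boundaries t = 0..T.
    c_adf, c_first = arr("c_adf"), arr("c_first_add")
    c_lrr1, c_lrr_post, c_dr = arr("c_lrr1"), arr("c_lrr_post"), arr("c_dr")
    u_adf, u_dr = arr("u_adf"), arr("u_dr")
    age_mult = age_index.multiplier(start_age + np.arange(T + 1))

    cost_payoff = (occ[:, :, ADF] * c_adf[:, None]
                   + occ[:, :, LRR_Y1] * c_lrr1[:, None]
                   + occ[:, :, LRR_POST] * c_lrr_post[:, None]
                   + occ[:, :, DR] * c_dr[:, None])
    cost_payoff[:, 1] += occ[:, 1, ADF] * c_first  # 1st-year disease-free add-on
    alive = occ[:, :, :DEAD].sum(axis=2)
    lrr_any = occ[:, :, LRR_Y1] + occ[:, :, LRR_POST]
    qaly_payoff = ((occ[:, :, ADF] + lrr_any) * u_adf[:, None]
                   + occ[:, :, DR] * u_dr[:, None]) * age_mult[None, :]

    rate, hc = settings.discount_rate, settings.half_cycle
    res = {
        "occupancy": occ,
        "cost": arr("oneoff_cost") + discounted_sum(cost_payoff, rate, hc),
        "qalys": discounted_sum(qaly_payoff, rate, hc) - arr("qaly_deduction"),
        "life_years": discounted_sum(alive, rate, hc),
        "cost_undiscounted": arr("oneoff_cost") + discounted_sum(cost_payoff, 0.0, hc),
        "qalys_undiscounted": discounted_sum(qaly_payoff, 0.0, hc) - arr("qaly_deduction"),
        "life_years_undiscounted": discounted_sum(alive, 0.0, hc),
        "cost_payoff": cost_payoff,
        "qaly_payoff": qaly_payoff,
        "oneoff_cost": arr("oneoff_cost"),
    }
    return res


def run_cohort(
    subgroup: Subgroup,
    arm: Arm,
    params: ParameterSet,
    life_table: LifeTable,
    settings: EconSettings | None = None,
    age_index: AgeUtilityIndex | None = None,
) -> tuple[CohortTrace, ArmResult]:
    """Run the cohort model for one subgroup and arm at point estimates.

    Returns the full cycle-by-cycle trace and the expected lifetime
    discounted cost, QALYs and life years per cohort member.
    """
    check_eligibility(subgroup, arm)
    settings = settings or params.settings
    age_index = age_index or make_age_utility_index(
        subgroup.start_age,
        params.utilities.age_decrement_per_year,
        params.utilities.age_multiplier_floor,
    )
    nums = _numeric_inputs(subgroup, arm, params)
    res = _simulate(nums, subgroup.start_age, settings, life_table, age_index)
    T = res["occupancy"].shape[1] - 1
    t_idx = np.arange(T + 1)
    w = np.ones(T + 1)
    if settings.half_cycle:
        w[0] = w[-1] = 0.5
    trace = CohortTrace(
        ages=subgroup.start_age + t_idx,
        occupancy=res["occupancy"][0],
        cost_payoffs=res["cost_payoff"][0],
        qaly_payoffs=res["qaly_payoff"][0],
        discount_factors=(1.0 + settings.discount_rate) ** (-t_idx.astype(float)),
        weights=w,
    )
    result = ArmResult(
        cost=float(res["cost"][0]),
        qalys=float(res["qalys"][0]),
        life_years=float(res["life_years"][0]),
        cost_undiscounted=float(res["cost_undiscounted"][0]),
        qalys_undiscounted=float(res["qalys_undiscounted"][0]),
        life_years_undiscounted=float(res["life_years_undiscounted"][0]),
        oneoff_cost=float(res["oneoff_cost"][0]),
    )
    return trace, result
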