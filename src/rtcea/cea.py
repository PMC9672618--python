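"""Decision analysis: dominance, ICER frontier, NMB, PSA and CEAC.

Treatment options are compared on expected discounted lifetime cost and
QALYs. Options with higher cost and no more QALYs than a comparator are
strictly dominated; options lying above the convex hull of the cost-QALY
frontier are removed by extended dominance (selectable; the frontier is then
built by ordering the remaining options from cheapest to most expensive and
dividing incremental costs by incremental QALYs). Cost-effectiveness at a
threshold is summarised by net monetary benefit (NMB = threshold x QALYs -
cost) and, across PSA draws, by the probability each option has the highest
NMB (the cost-effectiveness acceptability curve as the threshold varies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
import pandas as pd

from .markov_engine import ArmResult, _numeric_inputs, _simulate, run_cohort
from .parameters import (
    Arm, EconSettings, InvalidParameterError, ParameterSet, Subgroup,
    sample_parameter_arrays,
)
from .rt_costing import expected_acute_skin_cost, rt_delivery_cost
from .synthetic_inputs import LifeTable, make_age_utility_index
from .transition_model import arm_hazard_ratio, check_eligibility

logger = logging.getLogger(__name__)


def nmb(cost, qaly, threshold: float):
    """Net monetary benefit at a willingness-to-pay threshold (GBP/QALY)."""
    if threshold < 0:
        raise InvalidParameterError("threshold must be nonnegative")
    return threshold * np.asarray(qaly) - np.asarray(cost)


# ---------------------------------------------------------------------------
# Dominance and the ICER frontier
# ---------------------------------------------------------------------------

@dataclass
class CEAResult:
    """Summary of a cost-effectiveness comparison across arms."""

    table: pd.DataFrame          # arm, cost, qalys, status, icer
    frontier: list[str]          # arms on the efficiency frontier, cheapest first
    dominant: str | None = None  # arm strictly dominating all others, if any
    probabilities: dict[str, float] = field(default_factory=dict)
    threshold: float | None = None


def icer_frontier(points, extended: bool = True) -> CEAResult:
    """Dominance analysis and frontier ICERs for (name, cost, qaly) options.

    Strictly dominated options (higher cost, no more QALYs than some
    comparator) are excluded; with ``extended`` (default), options whose
    incremental ICER exceeds the next option's are also excluded (extended
    dominance). ICERs are then the cost differences over QALY differences
    between consecutive frontier options ordered by cost. Duplicate identical
    points are resolved in favour of the first-listed arm and flagged.
    """
    points = list(points)
    if len(points) < 2:
        raise InvalidParameterError("need at least two options to compare")
    names = [p[0] for p in points]
    cost = np.array([p[1] for p in points], dtype=float)
    qaly = np.array([p[2] for p in points], dtype=float)

    status = ["frontier"] * len(points)
    for i in range(len(points)):
        for j in range(len(points)):
            if i == j:
                continue
            if cost[j] == cost[i] and qaly[j] == qaly[i]:
                if j < i:  # duplicate point: first-listed arm wins
                    status[i] = "dominated (tie)"
                continue
            if cost[j] <= cost[i] and qaly[j] >= qaly[i]:
                status[i] = "dominated"
    alive = [i for i, s in enumerate(status) if s == "frontier"]
    order = sorted(alive, key=lambda i: (cost[i], -qaly[i]))

    if extended and len(order) > 2:
        logger.info("extended dominance enabled for frontier construction")
        changed = True
        while changed and len(order) > 2:
            changed = False
            icers = [(cost[b] - cost[a]) / (qaly[b] - qaly[a])
                     for a, b in zip(order, order[1:])]
            for k in range(len(icers) - 1):
                if icers[k] > icers[k + 1]:
                    status[order[k + 1]] = "extended dominated"
                    del order[k + 1]
                    changed = True
                    break

    icer_col: list[float | None] = [None] * len(points)
    for a, b in zip(order, order[1:]):
        dq = qaly[b] - qaly[a]
        icer_col[b] = float((cost[b] - cost[a]) / dq) if dq != 0 else np.inf

    dominant = None
    for i in range(len(points)):
        others = [j for j in range(len(points)) if j != i]
        if all(cost[i] < cost[j] and qaly[i] > qaly[j] for j in others):
            dominant = names[i]
    table = pd.DataFrame({
        "arm": names, "cost": cost, "qalys": qaly,
        "status": status, "icer": icer_col,
    })
    return CEAResult(table=table, frontier=[names[i] for i in order], dominant=dominant)


# ---------------------------------------------------------------------------
# Deterministic and probabilistic runs
# ---------------------------------------------------------------------------

def run_deterministic(
    subgroup: Subgroup,
    params: ParameterSet,
    life_table: LifeTable,
    arms: tuple[Arm, ...] | None = None,
) -> dict[Arm, ArmResult]:
    """Point-estimate cohort results for every (eligible) arm."""
    arms = arms or subgroup.eligible_arms
    return {arm: run_cohort(subgroup, arm, params, life_table)[1] for arm in arms}


@dataclass
class PSAResult:
    """Per-draw discounted outcomes across arms for one subgroup."""

    subgroup: Subgroup
    arms: tuple[Arm, ...]
    costs: np.ndarray   # (n_draws, n_arms)
    qalys: np.ndarray   # (n_draws, n_arms)
    seed: int
    n_draws: int

    def arm_index(self, arm: Arm) -> int:
        return self.arms.index(arm)

    def mean_results(self) -> pd.DataFrame:
        return pd.DataFrame({
            "arm": [a.value for a in self.arms],
            "cost": self.costs.mean(axis=0),
            "qalys": self.qalys.mean(axis=0),
        })


def run_psa(
    subgroup: Subgroup,
    params: ParameterSet,
    life_table: LifeTable,
    n_draws: int = 10_000,
    seed: int = 0,
    arms: tuple[Arm, ...] | None = None,
    settings: EconSettings | None = None,
    copula=None,
) -> PSAResult:
    """Probabilistic sensitivity analysis for one subgroup.

    One joint parameter draw per iteration is shared across arms (common
    random numbers: arms differ only through their own hazard-ratio
    combination and treatment-period costs), and the cohort model is run for
    every arm under every draw. Reproducible under ``seed``.
    """
    if n_draws < 1:
        raise InvalidParameterError("n_draws must be at least 1")
    arms = arms or subgroup.eligible_arms
    for arm in arms:
        check_eligibility(subgroup, arm)
    settings = settings or params.settings
    sg = subgroup.value
    draws = sample_parameter_arrays(params, n_draws, seed, copula=copula)

    u_adf = draws["utilities.u_adf_sg1"].copy()
    if subgroup is Subgroup.SG2:
        u_adf = u_adf - draws["utilities.sg2_decrement"]
    u_adf = np.clip(u_adf, 0.0, 1.0)
    u_dr = np.clip(u_adf - draws["utilities.dr_decrement"], 0.0, 1.0)
    addon = (draws[f"costs.adf_annual.{sg}"]
             if params.costs.unrelated_addon_policy == "adf_equivalent" else 0.0)

    hr_dr_pb = None
    if params.effects.hr_dr_pb is not None:
        hr_dr_pb = draws["effects.hr_dr_pb"]
    eff = SimpleNamespace(
        hr_lrr_5f=draws["effects.hr_lrr_5f"],
        hr_lrr_pb=draws["effects.hr_lrr_pb"],
        hr_dr_5f=draws["effects.hr_dr_5f"],
        hr_dr_pb=hr_dr_pb,
        use_trial_dr_hrs=params.effects.use_trial_dr_hrs,
        waning_horizon=params.effects.waning_horizon,
    )
    rtog_costs = np.asarray(params.skin_model.rtog_costs, dtype=float)
    skin_cost = {
        15: draws["skin_model.rtog_probs_15f"] @ rtog_costs,
        5: draws["skin_model.rtog_probs_5f"] @ rtog_costs,
    }
    age_index = make_age_utility_index(
        subgroup.start_age,
        params.utilities.age_decrement_per_year,
        params.utilities.age_multiplier_floor,
    )

    costs = np.empty((n_draws, len(arms)))
    qalys = np.empty((n_draws, len(arms)))
    for j, arm in enumerate(arms):
        rt_cost = rt_delivery_cost(arm, params.rt_cost_inputs)
        qaly_ded = (u_adf * arm.treatment_weeks / 52.0
                    if params.utilities.zero_treatment_utility else 0.0)
        nums = {
            "r_lrr": draws[f"rates.r_adf_lrr.{sg}"],
            "r_dr": draws[f"rates.r_adf_dr.{sg}"],
            "r_lrr_dr": draws["rates.r_lrr_dr"],
            "r_dr_death": draws[f"rates.r_dr_death.{sg}"],
            "dr_background_mortality": params.rates.dr_background_mortality,
            "hr_lrr": arm_hazard_ratio(arm, eff, "lrr"),
            "hr_dr": arm_hazard_ratio(arm, eff, "dr"),
            "waning_horizon": params.effects.waning_horizon,
            "time_varying": params.rates.time_varying,
            "c_adf": draws[f"costs.adf_annual.{sg}"],
            "c_first_add": draws["costs.adf_first_year_add"],
            "c_lrr1": draws["costs.lrr_y1_treatment"]
                      + draws["costs.lrr_y1_supportive"] + addon,
            "c_lrr_post": draws["costs.lrr_post_annual"] + addon,
            "c_dr": draws["costs.dr_annual"] + addon,
            "u_adf": u_adf,
            "u_dr": u_dr,
            "oneoff_cost": rt_cost + skin_cost[arm.n_fractions],
            "qaly_deduction": qaly_ded,
        }
        res = _simulate(nums, subgroup.start_age, settings, life_table, age_index)
        costs[:, j] = res["cost"]
        qalys[:, j] = res["qalys"]
    return PSAResult(subgroup=subgroup, arms=tuple(arms), costs=costs,
                     qalys=qalys, seed=seed, n_draws=n_draws)


# ---------------------------------------------------------------------------
# PSA summaries
# ---------------------------------------------------------------------------

def prob_cost_effective(psa: PSAResult, threshold: float) -> dict[Arm, float]:
    """Probability each arm is cost-effective: the share of PSA draws in
    which it has the highest net monetary benefit (ties split equally)."""
    b = nmb(psa.costs, psa.qalys, threshold)
    best = b.max(axis=1, keepdims=True)
    winners = (b == best).astype(float)
    winners /= winners.sum(axis=1, keepdims=True)
    probs = winners.mean(axis=0)
    return {arm: float(p) for arm, p in zip(psa.arms, probs)}


def ceac(psa: PSAResult, thresholds) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves (one column per arm)."""
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds < 0):
        raise InvalidParameterError("thresholds must be nonnegative")
    rows = [prob_cost_effective(psa, th) for th in thresholds]
    df = pd.DataFrame([{a.value: r[a] for a in psa.arms} for r in rows])
    df.insert(0, "threshold", thresholds)
    return df


def summarize_psa(psa: PSAResult, threshold: float, extended: bool = True) -> CEAResult:
    """Expected costs/QALYs across draws, dominance/ICER analysis on the
    expectations, and probability cost-effective at the threshold."""
    mean_cost = psa.costs.mean(axis=0)
    mean_qaly = psa.qalys.mean(axis=0)
    result = icer_frontier(
        [(a.value, c, q) for a, c, q in zip(psa.arms, mean_cost, mean_qaly)],
        extended=extended,
    )
    result.threshold = threshold
    result.probabilities = {
        a.value: p for a, p in prob_cost_effective(psa, threshold).items()
    }
    return result


def ce_plane(psa: PSAResult, reference: Arm = Arm.WB15F) -> pd.DataFrame:
    """Per-draw incremental cost and QALYs of every arm vs the reference."""
    r = psa.arm_index(reference)
    frames = []
    for j, arm in enumerate(psa.arms):
        if j == r:
            continue
        frames.append(pd.DataFrame({
            "draw": np.arange(psa.n_draws),
            "arm": arm.value,
            "inc_cost": psa.costs[:, j] - psa.costs[:, r],
            "inc_qalys": psa.qalys[:, j] - psa.qalys[:, r],
        }))
    return pd.concat(frames, ignore_index=True)
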