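"""Per-cycle transition probabilities for the post-treatment Markov model.

States (in order):

0. ``ADF``      — alive and disease free
1. ``LRR_y1``   — first year of locoregional relapse (one-cycle tunnel state
                  carrying the one-off relapse treatment costs)
2. ``LRR_post`` — locoregional relapse beyond the first year
3. ``DR``       — distant (metastatic) relapse
4. ``DEAD``     — absorbing

Annual rates are converted to one-cycle probabilities under competing
exponential risks: with total exit rate R over a cycle of length L, the
probability of any exit is 1 - exp(-R L) apportioned across causes in
proportion to their rates. Background mortality for ADF and LRR states comes
from the life table net of breast-cancer mortality at the attained age;
distant-relapse mortality uses the age-adjusted registry rate (constant over
age by default, since that rate already embeds all-cause risk).

Relative treatment effects act on the ADF exit rates as hazard ratios; the
unobserved PB5F arm combines the fractionation and volume effects additively
on the log-hazard scale (i.e. multiplies the hazard ratios).
"""

from __future__ import annotations

import numpy as np

from .parameters import (
    Arm,
    InvalidParameterError,
    ParameterSet,
    Subgroup,
    TreatmentEffects,
)
from .synthetic_inputs import LifeTable

STATES = ("ADF", "LRR_y1", "LRR_post", "DR", "DEAD")
N_STATES = len(STATES)
ADF, LRR_Y1, LRR_POST, DR, DEAD = range(N_STATES)


class EligibilityError(ValueError):
    """Raised when an arm is evaluated for a subgroup it is not offered to."""


def check_eligibility(subgroup: Subgroup, arm: Arm) -> None:
    if arm not in subgroup.eligible_arms:
        raise EligibilityError(f"{arm.value} is not an option for {subgroup.value}")


def arm_hazard_ratio(
    arm: Arm,
    effects: TreatmentEffects,
    endpoint: str,
    base_case: bool | None = None,
):
    """Hazard ratio vs the WB15F reference arm for the given endpoint.

    ``lrr``: WB15F -> 1; WB5F -> hr_lrr_5f; PB15F -> hr_lrr_pb;
    PB5F -> hr_lrr_5f * hr_lrr_pb (no synergy or attenuation: additive on
    the log scale).

    ``dr``: 1 for every arm in the base case (a common distant-recurrence
    pattern across arms — radiotherapy is a local treatment); the trial
    distant-recurrence hazard ratios apply only when ``base_case`` is False
    (or ``effects.use_trial_dr_hrs`` is set). The partial-breast distant HR
    has no published value and must be supplied via ``effects.hr_dr_pb``.

    Accepts scalar or array-valued hazard ratios on ``effects`` (PSA draws).
    """
    if endpoint == "lrr":
        hr5, hrpb = effects.hr_lrr_5f, effects.hr_lrr_pb
    elif endpoint == "dr":
        if base_case is None:
            base_case = not effects.use_trial_dr_hrs
        if base_case:
            return 1.0
        hr5 = effects.hr_dr_5f
        hrpb = effects.hr_dr_pb
        if arm.volume == "partial" and hrpb is None:
            raise InvalidParameterError(
                "distant-recurrence HR for partial-breast arms is not published; "
                "set effects.hr_dr_pb to evaluate this scenario"
            )
    else:
        raise InvalidParameterError(f"unknown endpoint {endpoint!r}")
    out = 1.0
    if arm.n_fractions == 5:
        out = out * hr5
    if arm.volume == "partial":
        out = out * hrpb
    return out


def effective_rate(baseline, hr, years_since_rt: float, waning_horizon: float | None):
    """Treated-arm rate: baseline x HR while the effect persists.

    Effects persist indefinitely when ``waning_horizon`` is None; otherwise
    they apply only while ``years_since_rt < waning_horizon``, after which
    the baseline rate resumes.
    """
    if waning_horizon is not None and years_since_rt >= waning_horizon:
        return baseline
    return baseline * hr


def competing_risk_probs(rates, cycle_length: float = 1.0):
    """One-cycle transition probabilities under competing exponential risks.

    Returns (probs, stay): probs[i] = (r_i / R) * (1 - exp(-R L)) and
    stay = exp(-R L), with R the total rate. All-zero rates give zero event
    probabilities and stay = 1. Vectorises over a leading draw axis.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise InvalidParameterError("rates must be nonnegative")
    total = rates.sum(axis=-1)
    stay = np.exp(-total * cycle_length)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total[..., None] > 0, rates / np.where(total[..., None] > 0, total[..., None], 1.0), 0.0)
    probs = share * (1.0 - stay)[..., None]
    return probs, stay


def _baseline_rate(rates, endpoint: str, subgroup: Subgroup, years_since_rt: float):
    """Constant baseline rate, or the time-varying hook's rate if installed."""
    fn = rates.time_varying.get(endpoint)
    if fn is not None:
        return fn(years_since_rt)
    return rates.r_adf_lrr[subgroup] if endpoint == "lrr" else rates.r_adf_dr[subgroup]


def cycle_rates(
    subgroup: Subgroup,
    arm: Arm,
    attained_age: int,
    years_since_rt: float,
    params: ParameterSet,
    life_table: LifeTable,
    effects: TreatmentEffects | None = None,
) -> dict[str, float]:
    """Annual exit rates for each transient state at one attained age.

    ``effects`` may override ``params.effects`` with array-valued hazard
    ratios (vectorised PSA); every returned value then broadcasts.
    """
    eff = effects if effects is not None else params.effects
    r = params.rates
    mort = life_table.net_hazard(attained_age)
    hr_lrr = arm_hazard_ratio(arm, eff, "lrr")
    hr_dr = arm_hazard_ratio(arm, eff, "dr")
    r_lrr = effective_rate(_baseline_rate(r, "lrr", subgroup, years_since_rt),
                           hr_lrr, years_since_rt, eff.waning_horizon)
    r_dr = effective_rate(_baseline_rate(r, "dr", subgroup, years_since_rt),
                          hr_dr, years_since_rt, eff.waning_horizon)
    r_dr_death = r.r_dr_death[subgroup]
    if r.dr_background_mortality:
        r_dr_death = r_dr_death + mort
    return {
        "adf_lrr": r_lrr, "adf_dr": r_dr, "mort": mort,
        "lrr_dr": r.r_lrr_dr, "dr_death": r_dr_death,
    }


def build_matrix(
    subgroup: Subgroup,
    arm: Arm,
    attained_age: int,
    years_since_rt: float,
    params: ParameterSet,
    life_table: LifeTable,
) -> np.ndarray:
    """5x5 row-stochastic one-cycle transition matrix at one attained age.

    * ADF exits to LRR_y1 / DR / DEAD under competing risks (treated LRR and
      DR rates, net background mortality).
    * LRR_y1 is a tunnel: survivors who stay relapsed move to LRR_post (no
      self-loop); exits to DR (rate 0.0515/yr) and DEAD compete.
    * LRR_post behaves identically but self-loops.
    * DR exits to DEAD at the distant-relapse death rate; DEAD is absorbing.
    """
    check_eligibility(subgroup, arm)
    L = params.settings.cycle_length
    rc = cycle_rates(subgroup, arm, attained_age, years_since_rt, params, life_table)
    m = np.zeros((N_STATES, N_STATES))

    p, stay = competing_risk_probs([rc["adf_lrr"], rc["adf_dr"], rc["mort"]], L)
    m[ADF, [LRR_Y1, DR, DEAD]] = p
    m[ADF, ADF] = stay

    p, stay = competing_risk_probs([rc["lrr_dr"], rc["mort"]], L)
    m[LRR_Y1, [DR, DEAD]] = p
    m[LRR_Y1, LRR_POST] = stay  # tunnel: residual mass moves on, no self-loop

    m[LRR_POST, [DR, DEAD]] = p
    m[LRR_POST, LRR_POST] = stay

    p, stay = competing_risk_probs([rc["dr_death"]], L)
    m[DR, DEAD] = p[0]
    m[DR, DR] = stay

    m[DEAD, DEAD] = 1.0
    return m
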