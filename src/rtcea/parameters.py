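"""Model parameters for the radiotherapy cost-effectiveness model.

Encodes every model input — radiotherapy delivery costs, acute skin-reaction
probabilities and costs, annual transition rates between health states,
relative treatment effects (hazard ratios), health-state costs and utilities,
and the economic settings — together with the uncertainty distribution
attached to each quantity for probabilistic sensitivity analysis (PSA).

Distribution conventions
------------------------
* Costs, rates and utility decrements are sampled from gamma distributions
  parameterised by method of moments from their mean and standard error.
* Hazard ratios are sampled lognormally with ``mu = ln(mean)`` and ``sigma``
  equal to the reported standard error on the log-hazard scale.
* Probability vectors over acute skin-reaction (RTOG) grades are sampled from
  Dirichlet distributions with a configurable effective sample size.
* Absolute utilities are sampled through their *disutility* ``1 - u`` (gamma)
  and truncated so utilities stay in ``[0, 1]``.
"""

from __future__ import annotations

import copy
import dataclasses
import enum
import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats


class InvalidParameterError(ValueError):
    """Raised when a parameter value violates its domain constraints."""


# ---------------------------------------------------------------------------
# Treatment arms and subgroups
# ---------------------------------------------------------------------------

class Arm(str, enum.Enum):
    """Radiotherapy modality: whole (WB) or partial (PB) breast volume,
    delivered in 15 fractions over three weeks or 5 fractions over one week."""

    WB15F = "WB15F"
    PB15F = "PB15F"
    WB5F = "WB5F"
    PB5F = "PB5F"

    @property
    def n_fractions(self) -> int:
        return 15 if "15" in self.value else 5

    @property
    def volume(self) -> str:
        return "whole" if self.value.startswith("WB") else "partial"

    @property
    def treatment_weeks(self) -> int:
        """Duration of the treatment course (one fraction per weekday)."""
        return 3 if self.n_fractions == 15 else 1


class Subgroup(str, enum.Enum):
    """Patient subgroups defined by eligibility for partial-breast
    radiotherapy (consensus criteria: age, grade, tumour size, ER/HER2
    status, nodal involvement)."""

    SG1 = "SG1"  # eligible for partial breast RT; cohort starts at age 63
    SG2 = "SG2"  # ineligible for partial breast RT; cohort starts at age 60

    @property
    def start_age(self) -> int:
        return 63 if self is Subgroup.SG1 else 60

    @property
    def eligible_arms(self) -> tuple[Arm, ...]:
        if self is Subgroup.SG1:
            return (Arm.WB15F, Arm.PB15F, Arm.WB5F, Arm.PB5F)
        return (Arm.WB15F, Arm.WB5F)


# ---------------------------------------------------------------------------
# Distribution specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution attached to one parameter entry.

    kind:
        ``fixed`` — no uncertainty; ``gamma`` — method-of-moments gamma on
        (mean, se); ``lognormal_hr`` — lognormal with mu=ln(mean), sigma=se
        (se on the log-hazard scale); ``dirichlet`` — Dirichlet with the
        given concentration ``alphas``.
    """

    kind: str
    mean: float = float("nan")
    se: float = float("nan")
    alphas: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in {"fixed", "gamma", "lognormal", "lognormal_hr", "dirichlet"}:
            raise InvalidParameterError(f"unknown distribution kind {self.kind!r}")
        if self.kind in {"gamma", "lognormal", "lognormal_hr"} and not self.mean > 0:
            raise InvalidParameterError(f"{self.kind} requires mean > 0, got {self.mean}")
        if self.kind == "dirichlet":
            a = np.asarray(self.alphas, dtype=float)
            if a.size == 0 or np.any(a < 0) or not np.any(a > 0):
                raise InvalidParameterError(
                    "dirichlet alphas must be nonnegative with at least one positive"
                )


def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments (shape, rate) for a gamma distribution.

    shape = mean^2 / se^2, rate = mean / se^2, so that the gamma's first two
    moments match the supplied mean and standard error.
    """
    if not (mean > 0 and se > 0):
        raise InvalidParameterError(f"mean and se must be positive, got {mean}, {se}")
    return mean**2 / se**2, mean / se**2


def dirichlet_from_probs(probs: Sequence[float], ess: float) -> np.ndarray:
    """Dirichlet concentration vector with the given mean probabilities.

    ``ess`` is the effective sample size: alphas = probs * ess, so sampled
    vectors have mean ``probs / sum(probs)`` and variance shrinking as ess
    grows. Zero-probability components get alpha 0 (degenerate at zero).
    A 2% slack around a unit sum is allowed because published severity
    profiles carry printed rounding.
    """
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0):
        raise InvalidParameterError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 0.02:
        raise InvalidParameterError(f"probabilities must sum to 1, got {p.sum()!r}")
    if not ess > 0:
        raise InvalidParameterError("effective sample size must be positive")
    return p * ess


def _sample_dirichlet(rng: np.random.Generator, alphas: np.ndarray, size: int) -> np.ndarray:
    """Dirichlet draws allowing zero-alpha (structurally absent) components."""
    alphas = np.asarray(alphas, dtype=float)
    out = np.zeros((size, alphas.size))
    pos = alphas > 0
    if pos.sum() == 1:
        out[:, pos] = 1.0
        return out
    out[:, pos] = rng.dirichlet(alphas[pos], size=size)
    return out


# ---------------------------------------------------------------------------
# Parameter blocks
# ---------------------------------------------------------------------------

@dataclass
class RTCostInputs:
    """Unit costs and breath-hold assumptions for radiotherapy delivery.

    Cardiac breath hold protects heart tissue during whole-breast irradiation
    and raises per-fraction cost by ``breath_hold_uplift``; partial-breast
    treatment needs it less often.
    """

    planning_cost: float = 315.0
    fraction_cost: float = 124.0
    breath_hold_uplift: float = 0.30
    breath_hold_prop: dict[str, float] = field(
        default_factory=lambda: {"whole": 0.25, "partial": 0.10}
    )

    def validate(self) -> None:
        if self.planning_cost < 0 or self.fraction_cost < 0 or self.breath_hold_uplift < 0:
            raise InvalidParameterError("RT cost inputs must be nonnegative")
        for v in self.breath_hold_prop.values():
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError("breath-hold proportions must be in [0, 1]")


RTOG_GRADES = ("RTOG0", "RTOG1", "RTOG2a", "RTOG2b", "RTOG3")


@dataclass
class AcuteSkinModel:
    """Acute skin-reaction severities (worst RTOG grade during treatment)
    and the one-off cost of managing each grade."""

    rtog_probs_15f: tuple[float, ...] = (0.0, 0.32, 0.275, 0.275, 0.14)
    rtog_probs_5f: tuple[float, ...] = (0.06, 0.62, 0.135, 0.135, 0.06)
    rtog_costs: tuple[float, ...] = (0.0, 0.0, 132.0, 132.0, 136.0)

    def probs_for(self, n_fractions: int) -> tuple[float, ...]:
        if n_fractions == 15:
            return self.rtog_probs_15f
        if n_fractions == 5:
            return self.rtog_probs_5f
        raise InvalidParameterError(f"unsupported fractionation: {n_fractions}")

    def validate(self) -> None:
        for vec in (self.rtog_probs_15f, self.rtog_probs_5f):
            v = np.asarray(vec)
            # published severity profiles sum to 101% (printed rounding);
            # kept as printed, so allow a 2% slack around 1
            if np.any(v < 0) or abs(v.sum() - 1.0) > 0.02:
                raise InvalidParameterError("RTOG probabilities must form a probability vector")
        if any(c < 0 for c in self.rtog_costs):
            raise InvalidParameterError("RTOG costs must be nonnegative")


@dataclass
class TransitionRates:
    """Annual transition rates between post-treatment health states,
    for the reference (WB15F) arm.

    All rates are constant per-annum hazards (exponential survival).
    Background mortality comes from the life table, not from this block.
    ``dr_background_mortality`` toggles whether general-population mortality
    is added on top of the distant-relapse death rate (off by default: the
    registry-based distant-relapse rates are taken to embed all-cause risk).
    """

    r_adf_lrr: dict[Subgroup, float] = field(
        default_factory=lambda: {Subgroup.SG1: 0.0022, Subgroup.SG2: 0.0077}
    )
    r_adf_dr: dict[Subgroup, float] = field(
        default_factory=lambda: {Subgroup.SG1: 0.0032, Subgroup.SG2: 0.0132}
    )
    r_lrr_dr: float = 0.0515
    r_dr_death: dict[Subgroup, float] = field(
        default_factory=lambda: {Subgroup.SG1: 0.2196, Subgroup.SG2: 0.21}
    )
    dr_background_mortality: bool = False
    # Optional time-varying-hazard hook: maps endpoint ("lrr" or "dr") to a
    # callable years-since-treatment -> annual rate, replacing the constant
    # baseline for that endpoint (used for non-exponential survival families).
    time_varying: dict[str, Callable[[float], float]] = field(default_factory=dict)

    def validate(self) -> None:
        vals = list(self.r_adf_lrr.values()) + list(self.r_adf_dr.values()) \
            + [self.r_lrr_dr] + list(self.r_dr_death.values())
        if any(v < 0 for v in vals):
            raise InvalidParameterError("transition rates must be nonnegative")


@dataclass
class TreatmentEffects:
    """Relative treatment effects as hazard ratios vs the WB15F reference.

    Locoregional-recurrence effects: ``hr_lrr_5f`` (5 vs 15 fractions) and
    ``hr_lrr_pb`` (partial vs whole breast); the unobserved PB5F combination
    assumes no synergy or attenuation, i.e. additivity on the log-hazard
    scale (the product of the two HRs).

    In the base case the distant-recurrence pattern is common across arms
    (radiotherapy is a local treatment). Setting ``use_trial_dr_hrs`` applies
    the trial-reported distant-recurrence HRs instead. ``hr_dr_pb`` has no
    published value and must be supplied by the user for partial-breast arms
    in that scenario.

    ``waning_horizon``: years after treatment during which the relative
    effects apply; ``None`` means effects persist for the full horizon.
    """

    hr_lrr_5f: float = 0.66
    hr_lrr_pb: float = 0.88
    hr_dr_5f: float = 1.27
    hr_dr_pb: float | None = None
    hr_dr_pb_se: float = 0.5
    use_trial_dr_hrs: bool = False
    waning_horizon: float | None = None

    def validate(self) -> None:
        for v in (self.hr_lrr_5f, self.hr_lrr_pb, self.hr_dr_5f):
            if not v > 0:
                raise InvalidParameterError("hazard ratios must be positive")
        if self.hr_dr_pb is not None and not self.hr_dr_pb > 0:
            raise InvalidParameterError("hazard ratios must be positive")


@dataclass
class CostModel:
    """Annual health-state costs (GBP, 2019 prices).

    The first year alive and disease free carries an additional cost on top
    of the annual amount. The first year of locoregional relapse carries
    one-off treatment (mastectomy) plus supportive-care costs.

    ``unrelated_addon_policy``: the disease-free state cost was estimated
    from trial resource-use questionnaires covering care related *and*
    unrelated to breast cancer; for consistency, unrelated costs are added to
    the relapse states. ``adf_equivalent`` (default) adds the subgroup's
    annual disease-free cost to each relapse-state annual cost; ``none``
    leaves relapse-state costs as printed.
    """

    adf_annual: dict[Subgroup, float] = field(
        default_factory=lambda: {Subgroup.SG1: 1216.0, Subgroup.SG2: 1412.0}
    )
    adf_first_year_add: float = 402.0
    lrr_y1_treatment: float = 4241.0
    lrr_y1_supportive: float = 2995.0
    lrr_post_annual: float = 2139.0
    dr_annual: float = 13426.0
    unrelated_addon_policy: str = "adf_equivalent"

    def validate(self) -> None:
        vals = list(self.adf_annual.values()) + [
            self.adf_first_year_add, self.lrr_y1_treatment, self.lrr_y1_supportive,
            self.lrr_post_annual, self.dr_annual,
        ]
        if any(v < 0 for v in vals):
            raise InvalidParameterError("costs must be nonnegative")
        if self.unrelated_addon_policy not in {"none", "adf_equivalent"}:
            raise InvalidParameterError(
                f"unknown unrelated_addon_policy {self.unrelated_addon_policy!r}"
            )


@dataclass
class UtilityModel:
    """Health-state utilities (EQ-5D index scale).

    Locoregional relapse carries the same utility as alive-and-disease-free;
    distant relapse applies ``dr_decrement``. The age-related decline in
    quality of life is applied multiplicatively via an age index built in
    :mod:`rtcea.synthetic_inputs`.

    ``zero_treatment_utility``: when set, quality of life during the
    radiotherapy course itself is weighted zero (a one-off QALY deduction of
    u_adf x treatment-weeks / 52 per arm).
    """

    u_adf_sg1: float = 0.8302
    sg2_decrement: float = 0.0150
    dr_decrement: float = 0.3030
    age_decrement_per_year: float = 0.004
    age_multiplier_floor: float = 0.5
    zero_treatment_utility: bool = False

    def u_adf(self, subgroup: Subgroup) -> float:
        u = self.u_adf_sg1
        if subgroup is Subgroup.SG2:
            u -= self.sg2_decrement
        return float(np.clip(u, 0.0, 1.0))

    def u_dr(self, subgroup: Subgroup) -> float:
        return float(np.clip(self.u_adf(subgroup) - self.dr_decrement, 0.0, 1.0))

    def validate(self) -> None:
        if not 0.0 <= self.u_adf_sg1 <= 1.0:
            raise InvalidParameterError("utility must be in [0, 1]")
        if self.sg2_decrement < 0 or self.dr_decrement < 0:
            raise InvalidParameterError("utility decrements must be nonnegative")


@dataclass
class EconSettings:
    """Economic evaluation settings (NICE reference case)."""

    discount_rate: float = 0.035
    threshold: float = 15_000.0
    horizon: int = 50
    cycle_length: float = 1.0
    half_cycle: bool = True
    cost_base_year: int = 2019

    def validate(self) -> None:
        if self.discount_rate < 0:
            raise InvalidParameterError("discount rate must be nonnegative")
        if self.horizon <= 0 or self.horizon % self.cycle_length != 0:
            raise InvalidParameterError("horizon must be a positive multiple of cycle length")


@dataclass
class ParameterSet:
    """Complete set of model inputs with attached PSA distributions."""

    rt_cost_inputs: RTCostInputs = field(default_factory=RTCostInputs)
    skin_model: AcuteSkinModel = field(default_factory=AcuteSkinModel)
    rates: TransitionRates = field(default_factory=TransitionRates)
    effects: TreatmentEffects = field(default_factory=TreatmentEffects)
    costs: CostModel = field(default_factory=CostModel)
    utilities: UtilityModel = field(default_factory=UtilityModel)
    settings: EconSettings = field(default_factory=EconSettings)
    dirichlet_ess: float = 100.0
    psa_fixed: bool = False  # force all entries fixed (degenerate PSA)

    def validate(self) -> None:
        for block in (self.rt_cost_inputs, self.skin_model, self.rates,
                      self.effects, self.costs, self.utilities, self.settings):
            block.validate()

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


def default_parameters() -> ParameterSet:
    """Point estimates for every model input, with PSA distributions."""
    ps = ParameterSet()
    ps.validate()
    return ps


# ---------------------------------------------------------------------------
# Dotted-path access (used by sampling, scenarios and serialization)
# ---------------------------------------------------------------------------

def get_path(ps: ParameterSet, path: str):
    obj: object = ps
    for part in path.split("."):
        if isinstance(obj, Mapping):
            key = Subgroup(part) if part in Subgroup.__members__ else part
            obj = obj[key]
        else:
            obj = getattr(obj, part)
    return obj


def set_path(ps: ParameterSet, path: str, value) -> None:
    parts = path.split(".")
    obj: object = ps
    for part in parts[:-1]:
        if isinstance(obj, Mapping):
            key = Subgroup(part) if part in Subgroup.__members__ else part
            obj = obj[key]
        else:
            obj = getattr(obj, part)
    last = parts[-1]
    if isinstance(obj, Mapping):
        key = Subgroup(last) if last in Subgroup.__members__ else last
        obj[key] = value
    else:
        if not hasattr(obj, last):
            raise InvalidParameterError(f"unknown parameter path {path!r}")
        setattr(obj, last, value)


# ---------------------------------------------------------------------------
# PSA distribution registry
# ---------------------------------------------------------------------------

# (path, source) in a stable order; the order fixes the per-entry RNG
# substreams so scenario overrides perturb only the entry they touch.
_PSA_SOURCES: tuple[tuple[str, str], ...] = (
    ("rates.r_adf_lrr.SG1", "trial (IMPORT LOW)"),
    ("rates.r_adf_lrr.SG2", "trial (FAST-Forward)"),
    ("rates.r_adf_dr.SG1", "trial (IMPORT LOW)"),
    ("rates.r_adf_dr.SG2", "trial (FAST-Forward)"),
    ("rates.r_lrr_dr", "literature"),
    ("rates.r_dr_death.SG1", "literature (registry)"),
    ("rates.r_dr_death.SG2", "literature (registry)"),
    ("effects.hr_lrr_5f", "trial (FAST-Forward)"),
    ("effects.hr_lrr_pb", "trial (IMPORT LOW)"),
    ("effects.hr_dr_5f", "trial (FAST-Forward)"),
    ("effects.hr_dr_pb", "user-supplied"),
    ("costs.adf_annual.SG1", "trial (FAST-Forward)"),
    ("costs.adf_annual.SG2", "trial (FAST-Forward)"),
    ("costs.adf_first_year_add", "trial (FAST-Forward)"),
    ("costs.lrr_y1_treatment", "literature"),
    ("costs.lrr_y1_supportive", "literature"),
    ("costs.lrr_post_annual", "literature"),
    ("costs.dr_annual", "literature"),
    ("utilities.u_adf_sg1", "trial (IMPORT LOW)"),
    ("utilities.sg2_decrement", "trial (FAST-Forward)"),
    ("utilities.dr_decrement", "literature"),
    ("skin_model.rtog_probs_15f", "trial (acute toxicity sub-study)"),
    ("skin_model.rtog_probs_5f", "trial (acute toxicity sub-study)"),
)

# Standard errors printed alongside the means; "+/- 20%" entries carry
# se = 0.20 * mean and are resolved at spec-construction time.
_FIXED_SES: dict[str, float] = {
    "rates.r_adf_lrr.SG1": 0.0008,
    "rates.r_adf_lrr.SG2": 0.0013,
    "rates.r_adf_dr.SG1": 0.0009,
    "rates.r_adf_dr.SG2": 0.0018,
    "rates.r_lrr_dr": 0.0045,
    "rates.r_dr_death.SG1": 0.5102,  # printed SE exceeds the mean; kept as-is
    "rates.r_dr_death.SG2": 0.5102,  # (flagged, see parameter_table notes)
    "effects.hr_lrr_5f": 0.167,
    "effects.hr_lrr_pb": 0.510,
    # log-scale SE recovered from the reported 95% interval 0.90-1.79
    "effects.hr_dr_5f": 0.1754,
    "costs.adf_annual.SG1": 82.0,
    "costs.adf_annual.SG2": 68.0,
    "costs.adf_first_year_add": 64.0,
    "utilities.u_adf_sg1": 0.0040,
    "utilities.sg2_decrement": 0.0100,
    "utilities.dr_decrement": 0.1550,
}

_PCT20_PATHS = (
    "costs.lrr_y1_treatment", "costs.lrr_y1_supportive",
    "costs.lrr_post_annual", "costs.dr_annual",
)

# Entries sampled through their disutility 1 - u.
_DISUTILITY_PATHS = ("utilities.u_adf_sg1",)


def distribution_specs(ps: ParameterSet) -> dict[str, DistributionSpec]:
    """Map each uncertain parameter path to its PSA distribution."""
    specs: dict[str, DistributionSpec] = {}
    for path, _src in _PSA_SOURCES:
        if ps.psa_fixed:
            specs[path] = DistributionSpec("fixed")
            continue
        if path.startswith("skin_model."):
            probs = get_path(ps, path)
            specs[path] = DistributionSpec(
                "dirichlet", alphas=tuple(dirichlet_from_probs(probs, ps.dirichlet_ess))
            )
        elif path.startswith("effects."):
            mean = get_path(ps, path)
            if mean is None:  # hr_dr_pb without a user-supplied value
                specs[path] = DistributionSpec("fixed")
            else:
                se = _FIXED_SES.get(path, get_path(ps, "effects.hr_dr_pb_se"))
                specs[path] = DistributionSpec("lognormal_hr", mean=float(mean), se=se)
        elif path in _DISUTILITY_PATHS:
            u = get_path(ps, path)
            specs[path] = DistributionSpec("gamma", mean=1.0 - u, se=_FIXED_SES[path])
        elif path.startswith("rates.r_dr_death"):
            # The published SE (0.5102) exceeds the mean and matches the
            # adjacent log-scale hazard-ratio SE (0.510) to the printed
            # digits; a moment-matched gamma would put most of its mass near
            # zero. It is therefore read as a log-scale SE: the rate is
            # sampled lognormally with median at the published mean.
            specs[path] = DistributionSpec(
                "lognormal", mean=float(get_path(ps, path)), se=_FIXED_SES[path])
        else:
            mean = float(get_path(ps, path))
            se = 0.20 * mean if path in _PCT20_PATHS else _FIXED_SES[path]
            if mean <= 0 or se <= 0:
                specs[path] = DistributionSpec("fixed")
            else:
                specs[path] = DistributionSpec("gamma", mean=mean, se=se)
    return specs


def sample_parameter_arrays(
    ps: ParameterSet,
    n: int,
    seed: int | np.random.SeedSequence,
    copula: tuple[Sequence[str], np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Draw ``n`` joint PSA samples of every uncertain entry.

    Returns a dict mapping parameter path to an ``(n,)`` array (``(n, 5)``
    for the Dirichlet RTOG vectors). Entries with ``fixed`` specs are
    returned as constant arrays. Each entry has its own RNG substream spawned
    from ``seed`` in registry order, so a change to one entry's distribution
    leaves every other entry's draws untouched.

    ``copula``: optional (paths, correlation matrix) inducing a Gaussian
    copula across the named gamma/lognormal entries (Dirichlet entries are
    not supported in the copula). Marginals are preserved exactly.
    """
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = seq.spawn(len(_PSA_SOURCES) + 1)
    specs = distribution_specs(ps)
    copula_paths: list[str] = []
    corr = None
    if copula is not None:
        copula_paths, corr = list(copula[0]), np.asarray(copula[1], dtype=float)
        for p in copula_paths:
            if specs[p].kind not in {"gamma", "lognormal", "lognormal_hr"}:
                raise InvalidParameterError(
                    f"copula supports gamma/lognormal entries only, got {p!r}"
                )
    # Uniforms for copula entries come from one joint multivariate normal
    # (its own substream); independent entries keep their per-entry streams.
    u_cop: dict[str, np.ndarray] = {}
    if copula_paths:
        rng_c = np.random.default_rng(children[-1])
        z = rng_c.multivariate_normal(
            np.zeros(len(copula_paths)), corr, size=n, method="cholesky"
        )
        for j, p in enumerate(copula_paths):
            u_cop[p] = stats.norm.cdf(z[:, j])

    out: dict[str, np.ndarray] = {}
    for i, (path, _src) in enumerate(_PSA_SOURCES):
        spec = specs[path]
        rng = np.random.default_rng(children[i])
        if spec.kind == "fixed":
            val = get_path(ps, path)
            if path.startswith("skin_model."):
                out[path] = np.tile(np.asarray(val, dtype=float), (n, 1))
            else:
                out[path] = np.full(n, np.nan if val is None else float(val))
            continue
        if spec.kind == "dirichlet":
            out[path] = _sample_dirichlet(rng, np.asarray(spec.alphas), n)
            continue
        if spec.kind == "gamma":
            shape, rate = gamma_from_moments(spec.mean, spec.se)
            if path in u_cop:
                draws = stats.gamma.ppf(u_cop[path], a=shape, scale=1.0 / rate)
            else:
                draws = rng.gamma(shape, scale=1.0 / rate, size=n)
            if path in _DISUTILITY_PATHS:
                draws = np.clip(1.0 - draws, 0.0, 1.0)
            out[path] = draws
            continue
        # lognormal / lognormal_hr: mu = ln(mean), sigma = log-scale se
        mu, sigma = np.log(spec.mean), spec.se
        if path in u_cop:
            out[path] = stats.lognorm.ppf(u_cop[path], s=sigma, scale=np.exp(mu))
        else:
            out[path] = rng.lognormal(mean=mu, sigma=sigma, size=n)
    return out


def sample_parameters(
    ps: ParameterSet,
    seed: int | np.random.SeedSequence,
    copula: tuple[Sequence[str], np.ndarray] | None = None,
) -> ParameterSet:
    """One joint PSA draw of the parameter set (bit-reproducible under seed)."""
    arrays = sample_parameter_arrays(ps, 1, seed, copula=copula)
    out = ps.copy()
    for path, arr in arrays.items():
        if path.startswith("skin_model."):
            set_path(out, path, tuple(float(x) for x in arr[0]))
        else:
            v = float(arr[0])
            if np.isnan(v):  # unset optional entry (hr_dr_pb = None)
                continue
            set_path(out, path, v)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _to_plain(obj):
    if isinstance(obj, enum.Enum):
        return obj.value
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)
                if f.name != "time_varying"}
    if isinstance(obj, Mapping):
        return {_to_plain(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def to_dict(ps: ParameterSet) -> dict:
    """Nested plain-python dict of all parameter values (callable hooks excluded)."""
    return _to_plain(ps)


def _apply_nested(ps: ParameterSet, data: Mapping, prefix: str = "") -> None:
    for key, val in data.items():
        path = f"{prefix}{key}"
        if isinstance(val, Mapping):
            _apply_nested(ps, val, prefix=f"{path}.")
        elif isinstance(val, list):
            set_path(ps, path, tuple(val))
        else:
            set_path(ps, path, val)


def from_dict(data: Mapping) -> ParameterSet:
    ps = default_parameters()
    _apply_nested(ps, data)
    ps.validate()
    return ps


def save_yaml(ps: ParameterSet, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(ps), fh, sort_keys=True)


def load_yaml(path: str) -> ParameterSet:
    with open(path) as fh:
        return from_dict(yaml.safe_load(fh))


def save_json(ps: ParameterSet, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(to_dict(ps), fh, indent=2, sort_keys=True)


def load_json(path: str) -> ParameterSet:
    with open(path) as fh:
        return from_dict(json.load(fh))


def parameter_table(ps: ParameterSet) -> pd.DataFrame:
    """Full parameter table: (name, value, se, distribution, source, note)."""
    specs = distribution_specs(ps)
    rows = []
    for path, src in _PSA_SOURCES:
        spec = specs[path]
        val = get_path(ps, path)
        note = ""
        if path.startswith("rates.r_dr_death"):
            note = ("published SE exceeds the mean and matches the adjacent "
                    "log-scale HR SE; read as log-scale (lognormal sampling)")
        if path in _DISUTILITY_PATHS:
            note = "gamma applied to disutility 1 - u, truncated to [0, 1]"
        rows.append({
            "name": path,
            "value": val if not path.startswith("skin_model.") else str(list(val)),
            "se": spec.se if spec.kind in {"gamma", "lognormal", "lognormal_hr"} else np.nan,
            "distribution": spec.kind,
            "source": src,
            "note": note,
        })
    fixed = [
        ("rt_cost_inputs.planning_cost", "expert opinion / national tariff"),
        ("rt_cost_inputs.fraction_cost", "expert opinion / national tariff"),
        ("rt_cost_inputs.breath_hold_uplift", "expert opinion"),
        ("settings.discount_rate", "reference case"),
        ("settings.threshold", "reference case"),
        ("settings.horizon", "model design"),
    ]
    for path, src in fixed:
        rows.append({"name": path, "value": get_path(ps, path), "se": np.nan,
                     "distribution": "fixed", "source": src, "note": ""})
    return pd.DataFrame(rows)
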