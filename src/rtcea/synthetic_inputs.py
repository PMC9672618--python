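"""Synthetic stand-ins for external model inputs.

The model needs three inputs that come from national statistics and survey
data rather than from the trials: an all-cause life table with breast-cancer
mortality removed (so that excess breast-cancer mortality enters only through
the distant-relapse state), an age-related quality-of-life index, and
individual patient data (IPD) for checking the exponential-rate estimator.
This module generates stylised versions of each so the full pipeline builds
and tests without any download; exact published tables can be loaded from CSV
instead for replication against real national data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import InvalidParameterError

MAX_HAZARD = 1.5  # per-annum hazard cap; ~78% one-year death probability


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------

@dataclass
class LifeTable:
    """Age-indexed annual mortality hazards.

    ``net_rate`` is the all-cause hazard with the breast-cancer mortality
    hazard removed (floored at zero); it drives background mortality for the
    disease-free and locoregional-relapse states, avoiding double counting
    with the modelled distant-relapse deaths.
    """

    ages: np.ndarray
    all_cause_rate: np.ndarray
    bc_rate: np.ndarray
    source: str = "synthetic"
    net_rate: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.all_cause_rate = np.asarray(self.all_cause_rate, dtype=float)
        self.bc_rate = np.asarray(self.bc_rate, dtype=float)
        if np.any(self.all_cause_rate < 0) or np.any(self.bc_rate < 0):
            raise InvalidParameterError("mortality hazards must be nonnegative")
        if np.any(self.all_cause_rate > MAX_HAZARD):
            raise InvalidParameterError(f"all-cause hazard exceeds cap {MAX_HAZARD}")
        if np.any(np.diff(self.ages) != 1):
            raise InvalidParameterError("life table must cover consecutive integer ages")
        self.net_rate = np.maximum(self.all_cause_rate - self.bc_rate, 0.0)

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def _index(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=int)
        if np.any(age < self.ages[0]) or np.any(age > self.max_age):
            raise InvalidParameterError(
                f"age outside life-table range [{self.ages[0]}, {self.max_age}]"
            )
        return age - int(self.ages[0])

    def net_hazard(self, age):
        """Net-of-breast-cancer annual mortality hazard at integer age(s)."""
        return self.net_rate[self._index(age)]

    def all_cause_hazard(self, age):
        return self.all_cause_rate[self._index(age)]

    def survival_from(self, start_age: int, years: int) -> np.ndarray:
        """S(t) for t = 0..years from the net hazard: exp(-sum of hazards)."""
        idx = self._index(start_age)
        h = self.net_rate[idx: idx + years]
        if h.size < years:
            raise InvalidParameterError("life table does not cover the horizon")
        return np.exp(-np.concatenate([[0.0], np.cumsum(h)]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age": self.ages,
            "all_cause_rate": self.all_cause_rate,
            "bc_rate": self.bc_rate,
        })

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "LifeTable":
        df = pd.read_csv(path)
        required = {"age", "all_cause_rate", "bc_rate"}
        if not required.issubset(df.columns):
            raise InvalidParameterError(f"life-table CSV must have columns {sorted(required)}")
        df = df.sort_values("age")
        return cls(df["age"].to_numpy(), df["all_cause_rate"].to_numpy(),
                   df["bc_rate"].to_numpy(), source=str(path))


def make_life_table(
    max_age: int = 113,
    makeham: tuple[float, float, float] = (5e-4, 2.5e-5, 0.095),
    bc_curve: tuple[float, float, float] | None = (8e-4, 85.0, 18.0),
) -> LifeTable:
    """Stylised UK-like life table net of breast-cancer mortality.

    All-cause mortality follows a Gompertz-Makeham hazard ``a + b*exp(c*age)``
    (defaults give ~1% annual mortality in the early 60s and near-certain
    death past age 110). Breast-cancer mortality is a small Gaussian-shaped
    bump ``peak * exp(-((age - mode) / width)^2 / 2)`` peaking in old age;
    pass ``None`` for a zero curve.
    """
    a, b, c = makeham
    ages = np.arange(0, max_age + 1)
    all_cause = a + b * np.exp(c * ages)
    if np.any(all_cause <= 0) or np.any(all_cause > MAX_HAZARD):
        raise InvalidParameterError(
            f"Gompertz-Makeham parameters yield hazards outside (0, {MAX_HAZARD}]"
        )
    if bc_curve is None:
        bc = np.zeros_like(all_cause)
    else:
        peak, mode, width = bc_curve
        if peak < 0 or width <= 0:
            raise InvalidParameterError("breast-cancer curve needs peak >= 0, width > 0")
        bc = peak * np.exp(-0.5 * ((ages - mode) / width) ** 2)
    return LifeTable(ages, all_cause, bc)


# ---------------------------------------------------------------------------
# Age-related utility index
# ---------------------------------------------------------------------------

@dataclass
class AgeUtilityIndex:
    """Multiplicative quality-of-life index by age, normalised to 1 at the
    cohort's start age and declining linearly after it (clamped at a floor)."""

    start_age: int
    decrement_per_year: float = 0.004
    floor: float = 0.5

    def multiplier(self, age):
        age = np.asarray(age, dtype=float)
        m = 1.0 - self.decrement_per_year * np.maximum(age - self.start_age, 0.0)
        return np.clip(m, self.floor, 1.0)


def make_age_utility_index(
    start_age: int, decrement_per_year: float = 0.004, floor: float = 0.5
) -> AgeUtilityIndex:
    """Age-related HRQoL decline: 1 at start age, minus ``decrement_per_year``
    for each subsequent year of age, never below ``floor``."""
    if not 0.0 <= decrement_per_year < 1.0 or not 0.0 <= floor <= 1.0:
        raise InvalidParameterError("decrement must be in [0, 1); floor in [0, 1]")
    return AgeUtilityIndex(start_age, decrement_per_year, floor)


# ---------------------------------------------------------------------------
# Synthetic trial IPD and exponential-rate estimation
# ---------------------------------------------------------------------------

def simulate_trial_ipd(
    n: int,
    r_lrr: float,
    r_dr: float,
    followup: float,
    seed: int | np.random.Generator,
    arm: str = "WB15F",
) -> pd.DataFrame:
    """Competing-exponential time-to-first-event trial data.

    Each subject has latent exponential times to locoregional relapse (rate
    ``r_lrr``) and distant relapse (rate ``r_dr``); the first to occur before
    administrative censoring at ``followup`` years is recorded.

    Returns a DataFrame with columns ``id, time, event, arm`` where event is
    one of ``lrr``, ``dr``, ``censor``.
    """
    if r_lrr < 0 or r_dr < 0:
        raise InvalidParameterError("rates must be nonnegative")
    if followup <= 0:
        raise InvalidParameterError("follow-up must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_lrr = rng.exponential(1.0 / r_lrr, size=n) if r_lrr > 0 else np.full(n, np.inf)
    t_dr = rng.exponential(1.0 / r_dr, size=n) if r_dr > 0 else np.full(n, np.inf)
    t_first = np.minimum(t_lrr, t_dr)
    time = np.minimum(t_first, followup)
    event = np.where(t_first >= followup, "censor", np.where(t_lrr <= t_dr, "lrr", "dr"))
    return pd.DataFrame({
        "id": np.arange(n), "time": time, "event": event, "arm": arm,
    })


def fit_exponential_rate(ipd: pd.DataFrame, event_type: str) -> tuple[float, float]:
    """Maximum-likelihood cause-specific rate under the constant-hazard model.

    rate = events / total person-time at risk; se = rate / sqrt(events)
    (the usual Poisson-likelihood asymptotics).
    """
    if event_type not in {"lrr", "dr"}:
        raise InvalidParameterError(f"unknown event type {event_type!r}")
    events = int((ipd["event"] == event_type).sum())
    if events == 0:
        raise InvalidParameterError(
            f"no {event_type!r} events observed; rate not identifiable"
        )
    person_time = float(ipd["time"].sum())
    rate = events / person_time
    return rate, rate / np.sqrt(events)
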