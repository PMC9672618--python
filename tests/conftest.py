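import numpy as np
import pytest

import rtcea
from rtcea.markov_engine import _numeric_inputs
from rtcea.synthetic_inputs import make_age_utility_index
from rtcea.transition_model import build_matrix


@pytest.fixture
def params():
    return rtcea.default_parameters()


@pytest.fixture(scope="session")
def life_table():
    return rtcea.make_life_table()


def microsimulate(subgroup, arm, params, life_table, n_patients, seed):
    """Independent individual-level oracle for the cohort expectation.

    Simulates ``n_patients`` independent state paths from the one-cycle
    transition matrices and accumulates each patient's discounted costs and
    QALYs with the same payoff, discounting and half-cycle conventions as
    the cohort model. Returns (mean_cost, se_cost, mean_qaly, se_qaly).
    """
    s = params.settings
    T = int(round(s.horizon / s.cycle_length))
    start_age = subgroup.start_age
    rng = np.random.default_rng(seed)
    nums = _numeric_inputs(subgroup, arm, params)
    age_index = make_age_utility_index(
        start_age, params.utilities.age_decrement_per_year,
        params.utilities.age_multiplier_floor)
    age_mult = age_index.multiplier(start_age + np.arange(T + 1))
    disc = (1.0 + s.discount_rate) ** (-np.arange(T + 1).astype(float))
    w = np.ones(T + 1)
    if s.half_cycle:
        w[0] = w[-1] = 0.5

    def cost_vec(t):
        c_adf = nums["c_adf"] + (nums["c_first_add"] if t == 1 else 0.0)
        return np.array([c_adf, nums["c_lrr1"], nums["c_lrr_post"], nums["c_dr"], 0.0])

    util_vec = np.array([nums["u_adf"], nums["u_adf"], nums["u_adf"], nums["u_dr"], 0.0])

    state = np.zeros(n_patients, dtype=np.int64)
    cost = np.full(n_patients, w[0] * disc[0] * cost_vec(0)[0])
    qaly = np.full(n_patients, w[0] * disc[0] * util_vec[0] * age_mult[0])
    for t in range(1, T + 1):
        m = build_matrix(subgroup, arm, start_age + t - 1, t - 1, params, life_table)
        cum = np.cumsum(m, axis=1)[state]
        u = rng.random(n_patients)
        state = (cum <= u[:, None]).sum(axis=1)
        cost += w[t] * disc[t] * cost_vec(t)[state]
        qaly += w[t] * disc[t] * util_vec[state] * age_mult[t]
    cost += nums["oneoff_cost"]
    qaly -= nums["qaly_deduction"]
    root_n = np.sqrt(n_patients)
    return (cost.mean(), cost.std(ddof=1) / root_n,
            qaly.mean(), qaly.std(ddof=1) / root_n)


@pytest.fixture(scope="session")
def microsim_oracle():
    return microsimulate
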