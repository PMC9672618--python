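"""Treatment-period decision tree: radiotherapy delivery and acute toxicity.

The treatment period is a simple decision tree applied at model entry: each
arm incurs a planning cost plus per-fraction delivery costs, with a fraction
of patients receiving cardiac breath hold at an uplifted per-fraction cost,
and an expected one-off cost of managing acute skin reactions graded by the
worst RTOG score observed during treatment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .parameters import AcuteSkinModel, Arm, InvalidParameterError, RTCostInputs


def rt_delivery_cost(arm: Arm, inputs: RTCostInputs) -> float:
    """Expected radiotherapy delivery cost (GBP) for one patient.

    planning + fractions without breath hold + uplifted fractions with
    breath hold, weighted by the volume-specific breath-hold proportion.
    """
    inputs.validate()
    p_bh = inputs.breath_hold_prop[arm.volume]
    n = arm.n_fractions
    without_bh = inputs.fraction_cost * n * (1.0 - p_bh)
    with_bh = inputs.fraction_cost * (1.0 + inputs.breath_hold_uplift) * n * p_bh
    return inputs.planning_cost + without_bh + with_bh


def expected_acute_skin_cost(n_fractions: int, model: AcuteSkinModel) -> float:
    """Expected one-off cost of managing acute skin reactions.

    Dot product of the fractionation-specific RTOG grade probabilities and
    the per-grade management costs.
    """
    probs = np.asarray(model.probs_for(n_fractions), dtype=float)
    costs = np.asarray(model.rtog_costs, dtype=float)
    return float(probs @ costs)


def costing_breakdown(arm: Arm, inputs: RTCostInputs) -> pd.DataFrame:
    """Per-component delivery-cost breakdown (mirrors the published costing
    arithmetic) for audit/export."""
    p_bh = inputs.breath_hold_prop[arm.volume]
    n = arm.n_fractions
    rows = [
        ("planning", f"£{inputs.planning_cost:.2f}", inputs.planning_cost),
        ("RT without breath hold",
         f"£{inputs.fraction_cost:.0f} x {n} x {100 * (1 - p_bh):g}%",
         inputs.fraction_cost * n * (1 - p_bh)),
        ("RT with breath hold",
         f"(£{inputs.fraction_cost:.0f} x {1 + inputs.breath_hold_uplift:g}) x {n} x {100 * p_bh:g}%",
         inputs.fraction_cost * (1 + inputs.breath_hold_uplift) * n * p_bh),
    ]
    rows.append(("total", "", sum(r[2] for r in rows)))
    return pd.DataFrame(rows, columns=["component", "formula", "gbp"]).assign(arm=arm.value)
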