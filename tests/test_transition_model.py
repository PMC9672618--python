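import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtcea import (
    Arm, InvalidParameterError, Subgroup, arm_hazard_ratio, build_matrix,
    competing_risk_probs, effective_rate, make_life_table,
)
from rtcea.parameters import TreatmentEffects, default_parameters
from rtcea.transition_model import ADF, DEAD, DR, LRR_POST, LRR_Y1, EligibilityError


class TestArmHazardRatio:
    def test_reference_arm_is_unity(self):
        assert arm_hazard_ratio(Arm.WB15F, TreatmentEffects(), "lrr") == 1.0

    def test_single_effects(self):
        eff = TreatmentEffects()
        assert arm_hazard_ratio(Arm.WB5F, eff, "lrr") == 0.66
        assert arm_hazard_ratio(Arm.PB15F, eff, "lrr") == 0.88

    def test_log_additive_combination_for_pb5f(self):
        hr = arm_hazard_ratio(Arm.PB5F, TreatmentEffects(), "lrr")
        assert hr == pytest.approx(0.66 * 0.88)
        assert np.log(hr) == pytest.approx(np.log(0.66) + np.log(0.88))

    def test_common_distant_pattern_in_base_case(self):
        for arm in Arm:
            assert arm_hazard_ratio(arm, TreatmentEffects(), "dr", base_case=True) == 1.0

    def test_trial_distant_hrs_in_scenario(self):
        eff = TreatmentEffects(use_trial_dr_hrs=True)
        assert arm_hazard_ratio(Arm.WB5F, eff, "dr") == 1.27
        with pytest.raises(InvalidParameterError):
            arm_hazard_ratio(Arm.PB5F, eff, "dr")  # PB distant HR unpublished
        eff.hr_dr_pb = 1.1
        assert arm_hazard_ratio(Arm.PB5F, eff, "dr") == pytest.approx(1.27 * 1.1)


class TestEffectiveRate:
    def test_product_while_effect_persists(self):
        assert effective_rate(0.0022, 0.5808, 3, None) == pytest.approx(0.0022 * 0.5808)

    def test_effect_expired(self):
        assert effective_rate(0.0077, 0.66, 7, 5) == 0.0077

    def test_null_effect(self):
        assert effective_rate(0.01, 1.0, 30, None) == 0.01


class TestCompetingRisks:
    def test_closed_form_example(self):
        probs, stay = competing_risk_probs([0.0022, 0.0032, 0.0100], 1.0)
        np.testing.assert_allclose(probs, [0.0021832, 0.0031756, 0.0099234], atol=5e-7)
        assert stay == pytest.approx(0.9847179, abs=5e-7)

    def test_zero_rates(self):
        probs, stay = competing_risk_probs([0.0, 0.0], 1.0)
        assert np.all(probs == 0) and stay == 1.0

    def test_single_rate_is_standard_conversion(self):
        probs, stay = competing_risk_probs([0.3], 1.0)
        assert probs[0] == pytest.approx(1 - np.exp(-0.3))
        assert probs[0] + stay == pytest.approx(1.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            competing_risk_probs([-0.1], 1.0)


class TestBuildMatrix:
    @given(r1=st.floats(0, 0.5), r2=st.floats(0, 0.5), r3=st.floats(0, 1.0),
           age=st.integers(50, 110))
    @settings(max_examples=60, deadline=None)
    def test_row_stochastic_and_absorbing(self, r1, r2, r3, age, life_table):
        ps = default_parameters()
        ps.rates.r_adf_lrr[Subgroup.SG1] = r1
        ps.rates.r_adf_dr[Subgroup.SG1] = r2
        ps.rates.r_dr_death[Subgroup.SG1] = r3
        m = build_matrix(Subgroup.SG1, Arm.PB5F, age, float(age - 63), ps, life_table)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(m >= 0)
        np.testing.assert_array_equal(m[DEAD], [0, 0, 0, 0, 1])
        assert m[LRR_Y1, LRR_Y1] == 0.0  # tunnel: no self-loop

    def test_zero_disease_rates_leave_only_background_mortality(self, life_table):
        ps = default_parameters()
        for sg in Subgroup:
            ps.rates.r_adf_lrr[sg] = 0.0
            ps.rates.r_adf_dr[sg] = 0.0
        m = build_matrix(Subgroup.SG2, Arm.WB15F, 70, 10.0, ps, life_table)
        expect_dead = 1 - np.exp(-life_table.net_hazard(70))
        assert m[ADF, DEAD] == pytest.approx(expect_dead)
        assert m[ADF, ADF] == pytest.approx(1 - expect_dead)
        assert m[ADF, LRR_Y1] == 0 and m[ADF, DR] == 0

    def test_cohort_survival_matches_life_table_with_no_disease(self, life_table):
        """With disease rates zeroed the Markov chain must reproduce the
        life-table survival curve exactly (oracle equivalence)."""
        ps = default_parameters()
        for sg in Subgroup:
            ps.rates.r_adf_lrr[sg] = 0.0
            ps.rates.r_adf_dr[sg] = 0.0
        occ = np.array([1.0, 0, 0, 0, 0])
        start = Subgroup.SG1.start_age
        surv = life_table.survival_from(start, 50)
        for t in range(1, 51):
            m = build_matrix(Subgroup.SG1, Arm.WB15F, start + t - 1, t - 1.0, ps, life_table)
            occ = occ @ m
            assert occ[ADF] == pytest.approx(surv[t], rel=1e-12)

    def test_distant_relapse_death_closed_form(self, life_table):
        ps = default_parameters()
        m = build_matrix(Subgroup.SG1, Arm.WB15F, 70, 7.0, ps, life_table)
        assert m[DR, DEAD] == pytest.approx(1 - np.exp(-0.2196), abs=1e-5)
        assert m[DR, DR] ** 5 == pytest.approx(np.exp(-5 * 0.2196), abs=1e-4)
        assert m[DR, DR] ** 5 == pytest.approx(0.3335, abs=2e-4)

    def test_dr_background_mortality_toggle(self, life_table):
        ps = default_parameters()
        base = build_matrix(Subgroup.SG1, Arm.WB15F, 80, 17.0, ps, life_table)
        ps.rates.dr_background_mortality = True
        with_bg = build_matrix(Subgroup.SG1, Arm.WB15F, 80, 17.0, ps, life_table)
        assert with_bg[DR, DEAD] > base[DR, DEAD]

    def test_protective_hr_reduces_expected_relapses(self, life_table):
        """hr < 1 yields fewer cumulative entries into locoregional relapse
        than hr = 1 over the full horizon."""
        def total_lrr_inflow(hr):
            ps = default_parameters()
            ps.effects.hr_lrr_5f = hr
            occ = np.array([1.0, 0, 0, 0, 0])
            inflow = 0.0
            for t in range(1, 51):
                m = build_matrix(Subgroup.SG2, Arm.WB5F, 60 + t - 1, t - 1.0,
                                 ps, life_table)
                inflow += occ[ADF] * m[ADF, LRR_Y1]
                occ = occ @ m
            return inflow
        assert total_lrr_inflow(0.66) < total_lrr_inflow(1.0)

    def test_higher_disease_rate_lowers_stay_probability(self, life_table):
        ps = default_parameters()
        lo = build_matrix(Subgroup.SG2, Arm.WB15F, 65, 5.0, ps, life_table)
        ps.rates.r_adf_dr[Subgroup.SG2] *= 5
        hi = build_matrix(Subgroup.SG2, Arm.WB15F, 65, 5.0, ps, life_table)
        assert hi[ADF, ADF] < lo[ADF, ADF]

    def test_waning_restores_baseline(self, life_table):
        ps = default_parameters()
        ps.effects.waning_horizon = 5.0
        before = build_matrix(Subgroup.SG2, Arm.WB5F, 62, 2.0, ps, life_table)
        after = build_matrix(Subgroup.SG2, Arm.WB5F, 68, 8.0, ps, life_table)
        ps2 = default_parameters()
        ref_after = build_matrix(Subgroup.SG2, Arm.WB15F, 68, 8.0, ps2, life_table)
        assert before[ADF, LRR_Y1] < after[ADF, LRR_Y1]
        assert after[ADF, LRR_Y1] == pytest.approx(ref_after[ADF, LRR_Y1])

    def test_ineligible_pairing_rejected(self, life_table):
        with pytest.raises(EligibilityError):
            build_matrix(Subgroup.SG2, Arm.PB5F, 60, 0.0,
                         default_parameters(), life_table)

    def test_age_beyond_table_rejected(self):
        lt = make_life_table(max_age=80)
        with pytest.raises(InvalidParameterError):
            build_matrix(Subgroup.SG1, Arm.WB15F, 90, 27.0,
                         default_parameters(), lt)

    def test_time_varying_hazard_hook(self, life_table):
        ps = default_parameters()
        ps.rates.time_varying = {"lrr": lambda t: 0.0077}  # constant hook
        hooked = build_matrix(Subgroup.SG2, Arm.WB15F, 65, 5.0, ps, life_table)
        plain = build_matrix(Subgroup.SG2, Arm.WB15F, 65, 5.0,
                             default_parameters(), life_table)
        np.testing.assert_allclose(hooked, plain)
        ps.rates.time_varying = {"lrr": lambda t: 0.02 if t < 10 else 0.001}
        early = build_matrix(Subgroup.SG2, Arm.WB15F, 65, 5.0, ps, life_table)
        late = build_matrix(Subgroup.SG2, Arm.WB15F, 75, 15.0, ps, life_table)
        assert early[ADF, LRR_Y1] > late[ADF, LRR_Y1]
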