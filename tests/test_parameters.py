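import numpy as np
import pytest

import rtcea
from rtcea import (
    Arm, DistributionSpec, InvalidParameterError, Subgroup,
    default_parameters, dirichlet_from_probs, gamma_from_moments,
    parameter_table, sample_parameter_arrays, sample_parameters,
)
from rtcea.parameters import distribution_specs, from_dict, to_dict


class TestDefaults:
    def test_point_estimates(self, params):
        assert params.rates.r_adf_lrr[Subgroup.SG1] == 0.0022
        assert params.rates.r_adf_dr[Subgroup.SG2] == 0.0132
        assert params.rates.r_lrr_dr == 0.0515
        assert params.effects.hr_lrr_5f == 0.66
        assert params.effects.hr_lrr_pb == 0.88
        assert params.costs.dr_annual == 13_426
        assert params.costs.adf_annual[Subgroup.SG1] == 1_216
        assert params.utilities.u_adf_sg1 == 0.8302
        assert params.utilities.dr_decrement == 0.3030
        assert params.settings.discount_rate == 0.035
        assert params.settings.threshold == 15_000

    def test_subgroup_structure(self):
        assert Subgroup.SG1.start_age == 63 and Subgroup.SG2.start_age == 60
        assert len(Subgroup.SG1.eligible_arms) == 4
        assert Subgroup.SG2.eligible_arms == (Arm.WB15F, Arm.WB5F)

    def test_arm_structure(self):
        assert Arm.PB5F.n_fractions == 5 and Arm.PB5F.volume == "partial"
        assert Arm.WB15F.n_fractions == 15 and Arm.WB15F.volume == "whole"


class TestGammaFromMoments:
    def test_closed_form(self):
        shape, rate = gamma_from_moments(1216, 82)
        assert shape == pytest.approx(1216**2 / 82**2)
        assert shape == pytest.approx(219.89, abs=0.05)
        assert rate == pytest.approx(0.18084, abs=1e-5)

    def test_exponential_special_case(self):
        assert gamma_from_moments(1, 1) == (1.0, 1.0)

    @pytest.mark.parametrize("mean,se", [(0, 1), (-1, 1), (1, 0)])
    def test_invalid(self, mean, se):
        with pytest.raises(InvalidParameterError):
            gamma_from_moments(mean, se)

    def test_monte_carlo_moments(self):
        # the "+/- 20%" cost entry: mean 4241, se 848.2
        shape, rate = gamma_from_moments(4241, 848.2)
        draws = np.random.default_rng(0).gamma(shape, 1 / rate, size=10**6)
        assert draws.mean() == pytest.approx(4241, abs=3 * 848.2 / 1000)
        assert draws.std() == pytest.approx(848.2, rel=0.01)


class TestDirichlet:
    def test_alphas(self):
        alphas = dirichlet_from_probs((0, 0.32, 0.275, 0.275, 0.14), 100)
        np.testing.assert_allclose(alphas, (0, 32, 27.5, 27.5, 14))

    def test_degenerate_component(self):
        from rtcea.parameters import _sample_dirichlet
        draws = _sample_dirichlet(np.random.default_rng(0),
                                  np.array([10.0, 0, 0, 0, 0]), 100)
        assert np.all(draws == [[1, 0, 0, 0, 0]])

    def test_negative_rejected(self):
        with pytest.raises(InvalidParameterError):
            dirichlet_from_probs((-0.1, 1.1), 10)

    def test_mean_recovery(self):
        from rtcea.parameters import _sample_dirichlet
        probs = np.array([0.06, 0.62, 0.135, 0.135, 0.06])
        alphas = dirichlet_from_probs(probs, 100)
        draws = _sample_dirichlet(np.random.default_rng(1), alphas, 10**5)
        expect = alphas / alphas.sum()
        mc_se = np.sqrt(expect * (1 - expect) / (alphas.sum() + 1)) / np.sqrt(10**5)
        np.testing.assert_array_less(np.abs(draws.mean(0) - expect), 3 * mc_se + 1e-12)
        # zero-probability grade stays structurally absent
        alphas15 = dirichlet_from_probs((0, 0.32, 0.275, 0.275, 0.14), 100)
        draws15 = _sample_dirichlet(np.random.default_rng(1), alphas15, 1000)
        assert np.all(draws15[:, 0] == 0)


class TestSampling:
    def test_all_fixed_is_identity(self, params):
        params.psa_fixed = True
        sampled = sample_parameters(params, seed=123)
        assert to_dict(sampled) == to_dict(params)

    def test_bit_reproducible(self, params):
        a = sample_parameters(params, seed=42)
        b = sample_parameters(params, seed=42)
        assert to_dict(a) == to_dict(b)
        c = sample_parameters(params, seed=43)
        assert to_dict(c) != to_dict(a)

    def test_lognormal_hr_median(self, params):
        draws = sample_parameter_arrays(params, 10**5, seed=7)
        assert np.median(draws["effects.hr_lrr_5f"]) == pytest.approx(0.66, rel=0.01)

    def test_hr_pb_interval(self, params):
        """The reported 95% interval 0.34-2.27 around HR 0.88 confirms the
        printed SE 0.510 is on the log-hazard scale (to SE rounding)."""
        draws = sample_parameter_arrays(params, 10**5, seed=7)["effects.hr_lrr_pb"]
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert lo == pytest.approx(0.34, rel=0.10)
        assert hi == pytest.approx(2.27, rel=0.10)

    def test_sampled_set_respects_invariants(self, params):
        for seed in range(25):
            sp = sample_parameters(params, seed=seed)
            sp.validate()
            assert 0 <= sp.utilities.u_adf_sg1 <= 1
            assert sp.utilities.u_adf(Subgroup.SG2) >= 0
            for vec in (sp.skin_model.rtog_probs_15f, sp.skin_model.rtog_probs_5f):
                assert np.isclose(sum(vec), 1.0, atol=0.02)
                assert min(vec) >= 0
            assert all(v >= 0 for v in sp.rates.r_dr_death.values())

    def test_gamma_entries_match_printed_moments(self, params):
        draws = sample_parameter_arrays(params, 10**5, seed=11)
        for path, mean, se in [
            ("costs.adf_annual.SG1", 1216, 82),
            ("rates.r_adf_lrr.SG2", 0.0077, 0.0013),
            ("utilities.dr_decrement", 0.3030, 0.1550),
        ]:
            d = draws[path]
            assert d.mean() == pytest.approx(mean, abs=3 * se / np.sqrt(10**5))
            assert d.std() == pytest.approx(se, rel=0.02)

    def test_dr_death_rate_sampled_on_log_scale(self, params):
        specs = distribution_specs(params)
        assert specs["rates.r_dr_death.SG1"].kind == "lognormal"
        draws = sample_parameter_arrays(params, 10**5, seed=3)["rates.r_dr_death.SG2"]
        assert np.median(draws) == pytest.approx(0.21, rel=0.02)
        assert np.all(draws > 0)

    def test_copula_preserves_marginals_and_induces_correlation(self, params):
        names = ["effects.hr_lrr_5f", "rates.r_adf_lrr.SG2"]
        corr = np.array([[1.0, 0.9], [0.9, 1.0]])
        draws = sample_parameter_arrays(params, 20_000, seed=5, copula=(names, corr))
        assert np.median(draws[names[0]]) == pytest.approx(0.66, rel=0.02)
        assert draws[names[1]].mean() == pytest.approx(0.0077, rel=0.03)
        from scipy import stats
        rho = stats.spearmanr(draws[names[0]], draws[names[1]]).statistic
        assert rho > 0.8


class TestSerialization:
    def test_roundtrip_dict(self, params):
        params.costs.dr_annual = 9999.0
        clone = from_dict(to_dict(params))
        assert clone.costs.dr_annual == 9999.0
        assert to_dict(clone) == to_dict(params)

    def test_yaml_roundtrip(self, params, tmp_path):
        path = tmp_path / "params.yaml"
        rtcea.parameters.save_yaml(params, path)
        clone = rtcea.parameters.load_yaml(path)
        assert to_dict(clone) == to_dict(params)

    def test_parameter_table_contents(self, params):
        table = parameter_table(params)
        assert {"name", "value", "se", "distribution", "source"} <= set(table.columns)
        row = table.set_index("name").loc["costs.dr_annual"]
        assert row["value"] == 13_426
        assert row["distribution"] == "gamma"
        flagged = table.set_index("name").loc["rates.r_dr_death.SG1", "note"]
        assert "log-scale" in flagged


def test_distribution_spec_validation():
    with pytest.raises(InvalidParameterError):
        DistributionSpec("gamma", mean=-1, se=1)
    with pytest.raises(InvalidParameterError):
        DistributionSpec("nonsense")
    with pytest.raises(InvalidParameterError):
        DistributionSpec("dirichlet", alphas=(0.0, 0.0))
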