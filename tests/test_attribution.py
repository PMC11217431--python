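import numpy as np
import pandas as pd
import pytest

from neoclim import attribution, dlnm
from neoclim.attribution import (RANGE_LABELS, SIDE_OF_RANGE, attributable_rate,
                                 case_af, climate_excess, monte_carlo_ui, scenario_burden)

from conftest import make_model


@pytest.fixture()
def model(quadratic_model):
    return quadratic_model


def scaled_model(model, exposure_vec, target_sum):
    """Rescale beta so the case's total log-RR sum equals ``target_sum`` exactly."""
    s = dlnm.lag_contributions(model, np.asarray(exposure_vec)[None, :]).sum()
    m = dlnm.recenter(model, model.mmt)
    m.beta = model.beta * (target_sum / s)
    return m


class TestCaseAF:
    def test_zero_when_all_lags_at_reference(self, model):
        ca = case_af(model, np.full(3, model.mmt))
        assert ca.af == pytest.approx(0.0, abs=1e-12)

    def test_retained_sum_ln2_gives_half(self, model):
        x = np.array([90.0, 85.0, 80.0])
        m = scaled_model(model, x, np.log(2.0))
        assert case_af(m, x).af == pytest.approx(0.5, abs=1e-12)

    def test_protective_sum_gives_negative_fraction(self, model):
        x = np.array([90.0, 85.0, 80.0])
        m = scaled_model(model, x, np.log(0.9))
        assert case_af(m, x).af == pytest.approx(1.0 - 1.0 / 0.9, abs=1e-12)

    def test_heat_restriction_zeroes_cold_lags(self, model):
        x = np.array([80.0, 20.0, 70.0])
        ca_all = case_af(model, x)
        ca_heat = case_af(model, x, "heat")
        ca_cold = case_af(model, x, "cold")
        np.testing.assert_array_equal(ca_heat.retained, x > model.mmt)
        s = ca_all.contributions
        assert ca_heat.af == pytest.approx(1 - np.exp(-s[[0, 2]].sum()), abs=1e-14)
        assert ca_cold.af == pytest.approx(1 - np.exp(-s[1]), abs=1e-14)

    def test_brute_force_reconstruction_small(self, model):
        """AF equals manual reassembly from raw spline basis matrices."""
        rng = np.random.default_rng(2)
        spec = model.spec
        Rlag = spec.lag_basis()
        B = model.beta.reshape(spec.df_var, spec.df_lag)
        for _ in range(50):
            x = rng.uniform(0, 100, 3)
            s = 0.0
            for l in range(3):
                v = dlnm.ns_basis([x[l]], spec.var_spline)[0] - dlnm.ns_basis([model.mmt], spec.var_spline)[0]
                s += float(v @ B @ Rlag[l])
            assert case_af(model, x).af == pytest.approx(1 - np.exp(-s), abs=1e-12)


class TestScenarioBurden:
    def test_zero_coefficients_zero_burden(self):
        m = make_model(beta=np.zeros(6), mmt=50.0)
        E = np.random.default_rng(0).uniform(0, 100, (40, 3))
        b = scenario_burden(m, E)
        assert b.an == pytest.approx(0.0, abs=1e-12)
        assert b.heat_an == b.cold_an == 0.0

    def test_single_case_hand_computed(self, model):
        x = np.array([95.0, 5.0, 50.0])
        b = scenario_burden(model, x[None, :])
        assert b.an == pytest.approx(case_af(model, x).af, abs=1e-12)
        assert b.af == b.an

    def test_one_sided_cases_heat_plus_cold_equals_total(self, model):
        E = np.random.default_rng(1).uniform(model.mmt + 1, 100, (30, 3))
        b = scenario_burden(model, E)
        assert b.heat_an == pytest.approx(b.an, abs=1e-12)
        assert b.cold_an == 0.0
        assert b.side_gap == pytest.approx(0.0, abs=1e-12)

    def test_mixed_cases_report_signed_gap(self, model):
        E = np.random.default_rng(2).uniform(0, 100, (100, 3))
        b = scenario_burden(model, E)
        assert b.side_gap != 0.0
        assert abs(b.side_gap) < 0.1 * max(abs(b.an), 1.0)

    def test_range_bins_partition_sides_exactly(self, model):
        E = np.random.default_rng(3).uniform(0, 100, (200, 3))
        b = scenario_burden(model, E)
        heat = sum(b.by_range[k] for k in RANGE_LABELS if SIDE_OF_RANGE[k] == "heat")
        cold = sum(b.by_range[k] for k in RANGE_LABELS if SIDE_OF_RANGE[k] == "cold")
        assert heat == pytest.approx(b.heat_an, rel=1e-12, abs=1e-12)
        assert cold == pytest.approx(b.cold_an, rel=1e-12, abs=1e-12)


class TestClimateExcess:
    def test_identical_scenarios_zero_excess(self, model):
        E = np.random.default_rng(4).uniform(0, 100, (50, 3))
        f = scenario_burden(model, E, scenario="factual")
        c = scenario_burden(model, E.copy(), scenario="counterfactual")
        ex = climate_excess(f, c)
        assert ex.excess_an == 0.0 and ex.heat_excess_an == 0.0 and ex.cold_excess_an == 0.0

    def test_heat_increase_ratio_arithmetic(self, model):
        f = scenario_burden(model, np.random.default_rng(5).uniform(0, 100, (50, 3)), scenario="factual")
        c = scenario_burden(model, np.random.default_rng(6).uniform(0, 100, (50, 3)),
                            scenario="counterfactual")
        c.heat_an = f.heat_an / 1.46  # factual heat burden 46% above counterfactual
        ex = climate_excess(f, c)
        assert ex.heat_share_of_factual == pytest.approx(1 - 1 / 1.46, abs=1e-12)

    def test_scope_mismatch_rejected(self, model):
        E = np.random.default_rng(7).uniform(0, 100, (10, 3))
        f = scenario_burden(model, E, scope="pooled", scenario="factual")
        c = scenario_burden(model, E, scope="loc01", scenario="counterfactual")
        with pytest.raises(ValueError, match="scope"):
            climate_excess(f, c)


class TestAttributableRate:
    rates = pd.DataFrame({"country": ["A"], "births": [10000],
                          "m_neonat": [2000.0], "very_early_share": [0.375]})

    def test_rate_is_m_times_af(self):
        assert attributable_rate(0.01, self.rates, "A") == pytest.approx(20.0)
        assert attributable_rate(0.0, self.rates, "A") == 0.0

    def test_very_early_uses_share_of_m(self):
        assert attributable_rate(0.01, self.rates, "A", outcome="very_early") == pytest.approx(7.5)

    def test_missing_country_raises(self):
        with pytest.raises(KeyError):
            attributable_rate(0.01, self.rates, "B")


class TestMonteCarlo:
    def make_inputs(self, model, vcov_scale=0.0, n=60, seed=8):
        m = dlnm.recenter(model, model.mmt)
        m.vcov = vcov_scale * np.eye(m.beta.size)
        rng = np.random.default_rng(seed)
        ef = rng.uniform(0, 100, (n, 3))
        ec = np.clip(ef - 3.0, 0.26, None)
        return [(m, ef, ec)]

    def test_zero_covariance_collapses_to_point(self, model):
        inputs = self.make_inputs(model, vcov_scale=0.0)
        mc = monte_carlo_ui(inputs, n_draws=200, seed=1)
        b = scenario_burden(inputs[0][0], inputs[0][1])
        assert mc.loc["af_total_factual", "point"] == pytest.approx(b.af, abs=1e-12)
        assert (mc["hi"] - mc["lo"]).abs().max() == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_bit_identical(self, model):
        inputs = self.make_inputs(model, vcov_scale=1e-4)
        a = monte_carlo_ui(inputs, n_draws=300, seed=5)
        b = monte_carlo_ui(inputs, n_draws=300, seed=5)
        pd.testing.assert_frame_equal(a, b)
        c = monte_carlo_ui(inputs, n_draws=300, seed=6)
        assert not a.equals(c)

    def test_non_psd_covariance_rejected(self, model):
        m = dlnm.recenter(model, model.mmt)
        m.vcov = -np.eye(m.beta.size)
        with pytest.raises(ValueError, match="positive semi-definite"):
            monte_carlo_ui([(m, np.full((3, 3), 60.0), np.full((3, 3), 55.0))], n_draws=10, seed=0)

    def test_mmt_from_fit_held_fixed_across_scenarios(self, model):
        # counterfactual burdens are evaluated against the factual-fit MMT
        inputs = self.make_inputs(model)
        bfa = scenario_burden(inputs[0][0], inputs[0][1], scenario="factual")
        bcf = scenario_burden(inputs[0][0], inputs[0][2], scenario="counterfactual")
        assert inputs[0][0].mmt == model.mmt
        ex = climate_excess(bfa, bcf)
        assert ex.heat_excess_an == pytest.approx(bfa.heat_an - bcf.heat_an)
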