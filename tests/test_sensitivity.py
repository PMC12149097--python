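import numpy as np
import pytest

from mhspc_cea.econ_eval import DEFAULT_WTP
from mhspc_cea.sensitivity import (
    ParamSpec, moment_match, one_way_dsa, run_psa, sample_param,
    specs_from_parameters,
)


class TestMomentMatch:
    def test_gamma_from_published_range(self):
        spec = ParamSpec("cost.rezvilutamide", 823.03, 658.42, 987.63, "gamma")
        assert spec.se == pytest.approx(83.982, abs=1e-3)
        mm = moment_match(spec)
        assert mm["shape"] == pytest.approx((823.03 / spec.se) ** 2, rel=1e-12)
        assert mm["shape"] == pytest.approx(96.05, abs=0.05)
        assert mm["shape"] / mm["rate"] == pytest.approx(823.03, rel=1e-12)

    def test_beta_mean_equals_base(self):
        spec = ParamSpec("utility.pfs", 0.76, 0.684, 0.836, "beta")
        mm = moment_match(spec)
        mean = mm["alpha"] / (mm["alpha"] + mm["beta"])
        assert mean == pytest.approx(0.76, abs=1e-9)

    def test_beta_symmetric_at_half(self):
        mm = moment_match(ParamSpec("utility.pd", 0.5, 0.49, 0.51, "beta"))
        assert mm["alpha"] == pytest.approx(mm["beta"], rel=1e-9)

    def test_fixed_is_degenerate(self):
        mm = moment_match(ParamSpec("discount_rate", 0.05, 0.05, 0.05, "fixed"))
        rng = np.random.default_rng(0)
        draws = sample_param(ParamSpec("discount_rate", 0.05, 0.05, 0.05, "fixed"),
                             rng, 100)
        assert mm == {"dist": "fixed", "value": 0.05}
        assert np.all(draws == 0.05)

    def test_infeasible_beta_range_rejected(self):
        with pytest.raises(ValueError, match="narrow"):
            moment_match(ParamSpec("utility.pd", 0.01, 0.0, 0.9, "beta"))

    def test_bad_ordering_rejected(self):
        with pytest.raises(ValueError):
            ParamSpec("cost.x", 1.0, 2.0, 3.0)

    @pytest.mark.parametrize("spec", [
        ParamSpec("cost.rezvilutamide", 823.03, 658.42, 987.63, "gamma"),
        ParamSpec("utility.pfs", 0.76, 0.684, 0.836, "beta"),
    ])
    def test_sampling_round_trip_mean(self, spec):
        draws = sample_param(spec, np.random.default_rng(1), 1_000_000)
        assert draws.mean() == pytest.approx(spec.base, rel=0.005)


class TestOneWayDsa:
    def test_rezvilutamide_price_is_widest_bar(self, params, exp_model):
        specs = specs_from_parameters(params)
        tor = one_way_dsa(specs, exp_model)
        assert tor.iloc[0]["parameter"] == "cost.rezvilutamide"

    def test_unread_parameter_zero_width(self, params, exp_model):
        specs = [ParamSpec("cost.darolutamide", 1044.0, 835.2, 1252.8, "gamma")]
        tor = one_way_dsa(specs, exp_model)
        assert tor.iloc[0]["spread"] == 0.0  # not in the default basket

    def test_low_pfs_utility_raises_icer(self, params, exp_model):
        base = exp_model.evaluate().icer
        tor = one_way_dsa([ParamSpec("utility.pfs", 0.76, 0.684, 0.836, "beta")],
                          exp_model)
        assert tor.iloc[0]["icer_low"] > base
        assert tor.iloc[0]["icer_high"] < base

    def test_discount_rate_varied_over_dsa_range(self, params, exp_model):
        tor = one_way_dsa(specs_from_parameters(params), exp_model)
        row = tor[tor["parameter"] == "discount_rate"].iloc[0]
        assert row["spread"] > 0
        assert row["error"] == ""


class TestPsa:
    def test_all_fixed_collapses_to_base_case(self, params, exp_model):
        specs = [ParamSpec("cost.rezvilutamide", 823.03, 823.03, 823.03, "fixed")]
        res = run_psa(specs, exp_model, n_draws=50, seed=3)
        base = exp_model.evaluate()
        assert np.allclose(res.draws["delta_cost"], base.delta_cost)
        assert np.allclose(res.draws["delta_qaly"], base.delta_qaly)
        # CEAC is a step at the base ICER
        below = res.ceac[res.ceac["wtp"] < base.icer]["prob_cost_effective"]
        above = res.ceac[res.ceac["wtp"] > base.icer]["prob_cost_effective"]
        assert np.all(below == 0.0) and np.all(above == 1.0)

    def test_mean_delta_cost_near_deterministic(self, params, exp_model):
        """Model ~linear in costs: PSA mean dC within 3 MC standard errors
        of the deterministic dC."""
        specs = specs_from_parameters(params, include=("costs",))
        res = run_psa(specs, exp_model, n_draws=4000, seed=4)
        dc = res.draws["delta_cost"]
        se = dc.std(ddof=1) / np.sqrt(len(dc))
        assert abs(dc.mean() - exp_model.evaluate().delta_cost) <= 3 * se

    def test_reproducible_given_seed(self, params, exp_model):
        specs = specs_from_parameters(params)
        a = run_psa(specs, exp_model, n_draws=200, seed=11)
        b = run_psa(specs, exp_model, n_draws=200, seed=11)
        assert a.draws.equals(b.draws)
        assert a.ceac.equals(b.ceac)

    def test_ceac_monotone_when_all_gain_qalys(self, params, exp_model):
        specs = specs_from_parameters(params)
        res = run_psa(specs, exp_model, n_draws=500, seed=5)
        if (res.draws["delta_qaly"] > 0).all():
            assert np.all(np.diff(res.ceac["prob_cost_effective"]) >= 0)

    def test_ceac_limit_is_fraction_gaining_qalys(self, params, exp_model):
        specs = specs_from_parameters(params)
        res = run_psa(specs, exp_model, n_draws=300, seed=6)
        frac_gain = float((res.draws["delta_qaly"] > 0).mean())
        assert res.prob_cost_effective(1e15) == pytest.approx(frac_gain, abs=1e-12)

    def test_grid_includes_wtp_threshold(self, params, exp_model):
        res = run_psa(specs_from_parameters(params), exp_model, n_draws=10, seed=7)
        assert DEFAULT_WTP in res.ceac["wtp"].to_numpy()

    def test_invalid_draw_count_rejected(self, params, exp_model):
        with pytest.raises(ValueError):
            run_psa([], exp_model, n_draws=0, seed=0)
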