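import numpy as np
import pytest
from scipy import integrate, stats

from mhspc_cea.markov_engine import (
    ModelSettings, discount_factor, run_trace, transitions_from_curves,
)


def _exp_sf(rate):
    return lambda t: np.exp(-rate * np.asarray(t, dtype=float))


def _lognorm_sf(mu, sigma):
    def s(t):
        t = np.asarray(t, dtype=float)
        out = stats.norm.sf(np.log(np.maximum(t, 1e-300)), mu, sigma)
        return np.where(t <= 0, 1.0, out)
    return s


class TestDiscountFactor:
    def test_cycle_zero_is_one(self):
        assert discount_factor(0, ModelSettings()) == 1.0

    def test_zero_rate_always_one(self):
        st = ModelSettings(discount_annual=0.0)
        assert np.all(discount_factor(np.arange(170), st) == 1.0)

    def test_thirteen_year_value(self):
        st = ModelSettings()
        n = st.n_cycles  # 169 cycles ~ 12.96 years
        assert discount_factor(n, st) == pytest.approx(
            1.05 ** -(n * 28 / 365.25), rel=1e-12)
        assert discount_factor(n, st) == pytest.approx(0.531, abs=1e-3)

    def test_negative_index_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1, ModelSettings())


class TestSettings:
    def test_default_cycle_count(self):
        assert ModelSettings().n_cycles == 169

    def test_discount_outside_dsa_range_rejected(self):
        with pytest.raises(ValueError):
            ModelSettings(discount_annual=0.09)


class TestTransitions:
    def test_rows_stochastic_death_absorbing(self):
        st = ModelSettings()
        mats = transitions_from_curves(_exp_sf(0.05), _exp_sf(0.02), st)
        assert np.allclose(mats.sum(axis=2), 1.0, atol=1e-12)
        assert np.all(mats >= -1e-15)
        assert np.allclose(mats[:, 2], [0.0, 0.0, 1.0], atol=0)

    def test_no_progression_when_curves_equal(self):
        st = ModelSettings()
        mats = transitions_from_curves(_exp_sf(0.03), _exp_sf(0.03), st)
        tr = run_trace(mats, st, 1.0, 1.0)
        assert np.all(mats[:, 0, 1] == 0.0)
        assert np.allclose(tr.occupancy[:, 1], 0.0, atol=1e-12)

    def test_exponential_closed_form_boundaries(self):
        """Marginal matching reproduces S_pfs and 1-S_os at every cycle
        boundary to 1e-10 for exponential curves."""
        st = ModelSettings(half_cycle_correction=False)
        lam_p, lam_o = 0.2, 0.1  # per month; PFS exits faster than deaths accrue
        mats = transitions_from_curves(_exp_sf(lam_p), _exp_sf(lam_o), st)
        tr = run_trace(mats, st, 1.0, 1.0)
        tb = np.arange(st.n_cycles + 1) * st.cycle_months
        assert np.max(np.abs(tr.occupancy[:, 0] - np.exp(-lam_p * tb))) < 1e-10
        assert np.max(np.abs(tr.occupancy[:, 2] - (1 - np.exp(-lam_o * tb)))) < 1e-10
        # stationary per-cycle exit probabilities
        h = st.cycle_months
        assert np.allclose(1 - mats[:, 0, 0], 1 - np.exp(-lam_p * h), atol=1e-12)

    def test_pfs_above_os_clipped(self):
        st = ModelSettings()
        mats = transitions_from_curves(_exp_sf(0.01), _exp_sf(0.02), st)
        tr = run_trace(mats, st, 1.0, 1.0)
        assert np.all(tr.occupancy[:, 1] >= -1e-12)  # PD never negative

    def test_evaluator_outside_unit_interval_rejected(self):
        st = ModelSettings()
        with pytest.raises(ValueError):
            transitions_from_curves(lambda t: 1.5 * np.ones_like(np.asarray(t, float)),
                                    _exp_sf(0.02), st)


class TestRunTrace:
    def test_conservation_and_death_monotone(self):
        st = ModelSettings()
        mats = transitions_from_curves(_lognorm_sf(3.2, 0.9), _lognorm_sf(3.9, 0.8), st)
        tr = run_trace(mats, st, 0.76, 0.68)
        assert np.allclose(tr.occupancy.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diff(tr.occupancy[:, 2]) >= -1e-15)
        assert np.all(tr.occupancy >= -1e-15)

    def test_immortal_cohort_accrues_the_horizon(self):
        st = ModelSettings(discount_annual=0.0)
        one = lambda t: np.ones_like(np.asarray(t, dtype=float))
        mats = transitions_from_curves(one, one, st)
        tr = run_trace(mats, st, 1.0, 1.0)
        assert tr.total_ly == pytest.approx(st.n_cycles * st.cycle_years, rel=1e-12)

    def test_unit_utilities_make_qalys_equal_lifeyears(self):
        st = ModelSettings()
        mats = transitions_from_curves(_exp_sf(0.05), _exp_sf(0.02), st)
        tr = run_trace(mats, st, 1.0, 1.0)
        assert tr.total_qaly == tr.total_ly

    def test_geometric_discounting_closed_form(self):
        """Immortal-in-PFS cohort at constant cost X per cycle totals
        X * sum_t 1.05^(-t*28/365.25)."""
        st = ModelSettings()
        one = lambda t: np.ones_like(np.asarray(t, dtype=float))
        mats = transitions_from_curves(one, one, st)
        tr = run_trace(mats, st, 1.0, 1.0, cost_pfs=100.0)
        oracle = 100.0 * np.sum(1.05 ** (-np.arange(st.n_cycles) * 28 / 365.25))
        assert tr.total_cost == pytest.approx(oracle, rel=1e-12)

    def test_partitioned_survival_qaly_oracle(self):
        """Discounted QALYs agree with direct numerical integration of the
        partitioned-survival areas within 0.5% at 28-day cycles."""
        st = ModelSettings()
        s_p, s_o = _lognorm_sf(np.log(20), 0.9), _lognorm_sf(np.log(40), 0.8)
        mats = transitions_from_curves(s_p, s_o, st)
        tr = run_trace(mats, st, 0.76, 0.68)
        r = np.log(1.05)
        horizon = st.n_cycles * st.cycle_years
        f = lambda ty: (0.76 * s_p(ty * 12.0)
                        + 0.68 * (s_o(ty * 12.0) - s_p(ty * 12.0))) * np.exp(-r * ty)
        oracle, _ = integrate.quad(f, 0.0, horizon, limit=500)
        assert tr.total_qaly == pytest.approx(oracle, rel=0.005)

    def test_death_and_entry_costs(self):
        st = ModelSettings(discount_annual=0.0)
        mats = transitions_from_curves(_exp_sf(0.5), _exp_sf(0.5), st)
        tr = run_trace(mats, st, 1.0, 1.0, entry_cost=10.0, death_cost=100.0)
        # everyone dies within the horizon: death cost paid ~once per patient
        assert tr.occupancy[-1, 2] > 0.999999
        assert tr.total_cost == pytest.approx(10.0 + 100.0 * tr.occupancy[-1, 2], rel=1e-9)

    def test_utility_outside_unit_interval_rejected(self):
        st = ModelSettings()
        mats = transitions_from_curves(_exp_sf(0.05), _exp_sf(0.02), st)
        with pytest.raises(ValueError):
            run_trace(mats, st, 1.2, 0.5)
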