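import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mhspc_cea.families import FAMILIES, sample
from mhspc_cea.surv_models import ParametricFit, fit, fit_all, select_model, survival_at


def _censored_sample(family, params, n, seed, cen_scale=200.0):
    rng = np.random.default_rng(seed)
    t = sample(family, params, n, rng)
    cen = rng.exponential(cen_scale, n)
    return np.minimum(t, cen), (t <= cen).astype(int)


def test_exponential_mle_closed_form():
    """Uncensored exponential MLE is n_events / sum(t); AIC/BIC follow."""
    rng = np.random.default_rng(0)
    t = rng.exponential(10.0, 400)
    f = fit((t, np.ones(400, int)), "exponential")
    rate_hat = 400 / t.sum()
    assert f.params[0] == pytest.approx(rate_hat, rel=1e-5)
    ll = 400 * np.log(rate_hat) - rate_hat * t.sum()
    assert f.loglik == pytest.approx(ll, abs=1e-6)
    assert f.aic == pytest.approx(2 * 1 - 2 * ll, abs=1e-6)
    assert f.bic == pytest.approx(np.log(400) - 2 * ll, abs=1e-6)


def test_lognormal_parameter_recovery():
    mu, sigma = 3.2, 0.8
    obs, ev = _censored_sample("lognormal", (mu, sigma), 5000, seed=1)
    f = fit((obs, ev), "lognormal")
    assert f.converged
    assert f.params[0] == pytest.approx(mu, rel=0.03)
    assert f.params[1] == pytest.approx(sigma, rel=0.03)


def test_weibull_nests_exponential():
    """Weibull loglik is at least the exponential's; at shape 1 the two
    likelihoods agree."""
    obs, ev = _censored_sample("exponential", (0.08,), 800, seed=2)
    fe, fw = fit((obs, ev), "exponential"), fit((obs, ev), "weibull")
    assert fw.loglik >= fe.loglik - 1e-6
    from mhspc_cea.families import get_family
    wei = get_family("weibull")
    ll_shape1 = (wei.logpdf(obs[ev == 1], (1.0, 1 / fe.params[0])).sum()
                 + wei.logsf(obs[ev == 0], (1.0, 1 / fe.params[0])).sum())
    assert ll_shape1 == pytest.approx(fe.loglik, abs=1e-8)


def test_gompertz_nests_exponential():
    obs, ev = _censored_sample("exponential", (0.08,), 800, seed=4)
    fe, fg = fit((obs, ev), "exponential"), fit((obs, ev), "gompertz")
    assert fg.loglik >= fe.loglik - 1e-6


def test_loglik_matches_lifelines():
    """Independent cross-check of the censored log-likelihood against
    lifelines' fitters for the families both implement."""
    from lifelines import LogNormalFitter, WeibullFitter

    obs, ev = _censored_sample("lognormal", (3.0, 0.9), 1500, seed=5)
    ours = fit((obs, ev), "lognormal")
    ll = LogNormalFitter().fit(obs, ev)
    assert ours.loglik == pytest.approx(ll.log_likelihood_, rel=1e-6)
    ours_w = fit((obs, ev), "weibull")
    wf = WeibullFitter().fit(obs, ev)
    assert ours_w.loglik == pytest.approx(wf.log_likelihood_, rel=1e-6)


def test_fit_needs_two_events():
    with pytest.raises(ValueError):
        fit((np.array([1.0, 2.0, 3.0]), np.array([1, 0, 0])), "weibull")


class TestSelectModel:
    def test_single_candidate_returned(self):
        obs, ev = _censored_sample("exponential", (0.1,), 200, seed=6)
        f = fit((obs, ev), "exponential")
        assert select_model([f]) is f

    def test_tie_broken_by_fewer_parameters(self):
        a = ParametricFit("exponential", np.array([0.1]), -100.0, 50, 50, True)
        b = ParametricFit("weibull", np.array([1.0, 10.0]), -99.0, 50, 50, True)
        assert a.aic == b.aic
        assert select_model([b, a]).family == "exponential"

    def test_no_converged_fit_errors(self):
        bad = ParametricFit("weibull", np.array([1.0, 10.0]), -np.inf, 50, 50, False)
        with pytest.raises(ValueError):
            select_model([bad])

    def test_bic_criterion_penalises_parameters_harder(self):
        obs, ev = _censored_sample("exponential", (0.1,), 2000, seed=7)
        fits = fit_all((obs, ev))
        assert select_model(fits, "bic").family == "exponential"


class TestSurvivalAt:
    def test_exponential_closed_form(self):
        f = ParametricFit("exponential", np.array([0.1]), 0.0, 10, 10, True)
        assert survival_at(f, 10.0) == pytest.approx(np.exp(-1.0), abs=1e-4)

    def test_lognormal_median_identity(self):
        f = ParametricFit("lognormal", np.array([3.0, 0.7]), 0.0, 10, 10, True)
        assert survival_at(f, np.exp(3.0)) == pytest.approx(0.5, abs=1e-12)

    def test_survival_starts_at_one(self):
        for fam, p in [("exponential", [0.1]), ("weibull", [1.3, 20.0]),
                       ("lognormal", [3.0, 0.7]), ("loglogistic", [2.0, 20.0]),
                       ("gompertz", [0.01, 0.05])]:
            f = ParametricFit(fam, np.array(p), 0.0, 10, 10, True)
            assert survival_at(f, 0.0) == 1.0

    def test_negative_time_rejected(self):
        f = ParametricFit("exponential", np.array([0.1]), 0.0, 10, 10, True)
        with pytest.raises(ValueError):
            survival_at(f, -1.0)


@given(fam=st.sampled_from(FAMILIES), seed=st.integers(0, 1000))
@settings(max_examples=30, deadline=None)
def test_survival_monotone_over_13_year_horizon(fam, seed):
    """S(t) is non-increasing and in [0,1] on a dense monthly grid out to
    13 years, for every family at random plausible parameters."""
    rng = np.random.default_rng(seed)
    params = {
        "exponential": [rng.uniform(0.005, 0.3)],
        "weibull": [rng.uniform(0.3, 3.0), rng.uniform(5, 60)],
        "lognormal": [rng.uniform(1.0, 4.5), rng.uniform(0.3, 1.5)],
        "loglogistic": [rng.uniform(0.5, 4.0), rng.uniform(5, 60)],
        "gompertz": [rng.uniform(0.001, 0.1), rng.uniform(-0.05, 0.1)],
    }[fam]
    f = ParametricFit(fam, np.array(params), 0.0, 10, 10, True)
    s = survival_at(f, np.linspace(0.0, 156.0, 800))
    assert np.all(s >= -1e-12) and np.all(s <= 1 + 1e-12)
    assert np.all(np.diff(s) <= 1e-12)
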