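import numpy as np
import pytest
import scipy.stats as st

from flotcea.survival_fit import (
    STANDARD_FAMILIES,
    FitError,
    compare_models,
    fit_by_id,
    fit_flexible,
    fit_parametric,
    transition_probability,
)

# one sampler per family, parameterized as the fitter reports them
_TRUE = {
    "exponential": {"rate": 1 / 15.0},
    "weibull": {"shape": 1.3, "scale": 20.0},
    "gompertz": {"rate": 0.025, "shape": 0.05},
    "lognormal": {"mu": 2.2, "sigma": 0.8},
    "loglogistic": {"alpha": 12.0, "beta": 1.8},
    "gamma": {"shape": 1.5, "scale": 10.0},
    "gengamma": {"a": 1.5, "c": 0.9, "scale": 12.0},
}


def _sample(family, n, rng):
    p = _TRUE[family]
    if family == "exponential":
        return rng.exponential(1 / p["rate"], n)
    if family == "weibull":
        return p["scale"] * rng.weibull(p["shape"], n)
    if family == "gompertz":
        b = p["shape"]
        return st.gompertz(p["rate"] / b, scale=1 / b).rvs(n, random_state=rng)
    if family == "lognormal":
        return np.exp(rng.normal(p["mu"], p["sigma"], n))
    if family == "loglogistic":
        return st.fisk(p["beta"], scale=p["alpha"]).rvs(n, random_state=rng)
    if family == "gamma":
        return rng.gamma(p["shape"], p["scale"], n)
    if family == "gengamma":
        return st.gengamma(p["a"], p["c"], scale=p["scale"]).rvs(n, random_state=rng)
    raise KeyError(family)


def _censored(family, n=2000, q=0.95, seed=0):
    rng = np.random.default_rng(seed)
    x = _sample(family, n, rng)
    cens = np.quantile(x, q)
    return np.minimum(x, cens), (x <= cens).astype(int)


@pytest.fixture(scope="module")
def weibull_data():
    return _censored("weibull", n=1500, q=0.9, seed=1)


class TestParametricFits:
    def test_exponential_closed_form_mle(self):
        t, e = _censored("exponential", seed=2)
        m = fit_parametric((t, e), "exponential")
        assert m.params["rate"] == pytest.approx(e.sum() / t.sum(), rel=1e-6)

    def test_weibull_nests_exponential(self, weibull_data):
        t, e = weibull_data
        m_exp = fit_parametric((t, e), "exponential")
        m_wb = fit_parametric((t, e), "weibull")
        assert m_wb.loglik >= m_exp.loglik - 1e-6

    def test_loglik_is_maximum(self, weibull_data):
        t, e = weibull_data
        m = fit_parametric((t, e), "weibull")
        rng = np.random.default_rng(0)
        for _ in range(10):
            pert = m.theta + rng.normal(0, 0.05, size=m.theta.shape)
            assert m._negloglik(pert) >= -m.loglik - 1e-6

    def test_aic_bic_identities(self, weibull_data):
        m = fit_parametric(weibull_data, "weibull")
        assert m.aic == pytest.approx(2 * m.k - 2 * m.loglik)
        assert m.bic == pytest.approx(m.k * np.log(m.n) - 2 * m.loglik)

    @pytest.mark.parametrize("family", STANDARD_FAMILIES)
    def test_parameter_recovery(self, family):
        t, e = _censored(family, n=2000, seed=0)
        m = fit_parametric((t, e), family)
        assert m.converged
        for name, true in _TRUE[family].items():
            assert m.params[name] == pytest.approx(true, rel=0.10), name

    @pytest.mark.parametrize("family,sf", [
        ("exponential", lambda p, t: np.exp(-p["rate"] * t)),
        ("weibull", lambda p, t: np.exp(-((t / p["scale"]) ** p["shape"]))),
        ("loglogistic", lambda p, t: 1 / (1 + (t / p["alpha"]) ** p["beta"])),
    ])
    def test_sf_matches_closed_form_via_cumhaz(self, family, sf):
        t, e = _censored(family, n=500, seed=3)
        m = fit_parametric((t, e), family)
        grid = np.linspace(0.5, 60, 40)
        closed = sf(m.params, grid)
        assert np.allclose(np.exp(-m.cumhaz(grid)), closed, atol=1e-8)

    def test_sf_invariants(self, weibull_data):
        m = fit_parametric(weibull_data, "gengamma")
        grid = np.linspace(0.0, 120.0, 200)
        s = m.sf(grid)
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all(np.diff(m.cumhaz(grid)) >= -1e-12)

    def test_no_events_rejected(self):
        with pytest.raises(FitError):
            fit_parametric((np.ones(5), np.zeros(5, dtype=int)), "exponential")

    def test_unknown_family_rejected(self):
        with pytest.raises(KeyError):
            fit_parametric((np.ones(5), np.ones(5, dtype=int)), "pareto")


class TestFlexibleFits:
    def test_rp_zero_knots_is_weibull(self, weibull_data):
        t, e = weibull_data
        m_wb = fit_parametric((t, e), "weibull")
        m_rp = fit_flexible((t, e), "rp", scale="hazard", n_knots=0)
        assert m_rp.loglik == pytest.approx(m_wb.loglik, abs=1e-3)

    @pytest.mark.parametrize("scale", ["hazard", "odds", "normal"])
    def test_rp_scales_fit_and_are_valid(self, weibull_data, scale):
        m = fit_flexible(weibull_data, "rp", scale=scale, n_knots=1)
        assert m.converged
        grid = np.linspace(0.0, 120.0, 100)
        s = m.sf(grid)
        assert s[0] == 1.0 and np.all(np.diff(s) <= 1e-9)

    def test_fp1_includes_weibull_as_power_zero(self, weibull_data):
        t, e = weibull_data
        m_wb = fit_parametric((t, e), "weibull")
        m_fp = fit_by_id((t, e), "fp1")
        assert m_fp.loglik >= m_wb.loglik - 1e-3

    def test_mcm_fixed_zero_cure_equals_latency_fit(self, weibull_data):
        t, e = weibull_data
        m_wb = fit_parametric((t, e), "weibull")
        m_mcm = fit_flexible((t, e), "mixture_cure", latency="weibull",
                             fix_cure_fraction=0.0)
        assert m_mcm.loglik == pytest.approx(m_wb.loglik, abs=1e-3)

    def test_mcm_recovers_cure_fraction(self):
        rng = np.random.default_rng(3)
        n = 2000
        cured = rng.random(n) < 0.3
        x = np.where(cured, np.inf, 10.0 * rng.weibull(1.5, n))
        e = (x <= 80.0).astype(int)
        m = fit_flexible((np.minimum(x, 80.0), e), "mixture_cure")
        assert abs(m.params["cure_fraction"] - 0.3) <= 0.05

    def test_gam_registered_but_unavailable(self):
        with pytest.raises(NotImplementedError):
            fit_flexible((np.ones(5), np.ones(5, dtype=int)), "gam")


class TestCompareModels:
    def test_single_fit_selected(self, weibull_data):
        m = fit_parametric(weibull_data, "weibull")
        table, sel = compare_models([m])
        assert sel is m and len(table) == 1

    def test_conservative_picks_lower_tail(self, weibull_data):
        t, e = weibull_data
        fits = [fit_parametric((t, e), f)
                for f in ("weibull", "lognormal", "gompertz")]
        table, sel = compare_models(fits, policy="conservative")
        best_aic = min(m.aic for m in fits)
        close = [m for m in fits if m.aic <= best_aic + 3.0]
        assert sel.sf(120.0) == min(m.sf(120.0) for m in close)

    def test_aic_policy_picks_best_aic(self, weibull_data):
        t, e = weibull_data
        fits = [fit_parametric((t, e), f) for f in ("weibull", "exponential")]
        _, sel = compare_models(fits, policy="aic")
        assert sel.aic == min(m.aic for m in fits)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_models([])


class TestTransitionProbability:
    def test_exponential_constant(self):
        t, e = _censored("exponential", n=500, seed=4)
        m = fit_parametric((t, e), "exponential")
        lam = m.params["rate"]
        expect = 1 - np.exp(-lam * 0.92)
        for u in (0, 5, 50):
            assert transition_probability(m, u, 0.92) == pytest.approx(expect)

    def test_cycle_zero_is_one_minus_sf(self, weibull_data):
        m = fit_parametric(weibull_data, "weibull")
        assert transition_probability(m, 0, 0.92) == pytest.approx(
            1 - float(m.sf(0.92)), rel=1e-9
        )

    def test_probabilities_in_unit_interval(self, weibull_data):
        m = fit_parametric(weibull_data, "gompertz")
        ps = [transition_probability(m, u, 0.92) for u in range(130)]
        assert all(0.0 <= p <= 1.0 for p in ps)

    def test_exhausted_survival_warns_and_returns_one(self):
        t, e = _censored("weibull", n=300, seed=5)
        m = fit_parametric((t, e), "weibull")
        # far beyond the support the survival evaluator underflows to 0
        with pytest.warns(UserWarning):
            assert transition_probability(m, 10_000_000, 100.0) == 1.0
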