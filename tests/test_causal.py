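"""ATE machinery: EIC algebra, plug-in, IPTW, TMLE, exact remainder."""

import numpy as np
import pytest

import halcausal as hc
from halcausal.basis import BasisDictionary, BasisFunction
from halcausal.causal import NuisanceFits
from halcausal.dgp import make_dgp
from halcausal.fit import HALFit


def _linear_qbar_fit(d_w: int = 2, tau: float = 0.5) -> HALFit:
    """Hand-built HAL fit computing exactly Q(W, A) = W1 + tau * A.

    Order-1 hinges at 0 reproduce the identity on [0, 1] covariates; the
    treatment column is the last column of the joint design.
    """
    terms = [BasisFunction((0,), (0.0,), 1), BasisFunction((d_w,), (0.0,), 1)]
    dic = BasisDictionary(terms=terms, n_features=d_w + 1, max_degree=1,
                          order=1)
    return HALFit(dictionary=dic, beta0=0.0, beta=np.array([1.0, tau]),
                  lam=0.0)


def test_eic_formula_arithmetic():
    # treated observation
    v = hc.eic_ate(np.array([0.7]), np.array([0.3]), np.array([0.7]),
                   np.array([0.5]), np.array([1.0]), np.array([1.0]), 0.4)
    assert v[0] == pytest.approx(0.6)
    # control observation
    v0 = hc.eic_ate(np.array([0.7]), np.array([0.3]), np.array([0.3]),
                    np.array([0.5]), np.array([0.0]), np.array([0.0]), 0.4)
    assert v0[0] == pytest.approx(0.6)
    with pytest.raises(ZeroDivisionError):
        hc.eic_ate(np.array([0.7]), np.array([0.3]), np.array([0.3]),
                   np.array([1.0]), np.array([0.0]), np.array([0.0]), 0.4)


def test_eic_mean_zero_with_true_nuisances():
    spec = make_dgp("linear")
    n = 100_000
    data = hc.gen_ate_dgp(spec, n, 21)
    psi0 = spec.truth["psi0"]
    eic = hc.eic_ate(spec.qbar0(data.W, 1), spec.qbar0(data.W, 0),
                     spec.qbar0(data.W, data.A), spec.g0(data.W),
                     data.A, data.Y, psi0)
    assert abs(eic.mean()) < 4 * eic.std(ddof=1) / np.sqrt(n)


def test_plugin_with_exact_constant_effect():
    data = hc.gen_ate_dgp("linear", 400, 2)
    qfit = _linear_qbar_fit()
    est = hc.plugin_ate(qfit, data, g=np.full(len(data), 0.5))
    assert est.psi == pytest.approx(0.5)
    # a fit that ignores treatment gives exactly zero
    qnull = _linear_qbar_fit(tau=0.0)
    est0 = hc.plugin_ate(qnull, data, g=np.full(len(data), 0.5))
    assert est0.psi == pytest.approx(0.0)


def test_iptw_known_randomization_closed_form():
    data = hc.gen_ate_dgp("null", 600, 4)
    g = np.full(len(data), 0.5)
    est = hc.iptw_ate(g, data, qbar=_linear_qbar_fit(tau=0.0))
    closed = 2 * (np.mean(data.A * data.Y) - np.mean((1 - data.A) * data.Y))
    assert est.psi == pytest.approx(closed)
    assert abs(est.psi) < 3 * est.se  # null recovery


@pytest.fixture(scope="module")
def linear_fit_500():
    data = hc.gen_ate_dgp("linear", 500, 31)
    q = hc.fit_hal(data.X, data.Y, knot_reduction="quantiles(6)",
                   cv_folds=5, n_lambda=30, lambda_min_ratio=1e-3, seed=0)
    g = hc.fit_hal(data.W, data.A, family="binomial",
                   knot_reduction="quantiles(6)", cv_folds=5, n_lambda=20,
                   lambda_min_ratio=1e-2, seed=1)
    return data, NuisanceFits(qbar=q, g=g)


def test_tmle_solves_eic_equation(linear_fit_500):
    data, nuis = linear_fit_500
    est = hc.tmle_ate(data, nuis)
    assert abs(est.pn_eic) < 1e-8
    assert est.ci[0] < est.psi < est.ci[1]
    assert est.se == pytest.approx(
        np.std(est.eic_values, ddof=1) / np.sqrt(len(data)))


def test_tmle_near_positivity_truncation_logged():
    data = hc.gen_ate_dgp("near-positivity", 600, 8)
    q = hc.fit_hal(data.X, data.Y, knot_reduction="quantiles(6)",
                   cv_folds=5, n_lambda=25, seed=0)
    g = hc.fit_hal(data.W, data.A, family="binomial",
                   knot_reduction="quantiles(6)", cv_folds=5, n_lambda=20,
                   lambda_min_ratio=1e-2, seed=1)
    est = hc.tmle_ate(data, NuisanceFits(qbar=q, g=g))
    assert abs(est.pn_eic) < 1e-8
    assert "n_g_truncated" in est.diagnostics


def test_undersmoothed_iptw_solves_score(linear_fit_500):
    data, nuis = linear_fit_500
    est = hc.iptw_ate(nuis.g, data, undersmooth=True, qbar=nuis.qbar)
    n = len(data)
    if est.diagnostics["undersmooth_achieved"]:
        sig = est.eic_values.std(ddof=1)
        assert abs(est.pn_eic) <= sig / (np.sqrt(n) * np.log(n)) + 1e-12


def test_double_robustness_direction():
    """With one nuisance misspecified TMLE stays near the truth; with both
    misspecified (and real confounding) it does not."""
    spec = make_dgp("linear", g_slope=4.0)
    data = hc.gen_ate_dgp(spec, 5000, 13)
    psi0 = spec.truth["psi0"]
    # intercept-only (misspecified) fits
    dic = BasisDictionary(terms=[BasisFunction((0,), (0.0,), 0)],
                          n_features=data.d + 1, max_degree=1, order=0)
    q_bad = HALFit(dic, beta0=float(data.Y.mean()), beta=np.zeros(1), lam=0.0)
    dic_g = BasisDictionary(terms=[BasisFunction((0,), (0.0,), 0)],
                            n_features=data.d, max_degree=1, order=0)
    from scipy.special import logit
    g_bad = HALFit(dic_g, beta0=float(logit(data.A.mean())),
                   beta=np.zeros(1), lam=0.0, family="binomial")
    g_good = hc.fit_hal(data.W, data.A, family="binomial",
                        knot_reduction="quantiles(8)", cv_folds=5,
                        n_lambda=20, lambda_min_ratio=1e-2, seed=3)
    est_half = hc.tmle_ate(data, NuisanceFits(qbar=q_bad, g=g_good))
    assert abs(est_half.psi - psi0) < 3 * est_half.se
    est_none = hc.tmle_ate(data, NuisanceFits(qbar=q_bad, g=g_bad))
    assert abs(est_none.psi - psi0) > 3 * est_none.se


def test_binary_outcome_estimates_respect_bounds():
    for s in range(5):
        data = hc.gen_ate_dgp("logistic", 300, 50 + s)
        q = hc.fit_hal(data.X, data.Y, family="binomial",
                       knot_reduction="quantiles(5)", cv_folds=5,
                       n_lambda=15, lambda_min_ratio=1e-2, seed=s)
        g = hc.fit_hal(data.W, data.A, family="binomial",
                       knot_reduction="quantiles(5)", cv_folds=5,
                       n_lambda=15, lambda_min_ratio=1e-2, seed=s + 1)
        nuis = NuisanceFits(qbar=q, g=g)
        for est in (hc.plugin_ate(q, data, g=g), hc.tmle_ate(data, nuis)):
            assert -1.0 <= est.psi <= 1.0


def test_exact_remainder_double_zero_and_product_form():
    spec = make_dgp("linear")
    W = np.random.default_rng(5).uniform(size=(50_000, 2))
    qhat = lambda w, a: spec.qbar0(w, a) + 0.3
    ghat = lambda w: np.clip(spec.g0(w) + 0.1, 1e-3, 1 - 1e-3)
    assert hc.exact_remainder_ate(spec.qbar0, ghat, spec.qbar0, spec.g0, W) == 0.0
    assert hc.exact_remainder_ate(qhat, spec.g0, spec.qbar0, spec.g0, W) == 0.0
    # constant g0 and constant nuisance errors: closed form
    # R2 = dg*dq/ghat + dg*dq/(1-ghat) with dg = g0-ghat = -0.1, dq = -0.3
    g0c = lambda w: np.full(len(w), 0.5)
    ghatc = lambda w: np.full(len(w), 0.6)
    r2 = hc.exact_remainder_ate(qhat, ghatc, spec.qbar0, g0c, W)
    expected = (-0.1 / 0.6) * (-0.3) - (0.1 / 0.4) * (-0.3)
    assert r2 == pytest.approx(expected, abs=1e-12)
    with pytest.raises(ZeroDivisionError):
        hc.exact_remainder_ate(qhat, lambda w: np.zeros(len(w)),
                               spec.qbar0, g0c, W[:10])


def test_asymptotic_linearity_proxy():
    """The sampling variance of the TMLE tracks the EIC-based variance
    within a modest factor across replications."""
    psis, vars_ = [], []
    for r in range(40):
        data = hc.gen_ate_dgp("linear", 400, 600 + r)
        q = hc.fit_hal(data.X, data.Y, knot_reduction="quantiles(5)",
                       cv_folds=5, n_lambda=20, lambda_min_ratio=1e-3,
                       seed=r)
        g = hc.fit_hal(data.W, data.A, family="binomial",
                       knot_reduction="quantiles(5)", cv_folds=5,
                       n_lambda=15, lambda_min_ratio=1e-2, seed=r + 1)
        est = hc.tmle_ate(data, NuisanceFits(qbar=q, g=g))
        psis.append(est.psi)
        vars_.append(np.var(est.eic_values, ddof=1) / len(data))
    ratio = np.var(psis, ddof=1) / np.mean(vars_)
    assert 0.5 <= ratio <= 2.0
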