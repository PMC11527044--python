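"""Wald intervals, bootstrap path with plateau selection, working-model bands."""

import numpy as np
import pytest

import halcausal as hc
from halcausal.causal import NuisanceFits
from halcausal.inference import plateau_select


def test_wald_ci_normal_quantile_arithmetic():
    # eic values with sample sd exactly 1 and mean 0
    e = np.tile([1.0, -1.0], 50)
    e = e / e.std(ddof=1)
    lo, hi = hc.wald_ci(0.0, e, 0.95)
    assert (lo, hi) == pytest.approx((-0.196, 0.196), abs=5e-4)


def test_wald_ci_degenerate_warns():
    with pytest.warns(UserWarning):
        lo, hi = hc.wald_ci(1.0, np.zeros(20), 0.95)
    assert lo == hi == 1.0


def test_wald_ci_levels_nested():
    rng = np.random.default_rng(0)
    e = rng.normal(size=200)
    i90 = hc.wald_ci(0.3, e, 0.90)
    i95 = hc.wald_ci(0.3, e, 0.95)
    i99 = hc.wald_ci(0.3, e, 0.99)
    assert i99[0] <= i95[0] <= i90[0] <= i90[1] <= i95[1] <= i99[1]


def test_plateau_hand_computed_example():
    widths = [1.0, 2.0, 3.0, 3.05, 3.06]
    lams = np.array([1.0, 0.5, 0.25, 0.125, 0.0625])
    sel = plateau_select(widths, lams)
    assert sel.index == 2 and sel.lambda_plateau == 0.25


def test_plateau_degenerate_curves():
    lams = np.array([1.0, 0.5, 0.25, 0.125])
    with pytest.warns(UserWarning):
        assert plateau_select([1, 2, 3, 4], lams).index == 0  # linear
    with pytest.warns(UserWarning):
        assert plateau_select([2, 2, 2, 2], lams).index == 0  # constant
    with pytest.raises(ValueError):
        plateau_select([1, 2, 3], lams[:3])


def test_plateau_scale_equivariant():
    rng = np.random.default_rng(1)
    w = np.cumsum(np.abs(rng.normal(size=12)))
    lams = np.geomspace(1, 0.01, 12)
    assert plateau_select(w, lams).index == plateau_select(17.3 * w, lams).index


@pytest.fixture(scope="module")
def boot_setup():
    data = hc.gen_ate_dgp("linear", 300, 77)
    nuis = hc.fit_nuisances(data, knot_reduction="quantiles(5)", cv_folds=5,
                            n_lambda=25, lambda_min_ratio=1e-3, seed=0)
    return data, nuis


def test_bootstrap_reproducible_and_widths_grow(boot_setup):
    data, nuis = boot_setup
    bp1 = hc.bootstrap_ci_path(data, nuisances=nuis, B=60, seed=5,
                               grid_size=4, index_span=12)
    bp2 = hc.bootstrap_ci_path(data, nuisances=nuis, B=60, seed=5,
                               grid_size=4, index_span=12)
    assert np.array_equal(bp1.widths, bp2.widths)
    assert bp1.final_interval == bp2.final_interval
    # weakest penalty gives a wider interval than the CV penalty
    assert bp1.widths[-1] >= bp1.widths[0] * 0.9
    assert bp1.lambda_plateau in bp1.lambda_grid
    k = bp1.plateau_index
    assert bp1.final_interval == tuple(bp1.intervals[k])


def test_bootstrap_percentile_variant(boot_setup):
    data, nuis = boot_setup
    bp = hc.bootstrap_ci_path(data, nuisances=nuis, B=40, seed=6,
                              grid_size=4, index_span=10,
                              interval="percentile")
    assert np.all(bp.intervals[:, 0] <= bp.intervals[:, 1])


def test_bootstrap_near_degenerate_noise():
    """Tiny outcome noise with a constant effect: intervals almost collapse."""
    spec = hc.make_dgp("linear", noise_sd=0.01)
    data = hc.gen_ate_dgp(spec, 300, 3)
    nuis = hc.fit_nuisances(data, knot_reduction="quantiles(5)", cv_folds=5,
                            n_lambda=25, seed=0)
    bp = hc.bootstrap_ci_path(data, nuisances=nuis, B=40, seed=1,
                              grid_size=4, index_span=10)
    assert np.all(bp.widths < 0.15)


def test_working_model_covariance_properties():
    rng = np.random.default_rng(2)
    data = hc.gen_ate_dgp("linear", 400, 12)
    res = hc.fit_hal(data.X, data.Y, knot_reduction="quantiles(5)",
                     cv_folds=5, n_lambda=25, seed=0)
    rel = hc.relaxed_fit(res.fit, data.X, data.Y, design=res.design)
    cb = hc.working_model_covariance(rel, data.X, data.Y)
    assert np.allclose(cb.cov, cb.cov.T, atol=1e-10)
    evals = np.linalg.eigvalsh(cb.cov)
    assert evals.min() >= -1e-10


def test_working_model_single_column_matches_hc0():
    """One-regressor sandwich variance agrees with the classical robust
    formula computed by hand."""
    rng = np.random.default_rng(3)
    n = 300
    x = (rng.uniform(size=n) > 0.4).astype(float)
    y = 1.0 + 2.0 * x + rng.normal(size=n) * (1 + x)
    from halcausal.basis import BasisDictionary, BasisFunction
    from halcausal.fit import HALFit

    dic = BasisDictionary(terms=[BasisFunction((0,), (1.0,), 0)],
                          n_features=1, max_degree=1, order=0)
    fit = HALFit(dic, 0.0, np.array([1.0]), 0.0)
    rel = hc.relaxed_fit(fit, x[:, None], y)
    cb = hc.working_model_covariance(rel, x[:, None], y)
    A = np.column_stack([np.ones(n), x])
    resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
    bread = np.linalg.inv(A.T @ A)
    hand = bread @ (A.T * resid**2) @ A @ bread
    assert np.allclose(cb.cov, hand, rtol=1e-8)


@pytest.fixture(scope="module")
def cate_setup():
    spec = hc.make_dgp("linear", interaction=(0.8, 0.0))
    data = hc.gen_ate_dgp(spec, 1500, 23)
    res = hc.fit_hal(data.X, data.Y, knot_reduction="quantiles(6)",
                     cv_folds=5, n_lambda=30, seed=0)
    rel = hc.relaxed_fit(res.fit, data.X, data.Y, design=res.design)
    cb = hc.working_model_covariance(rel, data.X, data.Y)
    return spec, data, rel, cb


def test_cate_curve_tracks_truth_and_band_ordering(cate_setup):
    spec, data, rel, cb = cate_setup
    grid = np.column_stack([np.linspace(0.1, 0.9, 20), np.full(20, 0.5)])
    inf = hc.cate_curve(rel, cb, grid, seed=0, X_train=data.X)
    truth = spec.truth["cate"](grid)
    # simultaneous band covers the truth at (nearly) every grid point
    inside = (inf.band_lo <= truth) & (truth <= inf.band_hi)
    assert inside.mean() >= 0.9
    # band at least as wide as the pointwise interval, everywhere
    assert np.all(inf.band_hi - inf.band_lo
                  >= inf.ci_hi - inf.ci_lo - 1e-12)
    # estimates increase with w1 (the interaction direction), loosely
    assert inf.estimates[-5:].mean() > inf.estimates[:5].mean()


def test_cate_without_treatment_terms_is_zero():
    rng = np.random.default_rng(4)
    n = 300
    X = np.column_stack([rng.uniform(size=n), rng.integers(0, 2, n)])
    y = X[:, 0] + rng.normal(size=n) * 0.1  # treatment-free outcome
    from halcausal.basis import BasisDictionary, BasisFunction
    from halcausal.fit import HALFit

    dic = BasisDictionary(terms=[BasisFunction((0,), (0.5,), 0)],
                          n_features=2, max_degree=1, order=0)
    fit = HALFit(dic, 0.0, np.array([1.0]), 0.0)
    rel = hc.relaxed_fit(fit, X, y)
    cb = hc.working_model_covariance(rel, X, y)
    grid = np.linspace(0.1, 0.9, 10)[:, None]
    inf = hc.cate_curve(rel, cb, grid, seed=0)
    assert np.all(inf.estimates == 0.0)
    assert np.all(inf.ci_lo <= 0.0) and np.all(inf.ci_hi >= 0.0)


def test_dose_response_binary_encoding_matches_plugin(cate_setup):
    _, data, rel, cb = cate_setup
    inf = hc.dose_response_curve(rel, cb, np.array([0.0, 1.0]), data, seed=0)
    plug = hc.plugin_ate(rel, data, g=np.full(len(data), 0.5))
    assert inf.estimates[1] - inf.estimates[0] == pytest.approx(plug.psi,
                                                                abs=1e-10)


def test_dose_response_flat_null_band():
    hits = 0
    for r in range(6):
        d = hc.gen_dose_dgp(800, 400 + r, effect=0.0)
        res = hc.fit_hal(d.X, d.Y, knot_reduction="quantiles(6)", cv_folds=5,
                         n_lambda=25, seed=r)
        rel = hc.relaxed_fit(res.fit, d.X, d.Y, design=res.design)
        cb = hc.working_model_covariance(rel, d.X, d.Y)
        grid = np.linspace(0.1, 0.9, 15)
        inf = hc.dose_response_curve(rel, cb, grid, d, seed=r)
        # a horizontal line fits inside the simultaneous band
        hits += inf.band_lo.max() <= inf.band_hi.min()
    assert hits >= 5


def test_dose_response_extrapolation_warns(cate_setup):
    _, data, rel, cb = cate_setup
    with pytest.warns(UserWarning):
        hc.dose_response_curve(rel, cb, np.array([-0.5, 0.0, 0.5, 2.0]),
                               data, seed=0)
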