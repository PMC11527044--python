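"""Inference for HAL-based estimators.

Three layers of uncertainty quantification:

* Wald intervals from the efficient influence curve (first-order
  asymptotics): psi_hat +/- z * sd(EIC)/sqrt(n).
* Nonparametric bootstrap intervals for HAL-TMLE along a grid of penalties
  weaker than the cross-validated one.  For each penalty, every bootstrap
  resample refits the HAL lasso, relaxes it on the re-selected support,
  and reruns the TMLE targeting step; interval widths grow as the penalty
  weakens and stabilize once the fit captures the true function, and the
  penalty at the plateau onset — located at the extremal discrete second
  derivative of the width curve — gives the final interval.  This trades
  computation for finite-sample coverage when the second-order remainder is
  not negligible.
* Delta-method inference on the HAL working model: treating the relaxed
  fit's support as a fixed parametric model, a sandwich covariance for its
  coefficients yields pointwise and simultaneous (Gaussian max-statistic)
  bands for linear functionals such as the CATE curve
  tau(w) = Qbar(w,1) - Qbar(w,0) and the dose-response curve
  theta(a) = (1/n) sum_i Qbar(W_i, a).  The covariance conditions on the
  selected support; the HAL working model is data-adaptive, which is what
  justifies this as an approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import sparse
from scipy.stats import norm

from .causal import NuisanceFits, fit_nuisances
from .dgp import CausalDataset
from .fit import FitResult, HALFit
from ._solver import logistic_newton, solve_lasso

__all__ = [
    "wald_ci",
    "BootstrapPath",
    "bootstrap_ci_path",
    "plateau_select",
    "CovBeta",
    "working_model_covariance",
    "WorkingModelInference",
    "cate_curve",
    "dose_response_curve",
]


def wald_ci(psi: float, eic_values: np.ndarray, level: float = 0.95):
    """Influence-curve-based Wald interval psi +/- z * sd(EIC)/sqrt(n)."""
    eic = np.asarray(eic_values, dtype=float)
    n = len(eic)
    if n < 2:
        raise ValueError("need at least 2 observations")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    sd = float(np.std(eic, ddof=1))
    if sd == 0.0:
        warnings.warn("degenerate influence curve (zero variance): "
                      "interval has zero width")
    z = norm.ppf(0.5 + level / 2)
    half = z * sd / np.sqrt(n)
    return (psi - half, psi + half)


class PlateauResult(NamedTuple):
    lambda_plateau: float
    index: int


def plateau_select(widths, lambda_grid, smooth_window: int | None = None,
                   rel_tol: float = 1e-12) -> PlateauResult:
    """Locate the plateau onset of a bootstrap-CI width curve.

    ``lambda_grid`` is ordered by decreasing penalty; widths typically rise
    as the penalty weakens and then flatten.  The selector computes discrete
    second differences of the (optionally moving-average smoothed) widths
    with respect to grid index and returns the penalty at the point of
    extremal concave curvature — the knee where the rise levels off.  With
    no measurable curvature (linear or constant widths) the largest penalty
    is returned with a warning.  The choice is invariant to rescaling all
    widths by a positive constant.
    """
    w = np.asarray(widths, dtype=float)
    lam = np.asarray(lambda_grid, dtype=float)
    if len(w) < 4:
        raise ValueError("plateau selection needs at least 4 grid points")
    if len(w) != len(lam):
        raise ValueError("widths and lambda_grid must align")
    if not np.all(np.isfinite(w)):
        raise ValueError("widths must be finite")
    if smooth_window is not None and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        wp = np.pad(w, pad, mode="edge")
        w = np.convolve(wp, kernel, mode="valid")[: len(lam)]
    d2 = w[2:] - 2 * w[1:-1] + w[:-2]
    scale = max(np.abs(w).max(), 1e-300)
    if np.abs(d2).max() <= rel_tol * scale:
        warnings.warn("width curve has no curvature; no plateau detected — "
                      "returning the largest penalty")
        return PlateauResult(float(lam[0]), 0)
    # widths rise then flatten: plateau onset is the most concave bend
    idx = int(np.argmin(d2)) + 1  # center point of the second difference
    return PlateauResult(float(lam[idx]), idx)


@dataclass
class BootstrapPath:
    """Per-penalty bootstrap intervals and the plateau-selected one."""

    lambda_grid: np.ndarray
    psi: np.ndarray                   # original-data TMLE at each penalty
    intervals: np.ndarray             # (L, 2)
    widths: np.ndarray
    B: int
    lambda_plateau: float
    plateau_index: int
    final_interval: tuple[float, float]
    level: float = 0.95
    boot_sd: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "lambda_grid": self.lambda_grid.tolist(),
            "psi": self.psi.tolist(),
            "intervals": self.intervals.tolist(),
            "widths": self.widths.tolist(),
            "B": self.B,
            "lambda_plateau": self.lambda_plateau,
            "final_interval": list(self.final_interval),
            "level": self.level,
        }


def bootstrap_ci_path(
    data: CausalDataset,
    nuisances: NuisanceFits | None = None,
    lambda_grid: np.ndarray | None = None,
    B: int = 200,
    seed: int = 0,
    level: float = 0.95,
    grid_size: int = 10,
    index_span: int = 40,
    interval: str = "normal",
    smooth_window: int | None = None,
    reselect_g_support: bool = False,
    **fit_kwargs,
) -> BootstrapPath:
    """Nonparametric bootstrap confidence intervals for HAL-TMLE.

    The outcome-regression penalty grid is restricted to values at or below
    the cross-validated penalty (equivalently, fits whose L1 norm is at
    least the CV-selected norm): ``grid_size`` penalties taken from the
    first ``index_span`` path points past lambda_cv.  For each penalty,
    each of ``B`` row resamples refits the lasso at that penalty (support
    re-selected within the resample), relaxes it, refits and relaxes the
    propensity at its own CV penalty, and reruns the TMLE targeting step.
    Resamples with a single treatment arm are rejected and redrawn (at most
    10B redraws).  Intervals are normal-approximation by default
    (psi_original +/- z * bootstrap sd); ``interval="percentile"`` uses the
    bootstrap quantiles instead.  The final interval is the one at the
    plateau of the width curve.
    """
    from .causal import _fluctuate  # local import avoids a cycle
    from scipy.special import expit, logit

    if B < 1:
        raise ValueError("B must be positive")
    if nuisances is None:
        nuisances = fit_nuisances(data, **fit_kwargs)
    qres: FitResult = nuisances.qbar
    gres: FitResult = nuisances.g
    if not isinstance(qres, FitResult) or not isinstance(gres, FitResult):
        raise ValueError("bootstrap_ci_path needs full FitResults "
                         "(from fit_hal / fit_nuisances)")
    n = len(data)
    z = norm.ppf(0.5 + level / 2)
    rng = np.random.default_rng(seed)

    # penalties with L1 norm >= the CV-selected norm (lambda <= lambda_cv)
    if lambda_grid is None:
        i0 = qres.cv.index_cv
        hi = min(len(qres.lambda_grid) - 1, i0 + index_span)
        idxs = np.unique(np.linspace(i0, hi, min(grid_size, hi - i0 + 1))
                         .astype(int))
        lambda_grid = qres.lambda_grid[idxs]
    else:
        lambda_grid = np.asarray(lambda_grid, dtype=float)
        idxs = np.array([int(np.argmin(np.abs(qres.lambda_grid - l)))
                         for l in lambda_grid])
    L = len(lambda_grid)

    # dense working copies: designs in the bootstrap are moderate (the
    # knot-reduction budget applies), and dense row slicing is what keeps
    # the B x L refit loop affordable
    Dq_dense = np.asarray(qres.design.todense())
    Dg_dense = np.asarray(gres.design.todense())
    # Q-design columns with treatment forced to 1 / 0 (counterfactuals)
    X1 = np.column_stack([data.W, np.ones(n)])
    X0 = np.column_stack([data.W, np.zeros(n)])
    D1_dense = np.asarray(qres.dictionary.evaluate(X1).todense())
    D0_dense = np.asarray(qres.dictionary.evaluate(X0).todense())

    q_pf = np.ones(Dq_dense.shape[1])
    g_lam = gres.lambda_cv
    g_fit = gres.fit

    g_supp0 = g_fit.support

    def g_on_rows(rows: np.ndarray, warm_g):
        """Propensity refit on a row multiset.

        By default the relaxed propensity is refit by Newton on the support
        selected by the original cross-validated fit (coefficients, not the
        support, vary across resamples); ``reselect_g_support=True`` reruns
        the full lasso at the CV penalty within each resample instead.
        """
        A = data.A[rows]
        if reselect_g_support:
            Dg_b = sparse.csc_matrix(Dg_dense[rows])
            gb0, gb, _ = solve_lasso(
                Dg_b, A, g_lam, "binomial",
                beta_init=None if warm_g is None else warm_g[1],
                beta0_init=0.0 if warm_g is None else warm_g[0],
                method="cd")
            gsupp = np.flatnonzero(gb)
            warm = np.concatenate([[gb0], gb[gsupp]])
        else:
            gsupp = g_supp0
            gb0, gb = 0.0, None
            warm = (np.concatenate([[g_fit.beta0], g_fit.beta[gsupp]])
                    if warm_g is None else warm_g)
        if len(gsupp) > 0:
            Dg_sub = np.column_stack([np.ones(len(rows)),
                                      Dg_dense[rows][:, gsupp]])
            coef = logistic_newton(Dg_sub, A, coef_init=warm)
            gW = expit(Dg_sub @ coef)
            warm_out = coef if not reselect_g_support else (gb0, gb)
        else:
            gW = np.full(len(rows), max(min(A.mean(), 1 - 1e-6), 1e-6))
            warm_out = warm_g
        return np.clip(gW, *nuisances.g_bounds), warm_out

    lo_y, hi_y = data.Y.min(), data.Y.max()
    span = hi_y - lo_y if hi_y > lo_y else 1.0
    sc = lambda v: np.clip((v - lo_y) / span, 0.0, 1.0)

    def targeted_psi(rows, Dq_b_csc, Dq_b, D1_b, D0_b, lam, warm_q, gW):
        """Q lasso refit at lam + relax + TMLE targeting on given rows."""
        Y, A = data.Y[rows], data.A[rows]
        # the penalized fit only proposes the support here (a relaxed refit
        # follows), so a looser tolerance than the final-fit default is safe
        qb0, qb, _ = solve_lasso(Dq_b_csc, Y, lam, qres.fit.family, q_pf,
                                 beta_init=None if warm_q is None else warm_q[1],
                                 beta0_init=0.0 if warm_q is None else warm_q[0],
                                 method="cd", tol=1e-5, max_iter=2000)
        # relaxed Q on the re-selected support, by normal equations
        supp = np.flatnonzero(qb)
        if len(supp) > 0:
            Amat = np.column_stack([np.ones(len(rows)), Dq_b[:, supp]])
            G = Amat.T @ Amat
            try:
                coef = np.linalg.solve(
                    G + 1e-10 * np.trace(G) * np.eye(G.shape[0]) / G.shape[0],
                    Amat.T @ Y)
            except np.linalg.LinAlgError:
                coef, *_ = np.linalg.lstsq(Amat, Y, rcond=None)
            qa = Amat @ coef
            q1 = coef[0] + D1_b[:, supp] @ coef[1:]
            q0 = coef[0] + D0_b[:, supp] @ coef[1:]
        else:
            qa = q1 = q0 = np.full(len(rows), Y.mean())

        # logistic fluctuation on the [0,1] outcome scale
        H = A / gW - (1 - A) / (1 - gW)
        eps = _fluctuate(sc(Y), sc(qa), H)
        upd = lambda q, h: expit(logit(np.clip(sc(q), 1e-9, 1 - 1e-9)) + eps * h)
        q1u = lo_y + span * upd(q1, 1 / gW)
        q0u = lo_y + span * upd(q0, -1 / (1 - gW))
        psi = float(np.mean(q1u - q0u))
        return psi, (qb0, qb)

    # original-data targeted estimates per penalty (warm start from the path)
    all_rows = np.arange(n)
    psi_orig = np.zeros(L)
    gW_orig, warm_g0 = g_on_rows(all_rows, None)
    Dq_csc_full = sparse.csc_matrix(Dq_dense)
    for li, lam in enumerate(lambda_grid):
        pf_fit = qres.path[idxs[li]]
        psi_orig[li], _ = targeted_psi(
            all_rows, Dq_csc_full, Dq_dense, D1_dense, D0_dense, lam,
            (pf_fit.beta0, pf_fit.beta), gW_orig)

    boot = np.full((L, B), np.nan)
    redraws = 0
    for b in range(B):
        while True:
            rows = rng.integers(0, n, size=n)
            if 0 < data.A[rows].sum() < n:
                break
            redraws += 1
            if redraws > 10 * B:
                raise RuntimeError("too many single-arm bootstrap resamples")
        gW_b, _ = g_on_rows(rows, warm_g0)
        Dq_b = Dq_dense[rows]
        Dq_b_csc = sparse.csc_matrix(Dq_b)
        D1_b, D0_b = D1_dense[rows], D0_dense[rows]
        warm_q = None
        for li, lam in enumerate(lambda_grid):
            psi_b, warm_q = targeted_psi(rows, Dq_b_csc, Dq_b, D1_b, D0_b,
                                         lam, warm_q, gW_b)
            boot[li, b] = psi_b

    sd = boot.std(axis=1, ddof=1)
    if interval == "normal":
        intervals = np.column_stack([psi_orig - z * sd, psi_orig + z * sd])
    elif interval == "percentile":
        a = (1 - level) / 2
        intervals = np.column_stack([
            np.quantile(boot, a, axis=1), np.quantile(boot, 1 - a, axis=1)])
    else:
        raise ValueError("interval must be 'normal' or 'percentile'")
    widths = intervals[:, 1] - intervals[:, 0]
    sel = plateau_select(widths, lambda_grid, smooth_window=smooth_window) \
        if L >= 4 else PlateauResult(float(lambda_grid[-1]), L - 1)
    return BootstrapPath(
        lambda_grid=np.asarray(lambda_grid, float), psi=psi_orig,
        intervals=intervals, widths=widths, B=B,
        lambda_plateau=sel.lambda_plateau, plateau_index=sel.index,
        final_interval=tuple(intervals[sel.index]), level=level, boot_sd=sd)


@dataclass
class CovBeta:
    """Sandwich covariance of (intercept, support coefficients)."""

    cov: np.ndarray
    support: np.ndarray  # dictionary indices aligned with cov rows 1..k


def working_model_covariance(relaxed: HALFit, X: np.ndarray,
                             y: np.ndarray) -> CovBeta:
    """Heteroscedasticity-robust covariance of the relaxed-fit coefficients.

    Treats the selected support as a fixed working model: with design
    A = [1, Phi_support], the HC0 sandwich is
    (A' W A)^{-1} A' diag((y - mu)^2) A (A' W A)^{-1}, with W = 1 for the
    gaussian family and W = mu(1-mu) for binomial.  Rank-deficient designs
    are pruned (first-come columns kept) with a warning.
    """
    from .fit import _independent_columns

    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    supp = relaxed.support
    D = relaxed.dictionary.subset(supp).evaluate(X).toarray() if len(supp) \
        else np.zeros((len(y), 0))
    A = np.column_stack([np.ones(len(y)), D])
    keep = _independent_columns(A)
    if len(keep) < A.shape[1]:
        warnings.warn(f"pruning {A.shape[1] - len(keep)} collinear columns "
                      "from the working-model design")
        A = A[:, keep]
        supp = supp[np.asarray(keep[1:]) - 1] if len(keep) > 1 else supp[:0]
    coef = np.concatenate([[relaxed.beta0], relaxed.beta[supp]])
    eta = A @ coef
    if relaxed.family == "binomial":
        from scipy.special import expit
        mu = expit(eta)
        wts = np.clip(mu * (1 - mu), 1e-10, None)
    else:
        mu = eta
        wts = np.ones(len(y))
    resid = y - mu
    bread = np.linalg.inv(A.T @ (A * wts[:, None]))
    meat = A.T @ (A * (resid ** 2)[:, None])
    cov = bread @ meat @ bread
    cov = (cov + cov.T) / 2
    return CovBeta(cov=cov, support=supp)


@dataclass
class WorkingModelInference:
    """Delta-method estimates and bands for a curve on an evaluation grid."""

    target_grid: np.ndarray
    estimates: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    level: float
    cov_beta: CovBeta = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "grid": np.asarray(self.target_grid).tolist(),
            "estimates": self.estimates.tolist(),
            "ci_lo": self.ci_lo.tolist(), "ci_hi": self.ci_hi.tolist(),
            "band_lo": self.band_lo.tolist(), "band_hi": self.band_hi.tolist(),
            "level": self.level,
        }


def _delta_bands(C: np.ndarray, coef: np.ndarray, cov: np.ndarray,
                 level: float, band_draws: int, seed: int):
    est = C @ coef
    S = C @ cov @ C.T
    se = np.sqrt(np.clip(np.diag(S), 0.0, None))
    z = norm.ppf(0.5 + level / 2)
    # simultaneous band: quantile of the max absolute standardized Gaussian
    rng = np.random.default_rng(seed)
    pos = se > 0
    if pos.any():
        Sp = S[np.ix_(pos, pos)]
        evals, evecs = np.linalg.eigh(Sp)
        root = evecs * np.sqrt(np.clip(evals, 0.0, None))
        draws = rng.standard_normal((band_draws, root.shape[1])) @ root.T
        maxz = np.abs(draws / se[pos]).max(axis=1)
        q = float(np.quantile(maxz, level))
        q = max(q, z)  # the band quantile cannot fall below the pointwise one
    else:
        q = z
    return est, se, z * se, q * se


def cate_curve(relaxed_qbar: HALFit, cov_beta: CovBeta, w_grid: np.ndarray,
               level: float = 0.95, band_draws: int = 10_000,
               seed: int = 0, X_train: np.ndarray | None = None
               ) -> WorkingModelInference:
    """CATE curve tau(w) = Qbar(w,1) - Qbar(w,0) with delta-method bands.

    The outcome fit must use the joint (W, A) design with A as the last
    column.  For each grid point the contrast vector is the difference of
    basis evaluations at treatment 1 and 0 (the intercept cancels), so
    tau_hat(w) = c(w)' beta_hat with pointwise variance c' cov c, and the
    simultaneous band uses the max-|Z| quantile over the grid from
    ``band_draws`` seeded Gaussian draws.
    """
    W = np.atleast_2d(np.asarray(w_grid, dtype=float))
    if X_train is not None:
        Xt = np.atleast_2d(np.asarray(X_train, float))[:, :W.shape[1]]
        if np.any(W < Xt.min(axis=0)) or np.any(W > Xt.max(axis=0)):
            warnings.warn("some grid points lie outside the observed "
                          "covariate range: extrapolating the working model")
    m = W.shape[0]
    supp = cov_beta.support
    sub = relaxed_qbar.dictionary.subset(supp)
    P1 = sub.evaluate(np.column_stack([W, np.ones(m)])).toarray() if len(supp) \
        else np.zeros((m, 0))
    P0 = sub.evaluate(np.column_stack([W, np.zeros(m)])).toarray() if len(supp) \
        else np.zeros((m, 0))
    C = np.column_stack([np.zeros(m), P1 - P0])  # intercept cancels
    coef = np.concatenate([[relaxed_qbar.beta0], relaxed_qbar.beta[supp]])
    est, se, half, band_half = _delta_bands(C, coef, cov_beta.cov, level,
                                            band_draws, seed)
    return WorkingModelInference(
        target_grid=W, estimates=est, ci_lo=est - half, ci_hi=est + half,
        band_lo=est - band_half, band_hi=est + band_half, level=level,
        cov_beta=cov_beta)


def dose_response_curve(relaxed_qbar: HALFit, cov_beta: CovBeta,
                        a_grid: np.ndarray, data,
                        level: float = 0.95, band_draws: int = 10_000,
                        seed: int = 0) -> WorkingModelInference:
    """Marginal dose-response theta(a) = (1/n) sum_i Qbar(W_i, a).

    The contrast vector averages the basis evaluations over the empirical
    covariate distribution at each dose; the intercept enters with weight 1.
    Doses outside the observed range trigger an extrapolation warning.
    """
    a_grid = np.asarray(a_grid, dtype=float).ravel()
    A_obs = np.asarray(data.A, dtype=float)
    if a_grid.min() < A_obs.min() or a_grid.max() > A_obs.max():
        warnings.warn("dose grid extends beyond observed treatment values: "
                      "extrapolating the working model")
    W = np.atleast_2d(data.W)
    n, m = W.shape[0], len(a_grid)
    supp = cov_beta.support
    sub = relaxed_qbar.dictionary.subset(supp)
    C = np.zeros((m, 1 + len(supp)))
    C[:, 0] = 1.0
    for j, a in enumerate(a_grid):
        if len(supp):
            Pa = sub.evaluate(np.column_stack([W, np.full(n, a)]))
            C[j, 1:] = np.asarray(Pa.mean(axis=0)).ravel()
    coef = np.concatenate([[relaxed_qbar.beta0], relaxed_qbar.beta[supp]])
    est, se, half, band_half = _delta_bands(C, coef, cov_beta.cov, level,
                                            band_draws, seed)
    return WorkingModelInference(
        target_grid=a_grid, estimates=est, ci_lo=est - half, ci_hi=est + half,
        band_lo=est - band_half, band_hi=est + band_half, level=level,
        cov_beta=cov_beta)
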