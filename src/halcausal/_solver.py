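"""Coordinate-descent solver for the HAL lasso.

The fitting objective is

    (1/n) * sum_i loss(y_i, b0 + X_i beta)  +  lambda * sum_j pf_j |beta_j|

with squared-error loss (gaussian) or the negative Bernoulli log-likelihood
under a logit link (binomial).  The intercept is never penalized and columns
are never standardized: the design columns are HAL basis functions, and
rescaling them would destroy the identity between the coefficient L1 norm
and the sectional variation norm of the fitted function.  Per-column penalty
factors ``pf_j >= 0`` allow user-supplied bases to be exempted from the
penalty entirely (``pf_j = 0``).

The worker operates on CSC arrays directly so large sparse designs are never
densified; the binomial family wraps the weighted-least-squares worker in an
IRLS loop, glmnet-style.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import sparse
from scipy.special import expit

__all__ = ["solve_lasso", "lasso_path", "lambda_max", "logistic_newton"]

_WMIN = 1e-5  # floor on IRLS working weights


@njit(cache=True)
def _cd_wls(indptr, indices, data, n, z, w, pf, alpha, beta, beta0,
            tol, max_iter):
    """Penalized weighted least squares by cyclic coordinate descent.

    Minimizes (1/(2n)) sum_i w_i (z_i - beta0 - (X beta)_i)^2
              + alpha * sum_j pf_j |beta_j|
    in place over ``beta``; returns (beta0, iterations, converged).
    Uses an active-set strategy: full sweeps alternate with sweeps over the
    current nonzero set until the largest coefficient update drops below
    ``tol``.
    """
    p = len(indptr) - 1
    # residual r = z - beta0 - X beta
    r = z - beta0
    for j in range(p):
        bj = beta[j]
        if bj != 0.0:
            for k in range(indptr[j], indptr[j + 1]):
                r[indices[k]] -= data[k] * bj
    # curvature c_j = (1/n) sum w x^2
    c = np.zeros(p)
    for j in range(p):
        acc = 0.0
        for k in range(indptr[j], indptr[j + 1]):
            acc += w[indices[k]] * data[k] * data[k]
        c[j] = acc / n
    wsum = w.sum()
    # convergence is declared when the largest single-coordinate decrease of
    # the quadratic objective, c_j * delta^2 / 2, falls below tol times the
    # weighted outcome variance (the glmnet criterion); this bounds the
    # relative suboptimality of the objective at roughly tol
    zbar = 0.0
    for i in range(len(z)):
        zbar += w[i] * z[i]
    zbar /= max(wsum, 1e-300)
    zvar = 0.0
    for i in range(len(z)):
        zvar += w[i] * (z[i] - zbar) ** 2
    thresh = tol * max(zvar / n, 1e-300)

    it = 0
    converged = False
    full_pass = True
    active = np.zeros(p, dtype=np.bool_)
    while it < max_iter:
        it += 1
        dmax = 0.0
        # intercept update (unpenalized)
        if wsum > 0.0:
            num = 0.0
            for i in range(len(r)):
                num += w[i] * r[i]
            d0 = num / wsum
            beta0 += d0
            for i in range(len(r)):
                r[i] -= d0
            v = (wsum / n) * d0 * d0
            if v > dmax:
                dmax = v
        for j in range(p):
            if not full_pass and not active[j]:
                continue
            cj = c[j]
            if cj <= 0.0:
                continue
            g = 0.0
            for k in range(indptr[j], indptr[j + 1]):
                g += w[indices[k]] * data[k] * r[indices[k]]
            g = g / n + cj * beta[j]
            t = alpha * pf[j]
            if g > t:
                nb = (g - t) / cj
            elif g < -t:
                nb = (g + t) / cj
            else:
                nb = 0.0
            d = nb - beta[j]
            if d != 0.0:
                beta[j] = nb
                for k in range(indptr[j], indptr[j + 1]):
                    r[indices[k]] -= data[k] * d
                v = cj * d * d
                if v > dmax:
                    dmax = v
            active[j] = nb != 0.0
        if dmax < thresh:
            if full_pass:
                converged = True
                break
            full_pass = True  # re-check all coordinates before declaring done
        else:
            full_pass = False
    return beta0, it, converged


def _as_csc(X) -> sparse.csc_matrix:
    if sparse.issparse(X):
        return X.tocsc().astype(np.float64)
    return sparse.csc_matrix(np.asarray(X, dtype=np.float64))


def lambda_max(X, y, family: str = "gaussian",
               penalty_factors: np.ndarray | None = None) -> float:
    """Smallest penalty at which every penalized coefficient is zero."""
    Xc = _as_csc(X)
    n = Xc.shape[0]
    y = np.asarray(y, dtype=float)
    pf = (np.ones(Xc.shape[1]) if penalty_factors is None
          else np.asarray(penalty_factors, dtype=float))
    if family == "gaussian":
        g = np.abs(Xc.T @ (y - y.mean())) / n
        scale = 2.0  # objective uses (1/n) sum (y-f)^2, not (1/(2n))
    elif family == "binomial":
        g = np.abs(Xc.T @ (y - y.mean())) / n
        scale = 1.0
    else:
        raise ValueError(f"unknown family: {family}")
    with np.errstate(divide="ignore"):
        vals = np.where(pf > 0, g / np.where(pf > 0, pf, 1.0), 0.0)
    out = scale * float(vals.max(initial=0.0))
    return out if out > 0 else 1.0


def _lars_applicable(family: str, pf: np.ndarray, n: int, p: int,
                     lam_min: float) -> bool:
    """Exact LARS is available for gaussian fits with strictly positive
    penalty factors (handled by column scaling) at moderate dense size."""
    return (family == "gaussian" and lam_min > 0 and p > 0
            and np.all(pf > 0) and n * p <= 20_000_000)


def _lars_gaussian(Xc: sparse.csc_matrix, y: np.ndarray, lambdas: np.ndarray,
                   pf: np.ndarray):
    """Exact gaussian lasso path via LARS, interpolated at ``lambdas``.

    The LARS-lasso path is piecewise linear in the penalty, so solutions at
    arbitrary penalties are exact linear interpolations between knots.
    Centering the columns makes the intercept unpenalized without touching
    the slope coefficients; dividing column j by pf_j turns a weighted L1
    penalty into a uniform one (coefficients are scaled back afterwards).
    """
    import warnings as _w

    from sklearn.linear_model import lars_path

    n, p = Xc.shape
    D = np.asarray(Xc.todense())
    uniform = np.all(pf == pf[0])
    if not uniform:
        D = D / pf
    colmeans = D.mean(axis=0)
    Dc = D - colmeans
    yc = y - y.mean()
    # sklearn's alpha equals lambda/2 for our (1/n) squared-error objective,
    # times the common factor for uniform penalty weights
    alpha_scale = pf[0] if uniform else 1.0
    amin = float(lambdas.min()) * alpha_scale / 2.0
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        alphas, _, coefs = lars_path(Dc, yc, method="lasso",
                                     alpha_min=amin * 0.999999)
    betas = np.empty((len(lambdas), p))
    beta0s = np.empty(len(lambdas))
    for i, lam in enumerate(lambdas):
        a = lam * alpha_scale / 2.0
        j = int(np.searchsorted(-alphas, -a))
        if j == 0:
            b = coefs[:, 0].copy()
        elif j >= len(alphas):
            b = coefs[:, -1].copy()
        else:
            t = (alphas[j - 1] - a) / (alphas[j - 1] - alphas[j])
            b = coefs[:, j - 1] + t * (coefs[:, j] - coefs[:, j - 1])
        beta0s[i] = y.mean() - colmeans @ b
        if not uniform:
            b = b / pf
        betas[i] = b
    return beta0s, betas


def solve_lasso(X, y, lam: float, family: str = "gaussian",
                penalty_factors: np.ndarray | None = None,
                beta_init: np.ndarray | None = None, beta0_init: float = 0.0,
                tol: float = 1e-7, max_iter: int = 100_000,
                method: str = "auto"):
    """Solve one lasso problem; returns (beta0, beta, converged)."""
    Xc = _as_csc(X)
    n, p = Xc.shape
    y = np.asarray(y, dtype=float)
    pf = (np.ones(p) if penalty_factors is None
          else np.asarray(penalty_factors, dtype=float))
    beta = np.zeros(p) if beta_init is None else beta_init.astype(float).copy()
    beta0 = float(beta0_init)

    if method == "auto" and _lars_applicable(family, pf, n, p, lam):
        b0s, bs = _lars_gaussian(Xc, y, np.array([lam]), pf)
        return float(b0s[0]), bs[0], True

    if family == "gaussian":
        w = np.ones(n)
        beta0, _, conv = _cd_wls(Xc.indptr, Xc.indices, Xc.data, n, y.copy(),
                                 w, pf, lam / 2.0, beta, beta0, tol, max_iter)
        return beta0, beta, conv
    if family != "binomial":
        raise ValueError(f"unknown family: {family}")

    # IRLS with penalized WLS inner solves
    if beta_init is None and beta0 == 0.0:
        pbar = min(max(y.mean(), 1e-6), 1 - 1e-6)
        beta0 = float(np.log(pbar / (1 - pbar)))
    conv = False
    # partial inner solves (capped sweep count) with outer re-linearization,
    # glmnet-style; joint convergence is declared on the coefficient change
    # across an outer iteration
    inner_iter = min(max_iter, 50)
    for _ in range(200):
        eta = beta0 + Xc @ beta
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), _WMIN)
        z = eta + (y - mu) / w
        b_old, b0_old = beta.copy(), beta0
        beta0, _, _ = _cd_wls(Xc.indptr, Xc.indices, Xc.data, n, z, w, pf,
                              lam, beta, beta0, tol, inner_iter)
        if max(np.max(np.abs(beta - b_old), initial=0.0),
               abs(beta0 - b0_old)) < 1e-5:
            conv = True
            break
    return beta0, beta, conv


def lasso_path(X, y, lambdas: np.ndarray, family: str = "gaussian",
               penalty_factors: np.ndarray | None = None,
               tol: float = 1e-7, max_iter: int = 100_000,
               method: str = "auto"):
    """Solution path over a decreasing penalty sequence.

    Gaussian fits with positive penalty factors use the exact LARS path;
    otherwise warm-started coordinate descent.  Returns (beta0s, betas)
    with betas of shape (len(lambdas), p).
    """
    Xc = _as_csc(X)
    n, p = Xc.shape
    lambdas = np.asarray(lambdas, dtype=float)
    pf_arr = (np.ones(p) if penalty_factors is None
              else np.asarray(penalty_factors, dtype=float))
    if method == "auto" and _lars_applicable(family, pf_arr, n, p,
                                             float(lambdas.min())):
        return _lars_gaussian(Xc, np.asarray(y, dtype=float), lambdas, pf_arr)
    beta0s = np.zeros(len(lambdas))
    betas = np.zeros((len(lambdas), p))
    beta = np.zeros(p)
    beta0 = 0.0
    first = True
    for i, lam in enumerate(lambdas):
        beta0, beta, _ = solve_lasso(
            Xc, y, lam, family, penalty_factors,
            beta_init=None if first else beta, beta0_init=beta0,
            tol=tol, max_iter=max_iter, method="cd")
        first = False
        beta0s[i] = beta0
        betas[i] = beta
    return beta0s, betas


def logistic_newton(D: np.ndarray, y: np.ndarray,
                    coef_init: np.ndarray | None = None,
                    max_iter: int = 50, tol: float = 1e-10) -> np.ndarray:
    """Unpenalized logistic regression by damped Newton on a small dense
    design (intercept included as the first column of ``D``).

    A tiny ridge proportional to the Hessian trace guards against exact
    separation; used for relaxed propensity refits where the support is
    small and speed matters.
    """
    n, k = D.shape
    coef = np.zeros(k) if coef_init is None else coef_init.copy()
    for _ in range(max_iter):
        eta = D @ coef
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = D.T @ (y - mu)
        H = D.T @ (D * w[:, None])
        H += 1e-10 * np.trace(H) / k * np.eye(k)
        step = np.linalg.solve(H, grad)
        # damp very large steps (separation)
        norm_step = np.abs(step).max()
        if norm_step > 10.0:
            step *= 10.0 / norm_step
        coef += step
        if norm_step < tol:
            break
    return coef
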