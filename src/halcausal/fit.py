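"""Fitting the Highly Adaptive LASSO.

HAL estimates a cadlag function of bounded sectional variation by lasso
regression on the tensor-product indicator design: minimizing

    (1/n) sum_i loss(y_i, b0 + Phi(x_i) beta) + lambda * ||beta||_1

over the HAL design Phi.  Because the columns are unstandardized indicator
(or hinge) bases, ``|b0| + ||beta||_1`` is exactly the sectional variation
norm of the fitted function, and the penalty is a variation-norm bound in
Lagrangian form.  The penalty is selected by V-fold cross-validation over a
log-spaced grid from ``lambda_max`` (all coefficients zero) downward;
``undersmooth_select`` weakens it further until a target score equation is
solved to within sigma_n / (sqrt(n) * log n), and ``relaxed_fit`` refits the
selected support without a penalty.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from scipy import sparse
from scipy.special import expit

from . import basis as _basis
from ._solver import lambda_max, lasso_path, solve_lasso

__all__ = [
    "HALFit",
    "CVResult",
    "FitResult",
    "fit_hal",
    "relaxed_fit",
    "undersmooth_select",
    "predict",
]

#: convergence tolerance on coefficient updates and iteration cap
TOL = 1e-7
MAX_ITER = 100_000
N_LAMBDA = 100
LAMBDA_MIN_RATIO = 1e-4


@dataclass
class HALFit:
    """A fitted HAL model: basis dictionary plus lasso coefficients."""

    dictionary: _basis.BasisDictionary
    beta0: float
    beta: np.ndarray
    lam: float
    family: str = "gaussian"
    relaxed: bool = False
    penalty_factors: np.ndarray | None = None
    #: include |beta0| in the reported variation norm (the intercept houses
    #: f(0), whose absolute value enters the sectional variation norm)
    include_intercept_in_norm: bool = True

    @property
    def variation_norm(self) -> float:
        vn = float(np.abs(self.beta).sum())
        if self.include_intercept_in_norm:
            vn += abs(self.beta0)
        return vn

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.beta)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        idx = self.support
        if len(idx) == 0:
            return np.full(np.atleast_2d(X).shape[0], self.beta0)
        Phi = self.dictionary.subset(idx).evaluate(X)
        return self.beta0 + Phi @ self.beta[idx]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predictions on the response scale (probabilities for binomial)."""
        eta = self.linear_predictor(X)
        return expit(eta) if self.family == "binomial" else eta

    # -- text serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "dictionary": self.dictionary.to_dict(),
            "beta0": float(self.beta0),
            "beta": [float(b) for b in self.beta],
            "lambda": float(self.lam),
            "family": self.family,
            "relaxed": self.relaxed,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "HALFit":
        return cls(
            dictionary=_basis.BasisDictionary.from_dict(d["dictionary"]),
            beta0=d["beta0"],
            beta=np.asarray(d["beta"], dtype=float),
            lam=d["lambda"],
            family=d["family"],
            relaxed=d.get("relaxed", False),
        )

    @classmethod
    def load(cls, path) -> "HALFit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class CVResult:
    lambda_grid: np.ndarray           # decreasing
    cv_risk: np.ndarray               # mean validation risk per lambda
    folds: np.ndarray                 # fold id per observation
    lambda_cv: float
    index_cv: int


@dataclass
class FitResult:
    """Output of :func:`fit_hal`: CV-selected fit, CV detail, and full path."""

    fit: HALFit
    cv: CVResult
    path: list[HALFit]
    dictionary: _basis.BasisDictionary
    design: sparse.csc_matrix = field(repr=False)
    lambda_grid: np.ndarray = field(default=None)

    @property
    def lambda_cv(self) -> float:
        return self.cv.lambda_cv


def _risk(y: np.ndarray, pred: np.ndarray, family: str) -> float:
    if family == "gaussian":
        return float(np.mean((y - pred) ** 2))
    p = np.clip(pred, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _response(eta: np.ndarray, family: str) -> np.ndarray:
    return expit(eta) if family == "binomial" else eta


def fit_hal(
    X: np.ndarray,
    y: np.ndarray,
    family: str = "gaussian",
    lambda_grid: np.ndarray | None = None,
    n_lambda: int = N_LAMBDA,
    lambda_min_ratio: float = LAMBDA_MIN_RATIO,
    cv_folds: int = 10,
    order: int = 0,
    max_degree: int | None = None,
    knot_reduction="auto",
    penalty_factors: np.ndarray | None = None,
    dictionary: _basis.BasisDictionary | None = None,
    seed: int = 0,
    tol: float = TOL,
    max_iter: int = MAX_ITER,
) -> FitResult:
    """Fit HAL with a cross-validation-selected penalty.

    Builds the basis dictionary from the data (unless one is supplied),
    solves the lasso path over a decreasing log-spaced ``lambda`` grid of
    ``n_lambda`` values from ``lambda_max`` down to
    ``lambda_min_ratio * lambda_max``, and selects the penalty minimizing
    V-fold cross-validated risk (ties broken toward the larger penalty).
    Fold assignment is a seeded permutation, so fits are reproducible.

    ``penalty_factors`` are per-column multipliers on the L1 penalty; a
    factor of 0 exempts that basis from penalization (prior-knowledge
    terms).  The intercept is always unpenalized.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X and y have different numbers of rows")
    if n < 10:
        raise ValueError("need at least 10 observations to cross-validate")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    if family == "binomial":
        uniq = np.unique(y)
        if not np.all(np.isin(uniq, (0.0, 1.0))):
            raise ValueError("binomial family requires y in {0, 1}")
        if len(uniq) == 1:
            warnings.warn("constant binary outcome: returning intercept-only fit")

    if dictionary is None:
        dictionary = _basis.enumerate_knots(
            X, max_degree=max_degree, knot_reduction=knot_reduction, order=order)
    design = dictionary.evaluate(X)
    p = design.shape[1]
    pf = np.ones(p) if penalty_factors is None else np.asarray(penalty_factors, float)

    if lambda_grid is None:
        lmax = lambda_max(design, y, family, pf)
        lambda_grid = np.geomspace(lmax, lambda_min_ratio * lmax, n_lambda)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if np.any(np.diff(lambda_grid) > 0):
        lambda_grid = np.sort(lambda_grid)[::-1]

    # deterministic fold assignment
    rng = np.random.default_rng(seed)
    folds = rng.permutation(n) % cv_folds
    val_risk = np.zeros((cv_folds, len(lambda_grid)))
    for v in range(cv_folds):
        tr, va = folds != v, folds == v
        Dtr = design[tr].tocsc()
        # columns identical on the training rows (knots separated only by
        # held-out points) are collapsed before solving, as in dictionary
        # construction; the retained representative carries the coefficient
        keep = _unique_column_indices(Dtr)
        b0s, bs = lasso_path(Dtr[:, keep], y[tr], lambda_grid, family,
                             pf[keep], tol=tol, max_iter=max_iter)
        eta_va = b0s[None, :] + (design[va][:, keep] @ bs.T)
        for li in range(len(lambda_grid)):
            val_risk[v, li] = _risk(y[va], _response(eta_va[:, li], family), family)
    cv_risk = val_risk.mean(axis=0)
    # ties toward larger lambda: first index attaining the minimum
    index_cv = int(np.flatnonzero(cv_risk <= cv_risk.min())[0])
    lambda_cv = float(lambda_grid[index_cv])

    b0s, bs = lasso_path(design, y, lambda_grid, family, pf,
                         tol=tol, max_iter=max_iter)
    path = [
        HALFit(dictionary, float(b0s[i]), bs[i].copy(), float(lambda_grid[i]),
               family=family, penalty_factors=pf)
        for i in range(len(lambda_grid))
    ]
    cv = CVResult(lambda_grid=lambda_grid, cv_risk=cv_risk, folds=folds,
                  lambda_cv=lambda_cv, index_cv=index_cv)
    return FitResult(fit=path[index_cv], cv=cv, path=path,
                     dictionary=dictionary, design=design,
                     lambda_grid=lambda_grid)


def _unique_column_indices(D: sparse.csc_matrix) -> np.ndarray:
    """Indices of the first occurrence of each distinct column."""
    dense = np.asarray(D.todense())
    seen: dict[bytes, int] = {}
    keep: list[int] = []
    for j in range(dense.shape[1]):
        key = dense[:, j].tobytes()
        if key not in seen:
            seen[key] = j
            keep.append(j)
    return np.asarray(keep, dtype=int)


def _independent_columns(D: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Indices of a maximal left-to-right linearly independent column set.

    Incremental Cholesky on the Gram matrix: a column is dropped when its
    residual variance after projection on the kept predecessors is ~0,
    i.e. it is exactly collinear with earlier columns ("keep first").
    """
    k = D.shape[1]
    G = D.T @ D
    scale = np.sqrt(np.maximum(np.diag(G), 1e-300))
    keep: list[int] = []
    L = np.zeros((k, k))
    for j in range(k):
        r = len(keep)
        lj = np.array([G[i, j] for i in keep])
        if r > 0:
            w = np.linalg.solve(L[:r, :r], lj) if r else lj
        else:
            w = lj
        s2 = G[j, j] - w @ w
        if s2 > (tol * scale[j]) ** 2:
            L[r, :r] = w
            L[r, r] = np.sqrt(s2)
            keep.append(j)
    return np.asarray(keep, dtype=int)


def relaxed_fit(fit: HALFit, X: np.ndarray, y: np.ndarray,
                design: sparse.csc_matrix | None = None) -> HALFit:
    """Unpenalized refit on the lasso-selected support (relaxed HAL).

    The support cannot grow; exactly collinear support columns are dropped
    (keeping the first) with a warning.  With an empty support the result is
    the intercept-only maximum likelihood fit.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    idx = fit.support
    beta = np.zeros_like(fit.beta)
    if len(idx) == 0:
        if fit.family == "binomial":
            pbar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
            b0 = float(np.log(pbar / (1 - pbar)))
        else:
            b0 = float(y.mean())
        return HALFit(fit.dictionary, b0, beta, fit.lam, fit.family, relaxed=True)

    if design is not None:
        D = design[:, idx].toarray()
    else:
        D = fit.dictionary.subset(idx).evaluate(X).toarray()
    keep = _independent_columns(D)
    if len(keep) < len(idx):
        warnings.warn(
            f"dropping {len(idx) - len(keep)} exactly-collinear support columns")
        idx = idx[keep]
        D = D[:, keep]

    if fit.family == "gaussian":
        A = np.column_stack([np.ones(len(y)), D])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        b0, bsub = float(coef[0]), coef[1:]
    else:
        b0, bsub, _ = solve_lasso(sparse.csc_matrix(D), y, 0.0,
                                  family="binomial",
                                  penalty_factors=np.zeros(D.shape[1]))
    beta[idx] = bsub
    return HALFit(fit.dictionary, b0, beta, fit.lam, fit.family, relaxed=True)


class UndersmoothResult(NamedTuple):
    lambda_u: float
    index: int
    achieved: bool


def undersmooth_select(
    path: list[HALFit],
    score_fn: Callable[[HALFit], tuple[float, float]],
    lambda_cv: float,
    n: int,
) -> UndersmoothResult:
    """Select an undersmoothed penalty along a decreasing-lambda path.

    Scanning from ``lambda_cv`` toward weaker penalties, returns the largest
    penalty at which the empirical mean of the target score is within
    ``sigma_n / (sqrt(n) * log n)`` of zero, where ``sigma_n^2`` is the
    empirical score variance from ``score_fn``.  If no penalty on the grid
    achieves the criterion the smallest one is returned with
    ``achieved=False``.
    """
    if len(path) == 0:
        raise ValueError("empty lambda path")
    lams = np.array([f.lam for f in path])
    if np.any(np.diff(lams) > 0):
        raise ValueError("path must be ordered by decreasing lambda")
    start = int(np.argmin(np.abs(lams - lambda_cv)))
    denom = np.sqrt(n) * np.log(n)
    for i in range(start, len(path)):
        mean, var = score_fn(path[i])
        thresh = np.sqrt(max(var, 0.0)) / denom
        if abs(mean) <= thresh:
            return UndersmoothResult(float(lams[i]), i, True)
    return UndersmoothResult(float(lams[-1]), len(path) - 1, False)


def predict(fit: HALFit, X: np.ndarray) -> np.ndarray:
    """Response-scale predictions (module-level convenience)."""
    return fit.predict(X)
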