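"""HAL-based estimation of the average treatment effect.

For O = (W, A, Y) with binary A, the target is the g-computation estimand
psi = E[Qbar(W,1) - Qbar(W,0)] where Qbar(W,A) = E[Y|W,A].  Its canonical
gradient (efficient influence curve, EIC) in the nonparametric model is

    D*(O) = Qbar(W,1) - Qbar(W,0) - psi
            + (A/g(1|W) - (1-A)/g(0|W)) (Y - Qbar(W,A)),

and the TMLE updates an initial Qbar along a one-dimensional logistic
fluctuation with clever covariate H = A/g(1|W) - (1-A)/g(0|W) until the
empirical mean of D* is zero.  The exact second-order remainder
R2(P, P0) = Psi(P) - Psi(P0) + P0 D*(P) has the product form implemented in
:func:`exact_remainder_ate`; it vanishes when either nuisance is correct,
which is the double-robustness property.

Nuisances are fit with HAL (:mod:`halcausal.fit`): the outcome regression
on the joint (W, A) design so treatment-covariate interactions enter the
basis, and the propensity with the binomial family.  Plug-in and IPTW
estimators are provided alongside TMLE, with optional undersmoothing of the
relevant nuisance along its lasso path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import norm

from .dgp import CausalDataset
from .fit import FitResult, HALFit, fit_hal, undersmooth_select

__all__ = [
    "NuisanceFits",
    "ATEEstimate",
    "eic_ate",
    "fit_nuisances",
    "plugin_ate",
    "iptw_ate",
    "tmle_ate",
    "exact_remainder_ate",
]

#: default truncation of predicted propensities, applied symmetrically
G_BOUNDS = (0.005, 0.995)


@dataclass
class NuisanceFits:
    """HAL fits for the two ATE nuisances with propensity truncation."""

    qbar: FitResult | HALFit
    g: FitResult | HALFit
    g_bounds: tuple[float, float] = G_BOUNDS

    def qbar_fit(self) -> HALFit:
        return self.qbar.fit if isinstance(self.qbar, FitResult) else self.qbar

    def g_fit(self) -> HALFit:
        return self.g.fit if isinstance(self.g, FitResult) else self.g


@dataclass
class ATEEstimate:
    psi: float
    eic_values: np.ndarray
    se: float
    ci: tuple[float, float]
    method: str
    level: float = 0.95
    epsilon: float | None = None
    pn_eic: float = float("nan")
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "psi": self.psi, "se": self.se, "ci": list(self.ci),
            "method": self.method, "level": self.level,
            "epsilon": self.epsilon, "pn_eic": self.pn_eic,
            "n": int(len(self.eic_values)),
            "diagnostics": self.diagnostics,
        }


def _wald(psi: float, eic: np.ndarray, level: float):
    n = len(eic)
    se = float(np.std(eic, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    z = norm.ppf(0.5 + level / 2)
    return se, (psi - z * se, psi + z * se)


def eic_ate(QbarW1, QbarW0, QbarWA, gW, A, Y, psi: float) -> np.ndarray:
    """Efficient influence curve of the ATE evaluated observation-wise.

    ``gW`` is P(A=1|W); it must already be truncated away from 0 and 1.
    """
    gW = np.asarray(gW, dtype=float)
    if np.any(gW <= 0) or np.any(gW >= 1):
        raise ZeroDivisionError(
            "propensity at 0 or 1: truncate g before computing the EIC")
    A = np.asarray(A, dtype=float)
    H = A / gW - (1 - A) / (1 - gW)
    return (np.asarray(QbarW1, float) - np.asarray(QbarW0, float) - psi
            + H * (np.asarray(Y, float) - np.asarray(QbarWA, float)))


def fit_nuisances(
    data: CausalDataset,
    family: str = "gaussian",
    g_bounds: tuple[float, float] = G_BOUNDS,
    max_degree: int | None = None,
    knot_reduction=None,
    cv_folds: int = 10,
    n_lambda: int = 100,
    g_n_lambda: int = 50,
    g_lambda_min_ratio: float = 1e-3,
    seed: int = 0,
    **kwargs,
) -> NuisanceFits:
    """Fit Qbar on the joint (W, A) design and g on W, both by CV-HAL.

    The default knot policy reduces to 20 per-coordinate quantile knots —
    the customary sieve size for moderate n — and the propensity path uses
    a shorter, shallower penalty grid than the outcome regression (its
    deep tail drives probabilities to 0/1 and is rarely selected).  Pass
    ``knot_reduction="all"`` for the exhaustive basis.
    """
    if knot_reduction is None:
        knot_reduction = f"quantiles({min(20, len(data))})"
    qbar = fit_hal(data.X, data.Y, family=family, max_degree=max_degree,
                   knot_reduction=knot_reduction, cv_folds=cv_folds,
                   n_lambda=n_lambda, seed=seed, **kwargs)
    g_kwargs = dict(kwargs)
    g_kwargs.setdefault("lambda_min_ratio", g_lambda_min_ratio)
    g = fit_hal(data.W, data.A, family="binomial", max_degree=max_degree,
                knot_reduction=knot_reduction, cv_folds=cv_folds,
                n_lambda=g_n_lambda, seed=seed + 1, **g_kwargs)
    return NuisanceFits(qbar=qbar, g=g, g_bounds=g_bounds)


def _truncate_g(g: np.ndarray, bounds: tuple[float, float],
                diagnostics: dict | None = None) -> np.ndarray:
    lo, hi = bounds
    n_trunc = int(np.sum((g < lo) | (g > hi)))
    if diagnostics is not None:
        diagnostics["n_g_truncated"] = n_trunc
        diagnostics["g_bounds"] = [lo, hi]
    return np.clip(g, lo, hi)


def _qbar_predictions(qfit: HALFit, data: CausalDataset):
    X1 = np.column_stack([data.W, np.ones(len(data))])
    X0 = np.column_stack([data.W, np.zeros(len(data))])
    return qfit.predict(X1), qfit.predict(X0), qfit.predict(data.X)


def plugin_ate(qbar, data: CausalDataset, g=None,
               g_bounds: tuple[float, float] = G_BOUNDS,
               level: float = 0.95) -> ATEEstimate:
    """Untargeted g-computation plug-in: average of Qbar(W,1) - Qbar(W,0).

    ``g`` (a HAL fit, a FitResult, or precomputed probabilities) is used
    only for the reported influence-curve standard error; if omitted a HAL
    propensity is fit internally.
    """
    qfit = qbar.fit if isinstance(qbar, FitResult) else qbar
    q1, q0, qa = _qbar_predictions(qfit, data)
    psi = float(np.mean(q1 - q0))
    diagnostics: dict = {}
    if g is None:
        g = fit_hal(data.W, data.A, family="binomial", knot_reduction="auto",
                    cv_folds=5, n_lambda=50, seed=0)
    if isinstance(g, (FitResult, HALFit)):
        gfit = g.fit if isinstance(g, FitResult) else g
        gW = gfit.predict(data.W)
    else:
        gW = np.asarray(g, dtype=float)
    gW = _truncate_g(gW, g_bounds, diagnostics)
    eic = eic_ate(q1, q0, qa, gW, data.A, data.Y, psi)
    se, ci = _wald(psi, eic, level)
    return ATEEstimate(psi, eic, se, ci, "plugin", level,
                       pn_eic=float(eic.mean()), diagnostics=diagnostics)


def iptw_ate(g, data: CausalDataset, undersmooth: bool = False,
             qbar=None, g_bounds: tuple[float, float] = G_BOUNDS,
             weight_cap: float = 1e3, level: float = 0.95) -> ATEEstimate:
    """Inverse-probability-of-treatment-weighted ATE with HAL propensity.

    ``g`` may be a HAL fit, a FitResult, or a vector of known treatment
    probabilities (e.g. the randomization probability in an experiment).
    With ``undersmooth=True`` the propensity penalty is re-selected along
    the lasso path so the empirical mean of the ATE efficient influence
    curve is solved to within sigma_n / (sqrt(n) log n); this requires the
    full path, i.e. ``g`` must be a FitResult.  ``qbar`` (optional) supplies
    outcome-regression predictions for the EIC score; when omitted a HAL
    outcome fit is computed internally.
    """
    n = len(data)
    diagnostics: dict = {}
    if qbar is None:
        qbar = fit_hal(data.X, data.Y, knot_reduction="auto",
                       cv_folds=5, n_lambda=50, seed=0)
    qfit = qbar.fit if isinstance(qbar, FitResult) else qbar
    q1, q0, qa = _qbar_predictions(qfit, data)

    def psi_at(gW: np.ndarray) -> float:
        return float(np.mean(data.A * data.Y / gW
                             - (1 - data.A) * data.Y / (1 - gW)))

    if undersmooth:
        if not isinstance(g, FitResult):
            raise ValueError("undersmoothing needs the full lasso path "
                             "(pass the FitResult from fit_hal)")

        def score(fitk: HALFit):
            gW = _truncate_g(fitk.predict(data.W), g_bounds)
            eic = eic_ate(q1, q0, qa, gW, data.A, data.Y, psi_at(gW))
            return float(eic.mean()), float(eic.var(ddof=1))

        sel = undersmooth_select(g.path, score, g.lambda_cv, n)
        gfit = g.path[sel.index]
        diagnostics["lambda_undersmoothed"] = sel.lambda_u
        diagnostics["undersmooth_achieved"] = sel.achieved
        gW_raw = gfit.predict(data.W)
    elif isinstance(g, (FitResult, HALFit)):
        gfit = g.fit if isinstance(g, FitResult) else g
        gW_raw = gfit.predict(data.W)
    else:
        gW_raw = np.asarray(g, dtype=float)

    gW = _truncate_g(gW_raw, g_bounds, diagnostics)
    w = np.where(data.A == 1, 1 / gW, 1 / (1 - gW))
    if np.any(w > weight_cap):
        warnings.warn(
            f"{int(np.sum(w > weight_cap))} IPTW weights exceed {weight_cap}; "
            f"max weight {w.max():.1f} — check positivity")
    psi = psi_at(gW)
    eic = eic_ate(q1, q0, qa, gW, data.A, data.Y, psi)
    se, ci = _wald(psi, eic, level)
    return ATEEstimate(psi, eic, se, ci, "iptw", level,
                       pn_eic=float(eic.mean()), diagnostics=diagnostics)


def _fluctuate(y01: np.ndarray, q01: np.ndarray, H: np.ndarray) -> float:
    """MLE of epsilon in the logistic fluctuation logit Q* = logit Q + eps H.

    The score  sum_i H_i (y_i - expit(logit q_i + eps H_i))  is strictly
    decreasing in eps, so the root is unique; solved by bracketed brentq to
    near machine precision, which is what makes Pn D* = 0 hold to 1e-8.
    """
    lq = logit(np.clip(q01, 1e-9, 1 - 1e-9))

    def score(eps: float) -> float:
        return float(np.mean(H * (y01 - expit(lq + eps * H))))

    s0 = score(0.0)
    if s0 == 0.0:
        return 0.0
    lo, hi = -1.0, 1.0
    for _ in range(60):
        if score(lo) * score(hi) < 0:
            break
        lo *= 2.0
        hi *= 2.0
    else:
        raise RuntimeError("TMLE fluctuation did not bracket a root; "
                           "check propensity truncation and outcome scaling")
    return float(optimize.brentq(score, lo, hi, xtol=1e-14, rtol=8.9e-16,
                                 maxiter=500))


def tmle_ate(data: CausalDataset, nuisances: NuisanceFits,
             level: float = 0.95) -> ATEEstimate:
    """Targeted maximum likelihood estimate of the ATE.

    Continuous outcomes are affinely mapped to [0, 1] (observed min/max)
    for the logistic fluctuation and mapped back afterwards; this keeps the
    update a submodel of the bounded-outcome model, so the plug-in respects
    the global bounds on psi.  After targeting, the empirical mean of the
    EIC is zero up to root-solver tolerance.
    """
    n = len(data)
    diagnostics: dict = {}
    qfit = nuisances.qbar_fit()
    gfit = nuisances.g_fit()
    q1, q0, qa = _qbar_predictions(qfit, data)
    gW = _truncate_g(gfit.predict(data.W), nuisances.g_bounds, diagnostics)

    y = data.Y
    binary = nuisances.qbar_fit().family == "binomial" or (
        np.all(np.isin(np.unique(y), (0.0, 1.0))))
    if binary:
        a_, b_ = 0.0, 1.0
    else:
        a_, b_ = float(y.min()), float(y.max())
        if b_ <= a_:
            b_ = a_ + 1.0
    sc = lambda v: np.clip((v - a_) / (b_ - a_), 0.0, 1.0)
    y01 = sc(y)
    q1s, q0s, qas = sc(q1), sc(q0), sc(qa)

    H = data.A / gW - (1 - data.A) / (1 - gW)
    H1, H0 = 1 / gW, -1 / (1 - gW)
    eps = _fluctuate(y01, qas, H)
    diagnostics["epsilon"] = eps

    upd = lambda q, h: expit(logit(np.clip(q, 1e-9, 1 - 1e-9)) + eps * h)
    q1u = a_ + (b_ - a_) * upd(q1s, H1)
    q0u = a_ + (b_ - a_) * upd(q0s, H0)
    qau = np.where(data.A == 1, q1u, q0u)

    psi = float(np.mean(q1u - q0u))
    eic = eic_ate(q1u, q0u, qau, gW, data.A, data.Y, psi)
    se, ci = _wald(psi, eic, level)
    return ATEEstimate(psi, eic, se, ci, "tmle", level, epsilon=eps,
                       pn_eic=float(eic.mean()), diagnostics=diagnostics)


def exact_remainder_ate(qbar_hat, g_hat, qbar0, g0,
                        W_sample: np.ndarray) -> float:
    """Monte-Carlo value of the exact second-order remainder R2(P, P0).

    R2 = E0[ ((g0 - g)/g)(1|W) (Qbar0 - Qbar)(W, 1)
             - ((g0 - g)/g)(0|W) (Qbar0 - Qbar)(W, 0) ]

    with all functions evaluated over a large covariate sample from P0.
    Each nuisance argument is a callable: ``qbar*(W, a)`` and ``g*(W)``
    returning P(A=1|W).  Zero when either nuisance equals the truth.
    """
    W = np.atleast_2d(np.asarray(W_sample, dtype=float))
    g1 = np.asarray(g_hat(W), dtype=float)
    if np.any(g1 <= 0) or np.any(g1 >= 1):
        raise ZeroDivisionError("estimated propensity outside (0,1)")
    g1_0 = np.asarray(g0(W), dtype=float)
    dq1 = np.asarray(qbar0(W, 1), float) - np.asarray(qbar_hat(W, 1), float)
    dq0 = np.asarray(qbar0(W, 0), float) - np.asarray(qbar_hat(W, 0), float)
    term1 = (g1_0 - g1) / g1 * dq1
    # at a = 0 the relevant propensity is 1 - g(1|W)
    term0 = ((1 - g1_0) - (1 - g1)) / (1 - g1) * dq0
    return float(np.mean(term1 - term0))
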