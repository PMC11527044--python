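"""Synthetic data-generating processes with known truth.

Every downstream estimator in this package is exercised against simulated
data whose true average treatment effect (ATE), conditional effect, and —
for the univariate sinusoid — sectional variation norm are known exactly.
The sinusoid regression draws X ~ Uniform(-4, 4) and
Y = 2 sin((pi/2)|X|) + N(0, 1); over the full domain the mean function
completes two periods, so its total variation is 16 (eight monotone arcs of
height 2) and its value at the left endpoint is 0.

Registered causal scenarios (all with W ~ Uniform(0,1)^2 unless noted):

``linear``
    g0(1|W) = expit(c (W1 - 1/2)) with c = 2; Y = W1 + 0.5 A + q2 W2 +
    optional A x W interactions + N(0, sd).  psi0 = tau + gamma . E[W].
``null``
    A ~ Bernoulli(1/2) independent of (W, Y); Y = W1 + noise; psi0 = 0.
``near-positivity``
    g0(1|W) = expit(-7 + 8 W1), which dips to ~1e-3 near W1 = 0 so part of
    the covariate space has treatment probabilities in [0.001, 0.02] — a
    practical positivity violation.  Outcome model as in ``linear``.
``logistic``
    Binary outcome, Q0(W, A) = expit(b0 + b1 W1 + tau A); psi0 is
    closed-form because expit integrates analytically against Uniform(0,1).

All generators draw from a single ``numpy`` Generator seeded per call, so
identical arguments give byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from scipy.special import expit

__all__ = [
    "CausalDataset",
    "DGPSpec",
    "SinusoidData",
    "gen_sinusoid",
    "make_dgp",
    "gen_ate_dgp",
    "gen_dose_dgp",
    "true_variation_norm_1d",
    "SCENARIOS",
]


class SinusoidData(NamedTuple):
    X: np.ndarray
    Y: np.ndarray


@dataclass
class CausalDataset:
    """Point-treatment observational data O = (W, A, Y)."""

    W: np.ndarray
    A: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        self.A = np.asarray(self.A, dtype=float).ravel()
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        n = self.W.shape[0]
        if len(self.A) != n or len(self.Y) != n:
            raise ValueError("W, A, Y must have aligned rows")
        for arr, nm in ((self.W, "W"), (self.A, "A"), (self.Y, "Y")):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{nm} contains missing or non-finite values")
        if not np.all(np.isin(self.A, (0.0, 1.0))):
            raise ValueError("treatment A must be binary 0/1")

    def __len__(self) -> int:
        return self.W.shape[0]

    @property
    def d(self) -> int:
        return self.W.shape[1]

    @property
    def X(self) -> np.ndarray:
        """Joint (W, A) matrix used to fit the outcome regression."""
        return np.column_stack([self.W, self.A])


@dataclass
class DGPSpec:
    """A registered scenario: generating equations plus known truth.

    ``qbar0(W, a)`` is the true outcome regression evaluated at treatment
    level ``a`` and ``g0(W)`` the true probability of treatment; ``truth``
    holds psi0 (and, when defined, the CATE function and outcome family).
    """

    name: str
    d: int
    params: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)
    qbar0: Callable[[np.ndarray, np.ndarray], np.ndarray] = None
    g0: Callable[[np.ndarray], np.ndarray] = None
    family: str = "gaussian"


def gen_sinusoid(n: int, seed: int) -> SinusoidData:
    """The univariate sinusoid experiment: Y = 2 sin((pi/2)|X|) + eps."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    X = rng.uniform(-4.0, 4.0, size=n)
    eps = rng.standard_normal(n)
    return SinusoidData(X=X, Y=2.0 * np.sin(np.pi / 2 * np.abs(X)) + eps)


def sinusoid_mean(x: np.ndarray) -> np.ndarray:
    """The sinusoid's true regression function f(x) = 2 sin((pi/2)|x|)."""
    return 2.0 * np.sin(np.pi / 2 * np.abs(x))


def _logistic_uniform_integral(a: float, b: float) -> float:
    """E[expit(a + b U)] for U ~ Uniform(0, 1), b != 0 (closed form)."""
    if b == 0:
        return float(expit(a))
    return float((np.log1p(np.exp(a + b)) - np.log1p(np.exp(a))) / b)


def _make_linear(params: dict) -> DGPSpec:
    p = {"q_intercept": 0.0, "q_w": (1.0, 0.5), "tau": 0.5,
         "interaction": (0.0, 0.0), "g_slope": 2.0, "noise_sd": 1.0}
    p.update(params)
    qw = np.asarray(p["q_w"], float)
    gam = np.asarray(p["interaction"], float)
    d = len(qw)

    def qbar0(W, a):
        a = np.broadcast_to(np.asarray(a, float), (W.shape[0],))
        return p["q_intercept"] + W @ qw + a * (p["tau"] + W @ gam)

    def g0(W):
        return expit(p["g_slope"] * (W[:, 0] - 0.5))

    # E[W_k] = 1/2 under Uniform(0,1): psi0 = tau + gamma . E[W]
    psi0 = float(p["tau"] + 0.5 * gam.sum())
    cate = lambda W: p["tau"] + W @ gam
    return DGPSpec("linear", d, p, {"psi0": psi0, "cate": cate},
                   qbar0, g0, "gaussian")


def _make_null(params: dict) -> DGPSpec:
    p = {"noise_sd": 1.0}
    p.update(params)

    def qbar0(W, a):
        return W[:, 0]

    def g0(W):
        return np.full(W.shape[0], 0.5)

    return DGPSpec("null", 2, p, {"psi0": 0.0, "cate": lambda W: np.zeros(len(W))},
                   qbar0, g0, "gaussian")


def _make_near_positivity(params: dict) -> DGPSpec:
    p = {"tau": 0.5, "noise_sd": 1.0}
    p.update(params)

    def qbar0(W, a):
        a = np.broadcast_to(np.asarray(a, float), (W.shape[0],))
        return W[:, 0] + p["tau"] * a

    def g0(W):
        return expit(-7.0 + 8.0 * W[:, 0])

    return DGPSpec("near-positivity", 2, p,
                   {"psi0": float(p["tau"]), "cate": lambda W: np.full(len(W), p["tau"])},
                   qbar0, g0, "gaussian")


def _make_logistic(params: dict) -> DGPSpec:
    p = {"b0": -0.5, "b1": 1.0, "tau": 0.8, "g_slope": 0.8}
    p.update(params)

    def qbar0(W, a):
        a = np.broadcast_to(np.asarray(a, float), (W.shape[0],))
        return expit(p["b0"] + p["b1"] * W[:, 0] + p["tau"] * a)

    def g0(W):
        return expit(p["g_slope"] * (W[:, 0] - 0.5))

    psi0 = (_logistic_uniform_integral(p["b0"] + p["tau"], p["b1"])
            - _logistic_uniform_integral(p["b0"], p["b1"]))
    return DGPSpec("logistic", 2, p, {"psi0": psi0}, qbar0, g0, "binomial")


SCENARIOS: dict[str, Callable[[dict], DGPSpec]] = {
    "linear": _make_linear,
    "null": _make_null,
    "near-positivity": _make_near_positivity,
    "logistic": _make_logistic,
}


def make_dgp(name: str, **params) -> DGPSpec:
    """Instantiate a registered scenario with optional parameter overrides."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    return SCENARIOS[name](params)


def gen_ate_dgp(spec: DGPSpec | str, n: int, seed: int) -> CausalDataset:
    """Draw n i.i.d. copies of O = (W, A, Y) from a registered scenario."""
    if isinstance(spec, str):
        spec = make_dgp(spec)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.0, 1.0, size=(n, spec.d))
    A = (rng.random(n) < spec.g0(W)).astype(float)
    mu = spec.qbar0(W, A)
    if spec.family == "binomial":
        Y = (rng.random(n) < mu).astype(float)
    else:
        Y = mu + spec.params.get("noise_sd", 1.0) * rng.standard_normal(n)
    return CausalDataset(W=W, A=A, Y=Y)


@dataclass
class DoseResponseData:
    """Continuous-treatment data for dose-response estimation."""

    W: np.ndarray
    A: np.ndarray  # continuous dose
    Y: np.ndarray

    @property
    def X(self) -> np.ndarray:
        return np.column_stack([self.W, self.A])


def gen_dose_dgp(n: int, seed: int, effect: float = 1.0,
                 noise_sd: float = 1.0) -> DoseResponseData:
    """Continuous dose A ~ Uniform(0,1), Y = effect * A + 0.5 W1 + noise.

    With ``effect = 0`` the true dose-response curve is flat, which is the
    null case for simultaneous-band coverage checks.
    """
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.0, 1.0, size=(n, 1))
    A = rng.uniform(0.0, 1.0, size=n)
    Y = effect * A + 0.5 * W[:, 0] + noise_sd * rng.standard_normal(n)
    return DoseResponseData(W=W, A=A, Y=Y)


def true_variation_norm_1d(f: Callable[[np.ndarray], np.ndarray],
                           domain: tuple[float, float],
                           grid_size: int) -> float:
    """Grid oracle for the d=1 sectional variation norm |f(a)| + TV(f).

    Evaluates ``f`` on a uniform grid and sums absolute first differences;
    converges to the true norm for functions of bounded variation as the
    grid refines.  Serves as the independent check on the identity between
    a HAL fit's coefficient L1 norm and its variation norm.
    """
    a, b = domain
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    x = np.linspace(a, b, grid_size)
    vals = np.asarray(f(x), dtype=float)
    if not np.all(np.isfinite(vals)):
        raise FloatingPointError("f produced non-finite values on the grid")
    return float(abs(vals[0]) + np.abs(np.diff(vals)).sum())
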