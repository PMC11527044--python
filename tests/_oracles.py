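"""Shared independent oracles for the test suite.

The brute-force lasso oracle minimizes the penalized risk with a
general-purpose bound-constrained optimizer over a positive/negative
coefficient split — no code shared with the package's solvers.
"""

import numpy as np
from scipy.optimize import minimize


def brute_force_objective(X, y, lam, family="gaussian", pf=None):
    n, p = X.shape
    pf = np.ones(p) if pf is None else pf

    def obj(z):
        b0, b = z[0], z[1 : p + 1] - z[p + 1 :]
        eta = b0 + X @ b
        if family == "gaussian":
            loss = np.mean((y - eta) ** 2)
        else:
            loss = np.mean(np.logaddexp(0, eta) - y * eta)
        return loss + lam * np.sum(pf * np.abs(b))

    bounds = [(None, None)] + [(0, None)] * (2 * p)
    res = minimize(obj, np.zeros(1 + 2 * p), method="L-BFGS-B",
                   bounds=bounds,
                   options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12})
    return res.fun
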