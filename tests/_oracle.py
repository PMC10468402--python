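"""Independent brute-force oracle for the two-part hurdle likelihood.

Maximizes the logistic and Gaussian part log-likelihoods numerically
(BFGS / Nelder-Mead), sharing no code with the fitting engine under test.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit


def oracle_loglik(y, X):
    """Return (discrete_llf, continuous_llf) by direct numerical maximization."""
    Xv = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    z = (y > 0).astype(float)
    k = Xv.shape[1]

    def nll_disc(b):
        p = np.clip(expit(Xv @ b), 1e-12, 1 - 1e-12)
        return -(z * np.log(p) + (1 - z) * np.log1p(-p)).sum()

    rd = minimize(nll_disc, np.zeros(k), method="BFGS",
                  options={"gtol": 1e-10, "maxiter": 2000})
    det = y > 0
    yd, Xd = y[det], Xv[det]

    def nll_cont(theta):
        b, logs = theta[:-1], theta[-1]
        s2 = np.exp(2 * logs)
        r = yd - Xd @ b
        return 0.5 * len(yd) * np.log(2 * np.pi * s2) + 0.5 * (r ** 2).sum() / s2

    x0 = np.zeros(k + 1)
    rc = minimize(nll_cont, x0, method="Nelder-Mead",
                  options={"xatol": 1e-12, "fatol": 1e-13,
                           "maxiter": 20000, "maxfev": 40000})
    rc2 = minimize(nll_cont, rc.x, method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 5000})
    return -rd.fun, -min(rc.fun, rc2.fun)


def random_tiny_instance(rng, max_cells=50):
    """A non-degenerate hurdle instance with <=50 cells and <=3 covariates."""
    import pandas as pd
    n = int(rng.integers(25, max_cells + 1))
    while True:
        X = pd.DataFrame({
            "Intercept": np.ones(n),
            "x1": rng.normal(size=n),
            "x2": (rng.random(n) < 0.5).astype(float),
        })
        eta = -0.2 + 0.8 * X["x1"] - 0.5 * X["x2"]
        z = rng.random(n) < expit(eta)
        y = np.where(z, np.abs(1.0 + 0.5 * X["x1"] + rng.normal(0, 0.7, n)) + 0.05, 0.0)
        n_det = int((y > 0).sum())
        if 5 <= n_det <= n - 5:
            return y, X
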