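"""Independent test oracles, kept separate from the implementation paths.

``ghq_ml`` maximises the *marginal* likelihood of the random-intercept
logistic model, integrating the stratum effect out of each stratum's
likelihood with adaptive Gauss-Hermite quadrature (nodes recentred at the
per-stratum mode and rescaled by the curvature there).  It shares no code
with the HMC sampler: the model only donates its aggregated count data.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit


def marginal_nll(theta: np.ndarray, gy, gn, gj, gX, n_strata: int, nodes, weights) -> float:
    """Negative marginal log likelihood at (beta0, beta, log sigma)."""
    b0, beta, lsig = theta[0], theta[1:-1], theta[-1]
    sig = np.exp(lsig)
    eta0 = b0 + gX @ beta
    total = 0.0
    for j in range(n_strata):
        sel = gj == j
        y, nn, e0 = gy[sel], gn[sel], eta0[sel]
        u = 0.0
        for _ in range(100):  # Newton for the integrand mode
            p = expit(e0 + u)
            g = np.sum(y - nn * p) - u / sig**2
            h = -np.sum(nn * p * (1.0 - p)) - 1.0 / sig**2
            step = g / h
            u -= step
            if abs(step) < 1e-12:
                break
        pm = expit(e0 + u)
        curv = np.sum(nn * pm * (1.0 - pm)) + 1.0 / sig**2
        s = 1.0 / np.sqrt(curv)
        uu = u + np.sqrt(2.0) * s * nodes
        eta = e0[None, :] + uu[:, None]
        logf = (y * eta - nn * np.logaddexp(0.0, eta)).sum(axis=1) - uu**2 / (2.0 * sig**2)
        c = logf.max()
        integral = np.sqrt(2.0) * s * np.sum(weights * np.exp(nodes**2 + logf - c))
        total += c + np.log(integral) - 0.5 * np.log(2.0 * np.pi * sig**2)
    return -total


def ghq_ml(model, n_nodes: int = 40):
    """Maximum-likelihood estimates (beta0, beta..., log sigma) via adaptive GHQ."""
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    args = (model._gy, model._gn, model._gj, model._gX, model.n_strata, nodes, weights)
    p = len(model.fixed_effect_names)
    theta0 = np.zeros(p + 2)
    theta0[-1] = np.log(0.3)
    res = minimize(marginal_nll, theta0, args=args, method="BFGS")
    assert res.success or np.linalg.norm(res.jac) < 1e-3, res.message
    return res.x


def sorted_quantiles(draws: np.ndarray, probs) -> list[float]:
    """Brute-force empirical quantiles by full sort and linear interpolation."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    out = []
    for q in probs:
        h = (n - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        out.append(float(x[lo] + (h - lo) * (x[hi] - x[lo])))
    return out
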