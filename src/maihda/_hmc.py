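"""Hamiltonian Monte Carlo with dual-averaging and diagonal mass adaptation.

Generic sampler used by the hierarchical model.  The target supplies a joint
log-density and its gradient; the sampler runs one chain at a time with:

* leapfrog integration, trajectory length jittered uniformly in
  ``[1, max_leapfrog]`` steps to decorrelate;
* Nesterov dual averaging of the step size during warmup, targeting a mean
  acceptance probability (default 0.8);
* a diagonal mass matrix estimated from the middle warmup window, after
  which step-size adaptation restarts;
* divergence guard: non-finite or exploding Hamiltonian errors reject.

Warmup draws are discarded by the caller (they are the model's burn-in).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["HmcChainResult", "sample_chain"]

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class HmcChainResult:
    draws: np.ndarray  # (n_retained, dim)
    accept_rate: float
    step_size: float
    n_divergent: int  # post-warmup only; warmup divergences are adaptation noise


def _find_initial_step(logp_grad: LogpGrad, x: np.ndarray, inv_mass: np.ndarray,
                       rng: np.random.Generator) -> float:
    """Heuristic: double/halve eps until one-step acceptance crosses 0.5."""
    eps = 0.1
    lp, grad = logp_grad(x)
    p = rng.standard_normal(x.size) / np.sqrt(inv_mass)
    h0 = -lp + 0.5 * np.sum(inv_mass * p * p)

    def one_step(eps: float) -> float:
        p1 = p + 0.5 * eps * grad
        x1 = x + eps * inv_mass * p1
        lp1, g1 = logp_grad(x1)
        p1 = p1 + 0.5 * eps * g1
        h1 = -lp1 + 0.5 * np.sum(inv_mass * p1 * p1)
        return h0 - h1  # log acceptance ratio

    d = one_step(eps)
    if not np.isfinite(d):
        d = -np.inf
    direction = 1 if d > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        d = one_step(eps)
        if not np.isfinite(d):
            d = -np.inf
        if (direction == 1 and d <= np.log(0.5)) or (
            direction == -1 and d >= np.log(0.5)
        ):
            break
    return eps


def sample_chain(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_iterations: int,
    burn_in: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_leapfrog: int = 48,
) -> HmcChainResult:
    """Run one HMC chain; returns the ``n_iterations - burn_in`` retained draws."""
    if burn_in >= n_iterations:
        raise ValueError("burn_in must be < n_iterations")
    dim = x0.size
    x = x0.astype(float).copy()
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")

    inv_mass = np.ones(dim)
    # warmup windows: [0, w1) eps only; [w1, w2) collect for mass; [w2, burn_in) re-adapt
    w1 = max(int(0.15 * burn_in), 10)
    w2 = max(int(0.75 * burn_in), w1 + 10)
    w1, w2 = min(w1, burn_in), min(w2, burn_in)
    window: list[np.ndarray] = []

    eps = _find_initial_step(logp_grad, x, inv_mass, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar, adapt_count = 0.0, 0.0, 0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    retained = np.empty((n_iterations - burn_in, dim))
    n_accept = 0
    n_div = 0
    n_post = 0

    for it in range(n_iterations):
        warming = it < burn_in
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = -lp + 0.5 * np.sum(inv_mass * p0 * p0)
        n_leap = int(rng.integers(1, max_leapfrog + 1))

        xq, pq, gq = x, p0, grad
        diverged = False
        pq = pq + 0.5 * eps * gq
        for step in range(n_leap):
            xq = xq + eps * inv_mass * pq
            lpq, gq = logp_grad(xq)
            if not np.isfinite(lpq):
                diverged = True
                break
            pq = pq + (eps if step < n_leap - 1 else 0.5 * eps) * gq
        if diverged:
            accept_prob = 0.0
        else:
            h1 = -lpq + 0.5 * np.sum(inv_mass * pq * pq)
            d_h = h0 - h1
            if not np.isfinite(d_h) or d_h < -1000.0:
                diverged = True
                accept_prob = 0.0
            else:
                accept_prob = min(1.0, np.exp(min(d_h, 0.0)))
                if np.log(rng.random()) < d_h:
                    x, lp, grad = xq, lpq, gq
                    if not warming:
                        n_accept += 1
        if diverged and not warming:
            n_div += 1

        if warming:
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - accept_prob)
            log_eps = mu - np.sqrt(adapt_count) / gamma * h_bar
            eta = adapt_count**-kappa
            log_eps_bar = eta * log_eps + (1.0 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            if w1 <= it < w2:
                window.append(x.copy())
            if it == w2 - 1 and len(window) >= 10:
                var = np.var(np.asarray(window), axis=0)
                var = np.where(var > 1e-10, var, 1e-10)
                # regularise towards unit, as a short window is noisy
                n_w = len(window)
                inv_mass = (n_w / (n_w + 5.0)) * var + (5.0 / (n_w + 5.0)) * 1.0
                eps = _find_initial_step(logp_grad, x, inv_mass, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_count = 0.0, 0.0, 0
            if it == burn_in - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            retained[n_post] = x
            n_post += 1

    return HmcChainResult(
        draws=retained,
        accept_rate=n_accept / max(n_iterations - burn_in, 1),
        step_size=eps,
        n_divergent=n_div,
    )
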