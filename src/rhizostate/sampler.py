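"""Gradient-based MCMC: Hamiltonian Monte Carlo with warmup adaptation.

A single-threaded HMC implementation in the style of Stan's static variant:
leapfrog integration with a jittered number of steps, dual-averaging step-size
adaptation toward a target acceptance rate, and windowed estimation of a
diagonal mass matrix during warmup. Inadmissible states (log density -inf)
and numerically exploding trajectories count as divergences and are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["HMCOptions", "HMCChainResult", "run_hmc_chain"]

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class HMCOptions:
    """Tuning knobs for one HMC chain."""

    n_iter: int = 2000  # total iterations, including warmup
    n_warmup: int = 1000
    target_accept: float = 0.8
    leapfrog_range: tuple[int, int] = (8, 32)  # L drawn uniformly per iter
    init_stepsize: float = 0.1
    max_divergent_energy: float = 500.0
    thin: int = 1  # keep every `thin`-th post-warmup draw

    def __post_init__(self):
        if self.n_warmup >= self.n_iter:
            raise ValueError("warmup must be smaller than total iterations")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept in (0, 1)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class HMCChainResult:
    draws: np.ndarray  # (n_kept, dim)
    accept_rate: float
    n_divergent: int
    stepsize: float
    inv_mass: np.ndarray


class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman & Gelman 2014)."""

    def __init__(self, mu: float, target: float, gamma: float = 0.05,
                 t0: float = 10.0, kappa: float = 0.75):
        self.mu, self.target = mu, target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.count = 0
        self.h_bar = 0.0
        self.log_eps_bar = 0.0

    def update(self, accept_prob: float) -> float:
        self.count += 1
        eta = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_prob)
        log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        w = self.count ** -self.kappa
        self.log_eps_bar = w * log_eps + (1 - w) * self.log_eps_bar
        return float(np.exp(log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


def _find_initial_stepsize(logp_grad: LogpGrad, x: np.ndarray,
                           inv_mass: np.ndarray, eps0: float,
                           rng: np.random.Generator) -> float:
    """Double/halve eps until one leapfrog step has acceptance near 0.5."""
    lp, g = logp_grad(x)
    eps = eps0
    r = rng.standard_normal(len(x)) / np.sqrt(inv_mass)
    h0 = lp - 0.5 * float(r * inv_mass @ r)

    def one_step(eps):
        r1 = r + 0.5 * eps * g
        x1 = x + eps * inv_mass * r1
        lp1, g1 = logp_grad(x1)
        if not np.isfinite(lp1):
            return -np.inf
        r1 = r1 + 0.5 * eps * g1
        return lp1 - 0.5 * float(r1 * inv_mass @ r1)

    h1 = one_step(eps)
    direction = 1 if (h1 - h0) > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0 ** direction
        h1 = one_step(eps)
        if direction == 1 and (h1 - h0) <= np.log(0.5):
            break
        if direction == -1 and (h1 - h0) > np.log(0.5):
            break
        if eps < 1e-10 or eps > 1e3:
            break
    return float(eps)


def run_hmc_chain(logp_grad: LogpGrad, x0: np.ndarray, options: HMCOptions,
                  rng: np.random.Generator) -> HMCChainResult:
    """Run one HMC chain; returns post-warmup draws thinned by options.thin."""
    opt = options
    x = np.asarray(x0, dtype=float).copy()
    dim = len(x)
    inv_mass = np.ones(dim)
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("initial position has zero posterior density")

    eps = _find_initial_stepsize(logp_grad, x, inv_mass, opt.init_stepsize, rng)
    da = _DualAveraging(mu=np.log(10.0 * eps), target=opt.target_accept)

    # mass-matrix adaptation windows within warmup (fractions of warmup)
    w = opt.n_warmup
    win_edges = [int(0.15 * w), int(0.45 * w), int(0.9 * w)] if w >= 40 else []
    win_samples: list[np.ndarray] = []

    kept = []
    n_acc = 0.0
    n_div = 0
    lo, hi = opt.leapfrog_range
    for it in range(opt.n_iter):
        in_warmup = it < opt.n_warmup
        r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * float(r0 * inv_mass @ r0)
        L = int(rng.integers(lo, hi + 1))
        x_new, g_new, lp_new, r = x, grad, lp, r0.copy()
        diverged = False
        r = r + 0.5 * eps * g_new
        for step in range(L):
            x_new = x_new + eps * inv_mass * r
            lp_new, g_new = logp_grad(x_new)
            if not np.isfinite(lp_new):
                diverged = True
                break
            r = r + (eps if step < L - 1 else 0.5 * eps) * g_new
        if diverged:
            accept_prob = 0.0
        else:
            h1 = lp_new - 0.5 * float(r * inv_mass @ r)
            dh = h1 - h0
            if not np.isfinite(dh) or -dh > opt.max_divergent_energy:
                diverged = True
                accept_prob = 0.0
            else:
                accept_prob = float(min(1.0, np.exp(min(dh, 0.0))))
        if diverged:
            n_div += 1
        if not diverged and rng.random() < accept_prob:
            x, lp, grad = x_new, lp_new, g_new
            n_acc += 1

        if in_warmup:
            eps = da.update(accept_prob)
            if win_edges and win_edges[0] <= it < win_edges[-1]:
                win_samples.append(x.copy())
            if win_edges and (it + 1) in win_edges[1:]:
                arr = np.asarray(win_samples)
                if len(arr) > 10:
                    var = arr.var(axis=0, ddof=1)
                    # regularize toward unit scale (Stan-style shrinkage)
                    n = len(arr)
                    inv_mass = (n / (n + 5.0)) * var \
                        + (5.0 / (n + 5.0)) * 1e-3
                    inv_mass = np.maximum(inv_mass, 1e-10)
                    eps = _find_initial_stepsize(logp_grad, x, inv_mass,
                                                 da.adapted, rng)
                    da = _DualAveraging(mu=np.log(10.0 * eps),
                                        target=opt.target_accept)
                win_samples = []
            if it == opt.n_warmup - 1:
                eps = da.adapted
        else:
            k = it - opt.n_warmup
            if k % opt.thin == 0:
                kept.append(x.copy())

    return HMCChainResult(
        draws=np.asarray(kept),
        accept_rate=n_acc / opt.n_iter,
        n_divergent=n_div,
        stepsize=float(eps),
        inv_mass=inv_mass,
    )
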