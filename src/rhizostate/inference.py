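"""Posterior sampling, convergence diagnostics, WAIC, and the stmin scan.

The threshold ``stmin`` is not sampled: the step discontinuity it induces is
hostile to gradient-based MCMC, so it is profiled on a grid and selected by
the widely applicable information criterion (WAIC), each grid value getting a
full posterior fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._posterior import UnconstrainedPosterior
from .core import EnvForcingSeries, PriorConfig, ProductionObservations
from .sampler import HMCOptions, run_hmc_chain

__all__ = ["MCMCConfig", "PosteriorDraws", "WaicResult", "fit_state_space",
           "compute_rhat", "compute_waic", "grid_search_stmin",
           "summarize_posterior"]


@dataclass
class MCMCConfig:
    """MCMC settings. Defaults reproduce the reference sampling protocol:
    4 chains x 30,000 iterations with 10,000 warmup, post-warmup draws
    thinned to 20%, for 16,000 retained draws."""

    chains: int = 4
    iterations: int = 30_000  # per chain, including warmup
    warmup: int = 10_000
    thin_keep_fraction: float = 0.2
    seed: int = 0
    rhat_threshold: float = 1.1
    target_accept: float = 0.8
    leapfrog_range: tuple[int, int] = (8, 32)

    def __post_init__(self):
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be below total iterations")
        if not 0 < self.thin_keep_fraction <= 1:
            raise ValueError("thin_keep_fraction must be in (0, 1]")
        thin = round(1.0 / self.thin_keep_fraction)
        if abs(thin - 1.0 / self.thin_keep_fraction) > 1e-9:
            raise ValueError("thin_keep_fraction must be 1/k for integer k")

    @property
    def thin(self) -> int:
        """Thinning stride: keep every k-th post-warmup draw."""
        return round(1.0 / self.thin_keep_fraction)

    @property
    def n_retained(self) -> int:
        per_chain = -(-(self.iterations - self.warmup) // self.thin)
        return self.chains * per_chain


@dataclass
class PosteriorDraws:
    """Thinned, merged posterior draws in the unconstrained space.

    ``draws`` stacks chains in order; ``chain_sizes`` records the per-chain
    draw counts so split diagnostics can recover the partition.
    ``pointwise_loglik`` holds the per-draw, per-(t, s, c) observation log
    density used by WAIC.
    """

    draws: np.ndarray  # (n_draws, dim), unconstrained
    chain_sizes: list[int]
    param_names: list[str]
    posterior: UnconstrainedPosterior
    pointwise_loglik: np.ndarray  # (n_draws, n_obs)
    stmin: float
    rhat: pd.Series  # per unconstrained coordinate
    n_divergent: int
    accept_rates: list[float]
    seed: int

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    def by_chain(self) -> list[np.ndarray]:
        out, i = [], 0
        for n in self.chain_sizes:
            out.append(self.draws[i:i + n])
            i += n
        return out

    def constrained(self, keys: tuple[str, ...] = ("gamma", "beta_base",
                                                   "b1", "sigma_le",
                                                   "sigma_st", "sigma_sm")
                    ) -> dict[str, np.ndarray]:
        """Natural-scale scalar draws."""
        out = {k: np.empty(self.n_draws) for k in keys}
        for i, d in enumerate(self.draws):
            u = self.posterior.unpack(d)
            for k in keys:
                out[k][i] = u[k]
        return out

    def paths(self, keys: tuple[str, ...] = ("le", "beta_st", "beta_sm",
                                             "b", "p")
              ) -> dict[str, np.ndarray]:
        """Natural-scale path draws, each (n_draws, T)."""
        T = self.posterior.layout.T
        out = {k: np.empty((self.n_draws, T)) for k in keys}
        for i, d in enumerate(self.draws):
            u = self.posterior.unpack(d)
            for k in keys:
                out[k][i] = u[k]
        return out

    def flagged_parameters(self, threshold: float = 1.1) -> list[str]:
        bad = self.rhat[self.rhat > threshold]
        return list(bad.index)


@dataclass
class WaicResult:
    lppd: float
    p_waic: float
    waic: float
    pointwise_lppd: np.ndarray
    pointwise_p: np.ndarray

    def __post_init__(self):
        assert np.isclose(self.waic, -2 * (self.lppd - self.p_waic))


def compute_rhat(chains: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Split potential-scale-reduction statistic per parameter.

    ``chains`` is (n_chains, n_draws, n_params) or a list of equal-length
    (n_draws, n_params) arrays. Each chain is split in half, so diagnostics
    see 2m sequences. Degenerate (zero-variance) parameters get NaN rather
    than raising; disjoint constant chains give a large value via the
    between-chain term.
    """
    if isinstance(chains, (list, tuple)):
        n = min(len(c) for c in chains)
        chains = np.stack([np.asarray(c)[:n] for c in chains])
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        chains = chains[:, :, None]
    m, n = chains.shape[0], chains.shape[1]
    if m < 2:
        raise ValueError("split-Rhat needs at least 2 chains")
    if n < 4:
        raise ValueError("split-Rhat needs at least 4 draws per chain")
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, half:2 * half]],
                           axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        W = split.var(axis=1, ddof=1).mean(axis=0)
        B = split.mean(axis=1).var(axis=0, ddof=1) * half
        var_plus = (half - 1) / half * W + B / half
        rhat = np.sqrt(var_plus / W)
    out = np.where(W > 0, rhat, np.where(B > 0, np.inf, np.nan))
    return out if out.ndim else float(out)


def compute_waic(pointwise_loglik: np.ndarray) -> WaicResult:
    """WAIC from an (n_draws, n_obs) pointwise log-likelihood table.

    lppd uses log-sum-exp stabilization; the effective-parameter term is the
    per-observation posterior variance of the log density with the n-1
    denominator; waic = -2 (lppd - p_waic).
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need an (n_draws >= 2, n_obs) table")
    if np.any(np.all(np.isneginf(ll), axis=0)):
        raise ValueError("an observation is impossible under every draw")
    if not np.all(np.isfinite(ll[np.isfinite(ll)])):
        raise ValueError("non-finite log-likelihood values")
    n_draws = ll.shape[0]
    pointwise_lppd = logsumexp(ll, axis=0) - np.log(n_draws)
    pointwise_p = ll.var(axis=0, ddof=1)
    lppd = float(pointwise_lppd.sum())
    p_waic = float(pointwise_p.sum())
    return WaicResult(lppd=lppd, p_waic=p_waic,
                      waic=-2.0 * (lppd - p_waic),
                      pointwise_lppd=pointwise_lppd, pointwise_p=pointwise_p)


def fit_state_space(obs: ProductionObservations, forcing: EnvForcingSeries,
                    stmin: float, priors: PriorConfig | None = None,
                    mcmc: MCMCConfig | None = None,
                    shared_lambda_s: bool = False) -> PosteriorDraws:
    """Sample the posterior at a fixed stmin with HMC.

    Runs ``mcmc.chains`` independent chains (seeded from ``mcmc.seed``),
    thins post-warmup draws to ``thin_keep_fraction``, merges them, computes
    split-Rhat per unconstrained coordinate and the pointwise observation
    log-likelihood per retained draw.
    """
    priors = priors or PriorConfig()
    mcmc = mcmc or MCMCConfig()
    post = UnconstrainedPosterior(obs, forcing, stmin=stmin, priors=priors,
                                  shared_lambda_s=shared_lambda_s)
    opt = HMCOptions(n_iter=mcmc.iterations, n_warmup=mcmc.warmup,
                     thin=mcmc.thin, target_accept=mcmc.target_accept,
                     leapfrog_range=mcmc.leapfrog_range)
    chains, accept, ndiv = [], [], 0
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for c in range(mcmc.chains):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(mcmc.seed) % (2**31), 1000 + c]))
            x0 = post.initial_position(rng)
            res = run_hmc_chain(post.logp_grad, x0, opt, rng)
            chains.append(res.draws)
            accept.append(res.accept_rate)
            ndiv += res.n_divergent
    draws = np.vstack(chains)
    names = post.layout.names()
    rhat_vals = compute_rhat(chains)
    rhat = pd.Series(rhat_vals, index=names)
    n_flag = int((rhat > mcmc.rhat_threshold).sum())
    if n_flag:
        warnings.warn(
            f"{n_flag} parameters have split-Rhat > {mcmc.rhat_threshold}",
            stacklevel=2)
    pll = np.empty((len(draws), obs.n_obs))
    for i, d in enumerate(draws):
        pll[i] = post.pointwise_loglik(d)
    return PosteriorDraws(draws=draws, chain_sizes=[len(c) for c in chains],
                          param_names=names, posterior=post,
                          pointwise_loglik=pll, stmin=stmin, rhat=rhat,
                          n_divergent=ndiv, accept_rates=accept,
                          seed=mcmc.seed)


def grid_search_stmin(obs: ProductionObservations, forcing: EnvForcingSeries,
                      grid_lo: float = 0.0, grid_hi: float = 10.0,
                      step: float = 0.1, priors: PriorConfig | None = None,
                      mcmc: MCMCConfig | None = None,
                      keep_fits: bool = False,
                      shared_lambda_s: bool = False
                      ) -> tuple[float, pd.DataFrame, dict]:
    """Profile stmin on a grid, fitting the model at each value.

    Returns ``(stmin_best, profile, fits)`` where ``profile`` has columns
    (stmin, lppd, p_waic, waic, converged, error). The argmin is over
    converged-and-successful points, ties broken toward the lower stmin.
    Per-point failures are flagged and the scan continues.
    """
    if not grid_lo < grid_hi:
        raise ValueError("grid_lo must be below grid_hi")
    if step <= 0:
        raise ValueError("step must be positive")
    mcmc = mcmc or MCMCConfig()
    n_pts = int(round((grid_hi - grid_lo) / step)) + 1
    grid = grid_lo + step * np.arange(n_pts)
    rows, fits = [], {}
    for g in grid:
        row = {"stmin": float(g), "lppd": np.nan, "p_waic": np.nan,
               "waic": np.nan, "converged": False, "error": ""}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_state_space(obs, forcing, stmin=float(g),
                                      priors=priors, mcmc=mcmc,
                                      shared_lambda_s=shared_lambda_s)
            w = compute_waic(fit.pointwise_loglik)
            row.update(lppd=w.lppd, p_waic=w.p_waic, waic=w.waic,
                       converged=len(fit.flagged_parameters(
                           mcmc.rhat_threshold)) == 0)
            if keep_fits:
                fits[float(g)] = fit
        except Exception as exc:  # keep scanning; flag the point
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    profile = pd.DataFrame(rows)
    ok = profile[profile["error"] == ""].dropna(subset=["waic"])
    if ok.empty:
        raise RuntimeError("every grid point failed")
    # ties toward the lower stmin: stable argmin on the sorted grid
    best = float(ok.loc[ok["waic"].idxmin(), "stmin"])
    return best, profile, fits


def summarize_posterior(fit: PosteriorDraws,
                        quantiles: tuple[float, ...] = (0.025, 0.25, 0.5,
                                                        0.75, 0.975)
                        ) -> pd.DataFrame:
    """Quantile summary for scalars and every path element."""
    rows = []
    scal = fit.constrained()
    for name, v in scal.items():
        rows.append({"param": name,
                     **{f"q{100 * q:g}": float(np.quantile(v, q))
                        for q in quantiles},
                     "rhat": _natural_rhat(fit, name)})
    paths = fit.paths()
    for name, mat in paths.items():
        for t in range(mat.shape[1]):
            rows.append({"param": f"{name}[{t}]",
                         **{f"q{100 * q:g}": float(np.quantile(mat[:, t], q))
                            for q in quantiles},
                         "rhat": np.nan})
    return pd.DataFrame(rows)


def _natural_rhat(fit: PosteriorDraws, name: str) -> float:
    try:
        j = fit.param_names.index(name)
    except ValueError:
        return float("nan")
    return float(fit.rhat.iloc[j])
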