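"""Model/Results interface over the fine-root production state-space model.

Follows the fit-object convention of statistical modelling packages: a
:class:`FineRootModel` is constructed from data, ``fit()`` samples the
posterior and returns a :class:`FineRootResults` carrying draws,
uncertainties, diagnostics and ``summary()``; derived-effect computation,
the stmin scan and plotting hang off these two objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import effects as _effects
from .core import EnvForcingSeries, PriorConfig, ProductionObservations
from .inference import (
    MCMCConfig,
    PosteriorDraws,
    WaicResult,
    compute_waic,
    fit_state_space,
    grid_search_stmin,
    summarize_posterior,
)
from .preprocess import (
    ModelData,
    aggregate_to_dekads,
    align_dataset,
    assign_production_to_dekads,
    exclude_disturbance_window,
)

__all__ = ["FineRootModel", "FineRootResults", "StminScanResults"]


class FineRootModel:
    """Bayesian state-space model of fine root production.

    Parameters
    ----------
    obs : ProductionObservations
        Production per (period, scanner, image), mm^2 cm^-2 day^-1.
    forcing : EnvForcingSeries
        Dekadal soil temperature (deg C) and moisture (%) with interval
        lengths (days).
    priors : PriorConfig, optional
        If omitted, weakly informative defaults are used with the
        standing-area prior mean taken from ``b1_reference`` (or 1.0).
    """

    def __init__(self, obs: ProductionObservations,
                 forcing: EnvForcingSeries,
                 priors: PriorConfig | None = None,
                 b1_reference: float | None = None,
                 shared_lambda_s: bool = False):
        if priors is None:
            priors = PriorConfig(
                b1_mean=float(b1_reference) if b1_reference else 1.0)
        self.obs = obs
        self.forcing = forcing
        self.priors = priors
        self.shared_lambda_s = shared_lambda_s

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_model_data(cls, data: ModelData, **kw) -> "FineRootModel":
        return cls(data.obs, data.forcing, **kw)

    @classmethod
    def from_csv(cls, forcing_csv, production_csv,
                 exclusion_days_by_stand: dict[str, int] | None = None,
                 **kw) -> "FineRootModel":
        """Build from the raw daily-forcing and scan-production CSVs.

        Applies the full preprocessing chain: disturbance-window exclusion,
        dekadal aggregation of the forcing, interval-overlap attribution of
        scan rates to dekads, and range alignment.
        """
        daily = pd.read_csv(forcing_csv)
        raw = pd.read_csv(production_csv)
        raw = exclude_disturbance_window(raw, exclusion_days_by_stand)
        forcing = aggregate_to_dekads(daily)
        prod = assign_production_to_dekads(raw)
        data = align_dataset(forcing, prod)
        return cls.from_model_data(data, **kw)

    @classmethod
    def from_synthetic(cls, study, **kw) -> "FineRootModel":
        return cls(study.observations, study.forcing, **kw)

    # -- estimation ----------------------------------------------------------

    def fit(self, stmin: float, mcmc: MCMCConfig | None = None
            ) -> "FineRootResults":
        """Sample the posterior at a fixed temperature threshold."""
        draws = fit_state_space(self.obs, self.forcing, stmin=stmin,
                                priors=self.priors, mcmc=mcmc,
                                shared_lambda_s=self.shared_lambda_s)
        return FineRootResults(self, draws)

    def scan_stmin(self, grid_lo: float = 0.0, grid_hi: float = 10.0,
                   step: float = 0.1, mcmc: MCMCConfig | None = None,
                   refit_best: bool = True,
                   refit_mcmc: MCMCConfig | None = None
                   ) -> "StminScanResults":
        """Grid-profile the minimum-temperature threshold by WAIC.

        Each grid value gets a full posterior fit; the WAIC-minimizing value
        (ties toward the lower stmin) is optionally refitted with
        ``refit_mcmc`` for the final results object.
        """
        best, profile, _ = grid_search_stmin(
            self.obs, self.forcing, grid_lo=grid_lo, grid_hi=grid_hi,
            step=step, priors=self.priors, mcmc=mcmc,
            shared_lambda_s=self.shared_lambda_s)
        results = None
        if refit_best:
            results = self.fit(best, mcmc=refit_mcmc or mcmc)
        return StminScanResults(stmin_best=best, profile=profile,
                                results=results)


@dataclass
class StminScanResults:
    stmin_best: float
    profile: pd.DataFrame
    results: "FineRootResults | None" = None

    def save_profile(self, path) -> None:
        self.profile.to_csv(path, index=False)


class FineRootResults:
    """Posterior results: draws, diagnostics, summaries, derived effects."""

    def __init__(self, model: FineRootModel, draws: PosteriorDraws):
        self.model = model
        self.draws = draws

    # -- basic accessors -----------------------------------------------------

    @property
    def stmin(self) -> float:
        return self.draws.stmin

    @property
    def n_draws(self) -> int:
        return self.draws.n_draws

    @property
    def rhat(self) -> pd.Series:
        return self.draws.rhat

    def flagged_parameters(self, threshold: float = 1.1) -> list[str]:
        return self.draws.flagged_parameters(threshold)

    def waic(self) -> WaicResult:
        return compute_waic(self.draws.pointwise_loglik)

    def summary(self, quantiles=(0.025, 0.25, 0.5, 0.75, 0.975)
                ) -> pd.DataFrame:
        """Posterior quantile table for scalars and latent paths."""
        return summarize_posterior(self.draws, quantiles)

    # -- derived quantities --------------------------------------------------

    def effect_series(self, **kw) -> _effects.EffectSummary:
        return _effects.effect_series(self.draws, self.model.forcing, **kw)

    def regression_curves(self, **kw) -> _effects.RegressionCurveSet:
        return _effects.regression_curves(self.draws, self.model.forcing,
                                          **kw)

    def production_report(self, **kw):
        return _effects.production_report(self.draws, self.model.forcing,
                                          self.model.obs, **kw)

    def percent_change_per_sm(self, t: int, statistic: str = "median",
                              **kw) -> float:
        """Draw-wise percent production change per +1% SM at period t,
        summarized by the posterior median (default)."""
        paths = self.draws.paths(("beta_sm",))
        st = self.model.forcing.st[t]
        vals = _effects.percent_change_per_sm(paths["beta_sm"][:, t], st,
                                              self.stmin, **kw)
        return float(np.median(vals) if statistic == "median"
                     else np.mean(vals))

    # -- plots ---------------------------------------------------------------

    def plot_production(self, ax=None):
        """Median production with 50%/95% credible bands and observed means."""
        import matplotlib.pyplot as plt

        table, _ = self.production_report()
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        x = np.arange(len(table))
        ax.fill_between(x, table["q2.5"], table["q97.5"], color="0.85",
                        label="95% CrI")
        ax.fill_between(x, table["q25"], table["q75"], color="0.65",
                        label="50% CrI")
        ax.plot(x, table["q50"], "k-", lw=1.2, label="posterior median")
        ax.plot(x, table["obs_mean"], "r-", lw=0.8, label="observed mean")
        ax.set_xlabel("period (dekad index)")
        ax.set_ylabel("fine root production (mm$^2$ cm$^{-2}$ d$^{-1}$)")
        ax.legend(frameon=False, fontsize=8)
        return ax

    def plot_effects(self, ax=None):
        """Overall temperature effect and the moisture contribution."""
        import matplotlib.pyplot as plt

        es = self.effect_series()
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        x = np.arange(len(es.beta_ext))
        ax.fill_between(x, es.beta_ext["q25"], es.beta_ext["q75"],
                        color="0.75")
        ax.plot(x, es.beta_ext["q50"], "k-", lw=1.2,
                label=r"$\beta_{ext}$")
        ax.fill_between(x, es.sm_contribution["q25"],
                        es.sm_contribution["q75"], color="tab:blue",
                        alpha=0.25)
        ax.plot(x, es.sm_contribution["q50"], color="tab:blue", lw=1.2,
                label=r"$\beta_{sm} \times SM$")
        ax.axhline(0.0, color="0.5", lw=0.5)
        ax.set_xlabel("period (dekad index)")
        ax.set_ylabel("effect on log growth response")
        ax.legend(frameon=False, fontsize=8)
        return ax

    def plot_regression_curves(self, periods=None, ax=None):
        """Fan of time-varying production-vs-temperature curves."""
        import matplotlib.pyplot as plt

        rc = self.regression_curves(periods=periods)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        cmap = plt.get_cmap("viridis")
        n = len(rc.median)
        for i, curve in enumerate(rc.median):
            ax.plot(rc.st_grid, curve, color=cmap(i / max(n - 1, 1)),
                    lw=0.6, alpha=0.7)
        ax.axvline(rc.stmin, color="k", ls="--", lw=0.8,
                   label=f"stmin = {rc.stmin:.1f} degC")
        ax.set_xlabel("soil temperature (degC)")
        ax.set_ylabel("production (mm$^2$ cm$^{-2}$ d$^{-1}$)")
        ax.legend(frameon=False, fontsize=8)
        return ax

    # -- persistence ---------------------------------------------------------

    def save(self, outdir) -> None:
        """Columnar draw table + JSON manifest + pointwise log-likelihood."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(self.draws.draws, columns=self.draws.param_names)
        df.to_csv(outdir / "draws_unconstrained.csv", index=False)
        np.savetxt(outdir / "pointwise_loglik.csv",
                   self.draws.pointwise_loglik, delimiter=",")
        manifest = {
            "stmin": self.stmin,
            "seed": self.draws.seed,
            "chain_sizes": self.draws.chain_sizes,
            "n_divergent": self.draws.n_divergent,
            "accept_rates": self.draws.accept_rates,
            "T": self.model.forcing.T,
            "S": self.model.obs.S,
            "C": self.model.obs.C,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        self.summary().to_csv(outdir / "posterior_summary.csv", index=False)
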