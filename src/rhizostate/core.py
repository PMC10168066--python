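"""Deterministic mathematics of the fine-root production state-space model.

The system model tracks standing fine-root area ``b_t`` (mm^2 cm^-2, projected
root area per unit soil-profile area) through a mass balance

    b_t = b_{t-1} + p_{t-1} V_{t-1} - gamma b_{t-1} V_{t-1},

where production is ``p_t = beta_t b_t`` and the growth rate responds to soil
temperature ST (deg C) and volumetric soil moisture SM (%) through
time-varying coefficients:

    beta_t = exp(le_t + beta_ext_t * log(ST_t - stmin)) + beta_base   if ST_t > stmin
    beta_t = beta_base                                               otherwise,

with ``beta_ext_t = beta_st_t + beta_sm_t * SM_t``. The latent paths ``le_t``
(other endogenous factors, log scale), ``beta_st_t`` and ``beta_sm_t`` evolve
as Gaussian random walks. Observations are scanner images of production,
modelled with a two-level gamma hierarchy: a scanner-level latent mean
``ps_{t,s} ~ Gamma(lambda_t p_t, lambda_t)`` and image-level values
``F_{t,s,c} ~ Gamma(lambda_s_{t,s} ps_{t,s}, lambda_s_{t,s})`` (shape/rate
parameterization, so the means are ``p_t`` and ``ps_{t,s}`` exactly).

Everything here is pure and deterministic; sampling lives in
:mod:`rhizostate.inference` and data simulation in :mod:`rhizostate.synthetic`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import special, stats

__all__ = [
    "THRESHOLD_EPS",
    "EnvForcingSeries",
    "ProductionObservations",
    "ScalarParams",
    "LatentTrajectory",
    "DispersionParams",
    "PriorConfig",
    "PositivityError",
    "overall_temperature_effect",
    "exogenous_effect",
    "growth_rate",
    "mean_production",
    "propagate_biomass",
    "biomass_trajectory",
    "hier_gamma_loglik",
    "random_walk_logprior",
    "log_posterior",
]

#: Strict margin above ``stmin`` (deg C) below which the temperature response
#: is switched off; ``log(ST - stmin)`` is singular at equality.
THRESHOLD_EPS = 0.01

TERCILES = ("early", "mid", "late")


class PositivityError(ValueError):
    """Raised when a parameter combination drives standing root area <= 0."""

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class EnvForcingSeries:
    """Dekadal environmental forcing aligned to a period index.

    Periods are month terciles (early = days 1-10, mid = 11-20, late = 21-end),
    36 per calendar year.

    Parameters
    ----------
    periods : sequence of (year, month, tercile)
        Ordered period labels; tercile is one of ``"early" | "mid" | "late"``.
    st : array
        Soil temperature per period, deg C.
    sm : array
        Volumetric soil moisture per period, %.
    v : array
        Interval length per period, days.
    """

    periods: Sequence[tuple[int, int, str]]
    st: np.ndarray
    sm: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        self.st = np.asarray(self.st, dtype=float)
        self.sm = np.asarray(self.sm, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.periods = [(int(y), int(m), str(tc)) for y, m, tc in self.periods]
        self.validate()

    @property
    def T(self) -> int:
        return len(self.st)

    def validate(self) -> None:
        T = len(self.st)
        if T < 2:
            raise ValueError("forcing series needs at least 2 periods")
        if not (len(self.sm) == len(self.v) == len(self.periods) == T):
            raise ValueError("ST, SM, V and period labels must share one length")
        if np.any(self.v <= 0):
            raise ValueError("interval lengths V must be positive")
        for y, m, tc in self.periods:
            if tc not in TERCILES:
                raise ValueError(f"unknown tercile label {tc!r}")
            if not 1 <= m <= 12:
                raise ValueError(f"month out of range: {m}")
        # complete calendar years must have 36 periods summing to 365/366
        by_year: dict[int, list[int]] = {}
        for i, (y, m, tc) in enumerate(self.periods):
            by_year.setdefault(y, []).append(i)
        for y, idx in by_year.items():
            labels = [self.periods[i][1:] for i in idx]
            complete = len(labels) == 36 and len(set(labels)) == 36
            if complete:
                total = float(self.v[idx].sum())
                expected = 366.0 if _is_leap(y) else 365.0
                if abs(total - expected) > 1e-9:
                    raise ValueError(
                        f"year {y}: interval lengths sum to {total}, "
                        f"expected {expected}"
                    )

    def to_frame(self):
        import pandas as pd

        years, months, tercs = zip(*self.periods)
        return pd.DataFrame(
            {
                "year": years,
                "month": months,
                "tercile": tercs,
                "soil_temp_c": self.st,
                "soil_moist_pct": self.sm,
                "interval_days": self.v,
            }
        )


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


@dataclass
class ProductionObservations:
    """Fine-root production measurements keyed by (period, scanner, image).

    ``t`` indexes the forcing periods (0-based), ``s`` scanners (0..S-1) and
    ``c`` depth-wise images within a scanner (0..C-1). Missing combinations
    (scanner failures) are simply absent.
    """

    t: np.ndarray
    s: np.ndarray
    c: np.ndarray
    value: np.ndarray  # production F, mm^2 cm^-2 day^-1
    S: int
    C: int

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=int)
        self.s = np.asarray(self.s, dtype=int)
        self.c = np.asarray(self.c, dtype=int)
        self.value = np.asarray(self.value, dtype=float)
        self.validate()

    @property
    def n_obs(self) -> int:
        return len(self.value)

    def validate(self) -> None:
        n = len(self.value)
        if not (len(self.t) == len(self.s) == len(self.c) == n):
            raise ValueError("t, s, c, value must share one length")
        if np.any(self.value < 0):
            raise ValueError("production observations must be >= 0")
        if n:
            if self.t.min() < 0:
                raise ValueError("negative period index")
            if self.s.min() < 0 or self.s.max() >= self.S:
                raise ValueError("scanner index out of range")
            if self.c.min() < 0 or self.c.max() >= self.C:
                raise ValueError("image index out of range")
            keys = set(zip(self.t.tolist(), self.s.tolist(), self.c.tolist()))
            if len(keys) != n:
                raise ValueError("duplicate (t, s, c) observation keys")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.t, "s": self.s, "c": self.c, "production": self.value}
        )


@dataclass
class ScalarParams:
    """Scalar parameters of the system model."""

    b1: float  # initial standing root area, mm^2 cm^-2
    gamma: float  # mortality rate, day^-1
    beta_base: float  # baseline growth rate, day^-1
    stmin: float  # minimum temperature threshold, deg C
    sigma_le: float = 0.5  # random-walk sd of le
    sigma_st: float = 0.1  # random-walk sd of beta_st
    sigma_sm: float = 0.01  # random-walk sd of beta_sm

    def __post_init__(self):
        if self.b1 <= 0:
            raise ValueError("b1 must be positive")
        if self.gamma < 0 or self.beta_base < 0:
            raise ValueError("gamma and beta_base must be nonnegative")
        for name in ("sigma_le", "sigma_st", "sigma_sm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **kw) -> "ScalarParams":
        return replace(self, **kw)


@dataclass
class LatentTrajectory:
    """Full latent state: coefficient paths plus the implied (b, p)."""

    le: np.ndarray
    beta_st: np.ndarray
    beta_sm: np.ndarray
    b: np.ndarray
    p: np.ndarray
    scalars: ScalarParams

    @property
    def T(self) -> int:
        return len(self.b)

    def validate(self, forcing: EnvForcingSeries) -> None:
        if np.any(self.b <= 0):
            raise PositivityError("standing root area must stay positive")
        above = forcing.st > self.scalars.stmin + THRESHOLD_EPS
        beta = self.p / self.b
        base = self.scalars.beta_base
        if not np.allclose(beta[~above], base, rtol=0, atol=1e-12):
            raise ValueError("below-threshold growth rate must equal beta_base")
        if np.any(self.p[above] < base * self.b[above] - 1e-12):
            raise ValueError("production below the baseline floor")
        # mass-balance recursion must hold to machine precision
        gamma, v = self.scalars.gamma, forcing.v
        recon = self.b[:-1] * (1.0 + (beta[:-1] - gamma) * v[:-1])
        if not np.allclose(recon, self.b[1:], rtol=1e-12, atol=0):
            raise ValueError("mass-balance recursion violated")


@dataclass
class DispersionParams:
    """Gamma dispersion (rate) parameters and scanner-level latent means."""

    lambda_t: np.ndarray  # (T,)
    lambda_s: np.ndarray  # (T, S)
    ps: np.ndarray  # (T, S) scanner-level mean production

    def __post_init__(self):
        self.lambda_t = np.asarray(self.lambda_t, dtype=float)
        self.lambda_s = np.asarray(self.lambda_s, dtype=float)
        self.ps = np.asarray(self.ps, dtype=float)
        if np.any(self.lambda_t <= 0) or np.any(self.lambda_s <= 0):
            raise ValueError("gamma rate parameters must be positive")
        if np.any(self.ps <= 0):
            raise ValueError("scanner-level means must be positive")


@dataclass
class PriorConfig:
    """Weakly informative priors; these defaults are this package's choice.

    ``b1_mean`` should be set from the standing root area observed on the
    first image; its prior sd is ``b1_cv * b1_mean``.
    """

    gamma_scale: float = 0.05  # half-Normal scale, day^-1
    beta_base_scale: float = 0.01  # half-Normal scale, day^-1
    sigma_scale: float = 1.0  # half-Normal scale for the RW sds
    #: half-Cauchy scale for the implied gamma SHAPES (lambda_t p_t and
    #: lambda_s ps): the shape is dimensionless, so one scale works at every
    #: period regardless of the production magnitude
    lambda_scale: float = 5.0
    b1_mean: float = 1.0
    b1_cv: float = 0.5
    le1_mean: float = -5.0
    le1_sd: float = 5.0
    coef1_sd: float = 1.0  # initial prior sd for beta_st_1, beta_sm_1
    zero_rule: str = "censor"  # "censor" | "offset" for F = 0 observations


# ---------------------------------------------------------------------------
# System-model operations
# ---------------------------------------------------------------------------


def overall_temperature_effect(beta_st, beta_sm, sm):
    """Overall temperature effect beta_ext = beta_st + beta_sm * SM.

    SM enters in raw percent. Vectorized over any broadcastable shapes.
    """
    sm = np.asarray(sm, dtype=float)
    if np.any(sm < 0):
        raise ValueError("soil moisture must be >= 0")
    return np.asarray(beta_st, dtype=float) + np.asarray(beta_sm, dtype=float) * sm


def exogenous_effect(beta_ext, st, stmin, eps: float = THRESHOLD_EPS):
    """Exogenous (temperature) effect ex = beta_ext * log(ST - stmin).

    Only defined strictly above the threshold; callers route below-threshold
    periods to the baseline branch of :func:`growth_rate`.
    """
    st = np.asarray(st, dtype=float)
    if np.any(st <= stmin + eps):
        raise ValueError(
            f"exogenous effect undefined at ST <= stmin + {eps} (got min "
            f"ST - stmin = {float(np.min(st - stmin)):.4g})"
        )
    return np.asarray(beta_ext, dtype=float) * np.log(st - stmin)


def growth_rate(le, beta_st, beta_sm, sm, st, stmin, beta_base,
                eps: float = THRESHOLD_EPS):
    """Growth rate beta_t = exp(le + ex) + beta_base, with threshold switch.

    Below ``stmin + eps`` the exogenous response is zero and the rate equals
    ``beta_base``. Total function; vectorized.
    """
    st = np.asarray(st, dtype=float)
    le = np.asarray(le, dtype=float)
    above = st > stmin + eps
    beta = np.full(np.broadcast(le, st).shape, float(beta_base))
    if np.any(above):
        bext = overall_temperature_effect(beta_st, beta_sm, sm)
        bext_b = np.broadcast_to(np.asarray(bext, dtype=float), beta.shape)
        le_b = np.broadcast_to(le, beta.shape)
        diff = np.where(above, st - stmin, 1.0)
        eta = le_b + bext_b * np.log(diff)
        beta = np.where(above, np.exp(eta) + beta_base, beta)
    if beta.ndim == 0:
        return float(beta)
    return beta


def mean_production(beta, b):
    """Mean production p = beta * b (mm^2 cm^-2 day^-1)."""
    beta = np.asarray(beta, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(b <= 0):
        raise ValueError("standing root area must be positive")
    if np.any(beta < 0):
        raise ValueError("growth rate must be nonnegative")
    out = beta * b
    return float(out) if out.ndim == 0 else out


def propagate_biomass(b_prev: float, beta_prev: float, gamma: float,
                      v_prev: float) -> float:
    """One mass-balance step: b_t = b_{t-1} (1 + (beta_{t-1} - gamma) V_{t-1}).

    Algebraically identical to b + pv - mv; raises :class:`PositivityError`
    if the multiplier is nonpositive (an inadmissible parameter combination
    the sampler must reject).
    """
    if b_prev <= 0:
        raise PositivityError("b_prev must be positive")
    if v_prev <= 0:
        raise ValueError("interval length must be positive")
    mult = 1.0 + (beta_prev - gamma) * v_prev
    if mult <= 0:
        raise PositivityError(
            f"biomass multiplier {mult:.4g} <= 0 "
            f"(beta={beta_prev:.4g}, gamma={gamma:.4g}, V={v_prev:.4g})"
        )
    return b_prev * mult


def biomass_trajectory(b1: float, le_path, beta_st_path, beta_sm_path,
                       forcing: EnvForcingSeries,
                       scalars: ScalarParams) -> LatentTrajectory:
    """Deterministic (b, p) trajectory implied by coefficient paths + forcing.

    The recursion has no innovation term, so ``b`` is computed, never sampled.
    Raises :class:`PositivityError` (with the offending index) if the
    parameters drive ``b`` nonpositive.
    """
    le = np.asarray(le_path, dtype=float)
    bst = np.asarray(beta_st_path, dtype=float)
    bsm = np.asarray(beta_sm_path, dtype=float)
    T = forcing.T
    if not (len(le) == len(bst) == len(bsm) == T):
        raise ValueError("coefficient paths must match forcing length")
    if b1 <= 0:
        raise PositivityError("b1 must be positive")
    beta = growth_rate(le, bst, bsm, forcing.sm, forcing.st, scalars.stmin,
                       scalars.beta_base)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    mult = 1.0 + (beta[:-1] - scalars.gamma) * forcing.v[:-1]
    bad = np.nonzero(mult <= 0)[0]
    if bad.size:
        i = int(bad[0])
        raise PositivityError(
            f"biomass multiplier <= 0 at step {i}", index=i
        )
    b = np.empty(T)
    b[0] = b1
    b[1:] = b1 * np.cumprod(mult)
    p = beta * b
    return LatentTrajectory(le=le, beta_st=bst, beta_sm=bsm, b=b, p=p,
                            scalars=scalars.replace(b1=float(b1)))


# ---------------------------------------------------------------------------
# Observation model and priors
# ---------------------------------------------------------------------------


def _gamma_logpdf(x, shape, rate):
    return shape * np.log(rate) - special.gammaln(shape) \
        + (shape - 1.0) * np.log(x) - rate * x


def hier_gamma_loglik(obs: ProductionObservations, ps, lambda_t, lambda_s,
                      p_path, zero_rule: str = "censor",
                      zero_delta: float | None = None):
    """Log-likelihood of the two-level gamma observation model.

    Returns ``(pointwise, scanner_level)`` where ``pointwise`` is an array of
    per-observation log densities (aligned with ``obs`` records) of
    ``F ~ Gamma(lambda_s ps, lambda_s)`` and ``scanner_level`` is the (T, S)
    array of log densities of ``ps ~ Gamma(lambda_t p_t, lambda_t)``.

    ``F = 0`` lies outside gamma support; under the default ``censor`` rule a
    zero is treated as left-censored at ``zero_delta`` (half the smallest
    positive F if not given) and contributes the gamma CDF there; under
    ``offset`` the value ``F + zero_delta`` is scored instead.
    """
    ps = np.asarray(ps, dtype=float)
    lambda_t = np.asarray(lambda_t, dtype=float)
    lambda_s = np.asarray(lambda_s, dtype=float)
    p_path = np.asarray(p_path, dtype=float)
    if np.any(lambda_t <= 0) or np.any(lambda_s <= 0) or np.any(ps <= 0):
        raise ValueError("gamma parameters must be strictly positive")
    alpha_t = lambda_t[:, None] * p_path[:, None]
    if np.any(alpha_t <= 0):
        raise ValueError("scanner-level gamma shape must be positive")
    scanner_level = _gamma_logpdf(ps, alpha_t, lambda_t[:, None])

    F = obs.value
    shp = lambda_s[obs.t, obs.s] * ps[obs.t, obs.s]
    rate = lambda_s[obs.t, obs.s]
    pointwise = np.empty(obs.n_obs)
    pos = F > 0
    pointwise[pos] = _gamma_logpdf(F[pos], shp[pos], rate[pos])
    if np.any(~pos):
        if zero_delta is None:
            if not np.any(pos):
                raise ValueError("cannot infer zero_delta: no positive F")
            zero_delta = 0.5 * float(F[pos].min())
        if zero_rule == "censor":
            # left-censored: log P(F <= delta) via regularized lower gamma
            from ._posterior import log_gammainc_lower

            pointwise[~pos] = log_gammainc_lower(
                shp[~pos], rate[~pos] * zero_delta)
        elif zero_rule == "offset":
            pointwise[~pos] = _gamma_logpdf(zero_delta, shp[~pos], rate[~pos])
        else:
            raise ValueError(f"unknown zero rule {zero_rule!r}")
    return pointwise, scanner_level


def random_walk_logprior(path, sigma: float,
                         init_mean: float | None = 0.0,
                         init_sd: float | None = None) -> float:
    """Gaussian random-walk log prior: sum of step densities plus init term.

    ``init_sd=None`` means a flat (improper) initialization prior, which
    contributes zero.
    """
    path = np.asarray(path, dtype=float)
    if len(path) < 2:
        raise ValueError("path must have length >= 2")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    steps = np.diff(path)
    lp = float(np.sum(stats.norm.logpdf(steps, 0.0, sigma)))
    if init_sd is not None:
        lp += float(stats.norm.logpdf(path[0], init_mean, init_sd))
    return lp


def _half_normal_logpdf(x, scale):
    return 0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (x / scale) ** 2


def _half_cauchy_logpdf(x, scale):
    return np.log(2.0 / np.pi) - np.log(scale) - np.log1p((x / scale) ** 2)


def log_posterior(traj: LatentTrajectory, disp: DispersionParams,
                  obs: ProductionObservations, forcing: EnvForcingSeries,
                  priors: PriorConfig):
    """Joint log posterior density and the pointwise observation table.

    The trajectory's (b, p) are recomputed from its paths and scalars, so an
    inadmissible combination returns ``-inf``. Returns ``(logp, pointwise)``
    with ``pointwise`` the per-(t, s, c) observation log-likelihood needed
    for WAIC.
    """
    sc = traj.scalars
    try:
        recomputed = biomass_trajectory(sc.b1, traj.le, traj.beta_st,
                                        traj.beta_sm, forcing, sc)
    except PositivityError:
        return -np.inf, None
    pointwise, scanner_level = hier_gamma_loglik(
        obs, disp.ps, disp.lambda_t, disp.lambda_s, recomputed.p,
        zero_rule=priors.zero_rule,
    )
    lp = float(pointwise.sum() + scanner_level.sum())
    lp += random_walk_logprior(traj.le, sc.sigma_le, priors.le1_mean,
                               priors.le1_sd)
    lp += random_walk_logprior(traj.beta_st, sc.sigma_st, 0.0, priors.coef1_sd)
    lp += random_walk_logprior(traj.beta_sm, sc.sigma_sm, 0.0, priors.coef1_sd)
    lp += float(_half_normal_logpdf(sc.gamma, priors.gamma_scale))
    lp += float(_half_normal_logpdf(sc.beta_base, priors.beta_base_scale))
    for s in (sc.sigma_le, sc.sigma_st, sc.sigma_sm):
        lp += float(_half_normal_logpdf(s, priors.sigma_scale))
    # dispersion priors act on the implied shapes (rate x mean); the change
    # of variable back to the rate contributes the log-mean Jacobian
    lp += float(np.sum(
        _half_cauchy_logpdf(disp.lambda_t * recomputed.p,
                            priors.lambda_scale)
        + np.log(recomputed.p)))
    lp += float(np.sum(
        _half_cauchy_logpdf(disp.lambda_s * disp.ps, priors.lambda_scale)
        + np.log(disp.ps)))
    b1_sd = priors.b1_cv * priors.b1_mean
    lp += float(stats.norm.logpdf(sc.b1, priors.b1_mean, b1_sd))
    return lp, pointwise
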