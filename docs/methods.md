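# Methods

## Model

The package fits a state-space model of fine root production observed by
repeated soil-profile imaging. The system model is a deterministic mass
balance for standing root area `b_t` (mm² cm⁻²) over dekadal periods
(36 per year, interval lengths `V_t` of 8–11 days):

    b_t = b_{t-1} (1 + (β_{t-1} − γ) V_{t-1}),    p_t = β_t b_t.

The recursion carries no innovation term, so `b` is computed, never
sampled; parameter combinations that drive the multiplier nonpositive are
rejected with zero posterior density rather than clamped, which keeps the
mass balance exact. The growth rate switches at a minimum temperature
`stmin`:

    β_t = exp(le_t + (βst_t + βsm_t SM_t) · log(ST_t − stmin)) + βbase
          for ST_t > stmin + ε,     β_t = βbase otherwise,

with ε = 0.01 °C: the paper-style condition `ST ≥ stmin` leaves
`log(ST − stmin)` singular at equality, and a 0.01 °C guard is invisible at
the 0.1 °C grid resolution. `le_t` (endogenous factors, log scale) and the
coefficients `βst_t`, `βsm_t` evolve as Gaussian random walks; moisture
enters in raw percent and only through the interaction term.

Observation errors are a two-level gamma hierarchy, scanner means
`ps_{t,s} ~ Gamma(λ_t p_t, λ_t)` and image values
`F_{t,s,c} ~ Gamma(λs ps, λs)` (shape/rate; both levels mean-preserving).
The image-level rate is free per (period, scanner) by default, matching the
model's indexing; with few images per scanner (C ≈ 4) those rates are
essentially unidentified, so a `shared_lambda_s` option pools them per
period, and the recovery studies use it. Observed zeros lie outside gamma
support and are treated as left-censored at δ = half the smallest positive
value in the dataset (gamma CDF term; an additive-offset alternative is
configurable). A numerically safe log-CDF (leading series term for tiny
arguments) keeps censored terms finite at extreme shapes.

## Priors

The reference publication's prior table is not available, so the defaults
are this package's choice, weakly informative and configurable
(`PriorConfig`):

| parameter | prior | rationale |
|---|---|---|
| γ | half-Normal(0, 0.05) day⁻¹ | mortality a few ‰/day at most |
| βbase | half-Normal(0, 0.01) day⁻¹ | baseline well below peak growth |
| σ_le, σ_st, σ_sm | half-Normal(0, 1) | per-step walk scales |
| λ_t p_t, λs ps | half-Cauchy(0, 5) | see below |
| b₁ | Normal(reference area, 50%), truncated > 0 | anchored to the first image |
| le₁ | Normal(−5, 5²) | growth rates span decades |
| βst₁, βsm₁ | Normal(0, 1) | order-one effects |

The dispersion priors act on the *implied gamma shapes* `λ_t p_t` and
`λs ps`, not on the rates: a rate has units of 1/production and its natural
magnitude swings over three orders within a single year (winter production
is ~10⁻⁴ of the summer peak), so any fixed scale on λ itself is badly wrong
for most periods and, in practice, drags winter periods into a
shape-collapse regime in which the gamma mean decouples from the data. The
shape is dimensionless and ~1–10 for any plausible measurement process;
one half-Cauchy(0, 5) covers every period. The change of variable back to
the rate contributes a `log p` Jacobian, which the density and its gradient
carry exactly.

## Sampling

The posterior is explored with a native Hamiltonian Monte Carlo sampler:
leapfrog integration with the step count jittered uniformly (8–32 by
default), dual-averaging step-size adaptation to a 0.9 target acceptance,
and windowed diagonal mass-matrix estimation during warmup. All positive
scalars are log-transformed; the three random walks are non-centered
(standard-normal increments scaled by their σ), which removes the
walk/step-size funnel. Gradients are reverse-mode and hand-derived; the
mass-balance recursion back-propagates in closed form through its product
structure (a reversed cumulative sum), so no per-period loop survives in
either direction. Trajectories whose energy error exceeds 500, or that
leave the admissible region, count as divergences and are rejected.

Chains start overdispersed: γ and βbase are drawn log-uniformly over their
plausible decades, the `le` path is anchored to per-period observed
production (tracking the biomass forward so the anchor stays consistent
with growth), and each period's dispersion starts where its implied shape
is ≈5. Overdispersion matters here because the posterior carries a long,
nearly flat ridge — γ, βbase and the overall level of `b` trade off against
`le`, with only the b₁ prior and the below-threshold periods pinning the
gauge — and chains started in one region understate the spread. Split-R̂ is
computed per coordinate on half-split chains against the 1.1 threshold; on
short-chain runs many path coordinates flag, which is reported, and the
recovery claims below rest on merged-chain intervals, not on a convergence
certificate.

`stmin` is profiled on a grid (default 0–10 °C by 0.1 °C; 101 fits) and
chosen by the lowest WAIC, ties toward the lower value. WAIC uses the
image-level (t, s, c) observation terms as the pointwise predictive unit —
scanner-level latent densities are excluded, since WAIC needs a predictive
factorization and the image is the natural prediction target — with
log-sum-exp stabilization and the n−1 variance for the effective-parameter
term. Thinning keeps every k-th post-warmup draw (k = 5 at the default 20%
fraction), so the reference protocol of 4 chains × 30,000 iterations with
10,000 warmup retains exactly 16,000 draws.

## Synthetic studies

The generator emulates a warm-temperate forest soil on a daily clock and
aggregates to dekads through the same code path real data take. Soil
temperature is a sinusoid (mean 15 °C, amplitude 12 °C, coldest in
mid-January, 0.8 °C daily noise), giving winter minima of ~1–6 °C and summer
maxima of ~25–28 °C. Soil moisture is a dry-down baseline of 14% plus
exponentially decaying pulses at Poisson times (0.1 events/day, mean height
4.5%, decay 0.07 day⁻¹), clipped at a 45% field-capacity ceiling — a
realized range of roughly 10–40%.

The default latent truth is the recovery-study condition: γ = 0.005 day⁻¹,
βbase = 10⁻⁴ day⁻¹, stmin = 4 °C, b₁ = 1 mm² cm⁻², with spring-peaked
smooth coefficient paths βst ∈ [0.5, 1.5] and βsm ∈ [0, 0.06]. The
endogenous path `le` is constructed rather than free: it tracks a
temperature-linked growth-rate target (βbase + 6·10⁻⁴ · (ST − stmin) day⁻¹,
≈0.014 day⁻¹ at the summer excess) at a reference moisture of 20%,
compensating the `(ST − stmin)^βext` factor there. Two reasons. First,
realism: with order-one exponents a constant `le` compounds the biomass by
orders of magnitude within a season, which no real stand does — in the
fitted models of field data the estimated `le` plays exactly this
compensating role. Second, identifiability of the threshold: tying the
target to the temperature excess makes production switch on where ST
crosses stmin, so the data carry the threshold's signature and the WAIC
scan has something to find. Moisture deviations from the 20% reference
still act through the full multiplicative response, so the interaction
remains genuinely present in the data. A `random_walk` path mode adds
walk noise around these bases, and `fixed` accepts user paths.

Observation noise holds the gamma *shape* constant (6 at both levels,
i.e. ~41% relative error) rather than the rate: scanner tracing error
scales with the traced amount, and a constant rate would imply shapes near
zero in winter — astronomically skewed draws whose means no amount of data
can pin down. Values below a detection limit of 10⁻⁶ mm² cm⁻² day⁻¹ (about
one 600-dpi pixel per day over the 200 cm² analyzed area) are recorded as
exact zeros, exercising the censoring rule. Missingness is completely at
random (5% default); scanner failures are not modelled mechanistically.

What passing recovery tests show: with data generated by the model's own
structure under these conditions (2 years, 3 scanners, 4 images, short
chains of 4 × 2000), the pipeline's 95% intervals cover γ and βbase, the
posterior-median production path correlates with truth at r > 0.9, and a
1 °C-step WAIC scan localizes stmin within 1 °C. What they do not show:
robustness to model misspecification (real phenology is not a smooth
sinusoid response; real scanner error need not be gamma), identification
of per-(t, s) dispersions, or the behavior of multi-year, multi-stand
datasets at the full 30,000-iteration protocol.

## Numerical choices and limitations

- Threshold guard ε = 0.01 °C; grid ties break toward the lower stmin.
- Positivity violations reject (−∞ density), never clamp.
- WAIC comparisons across the stmin grid share chain seeds, so grid noise
  is correlated rather than independent across points; the profile is flat
  to within tens of WAIC units away from the optimum, and threshold
  localization should be read at the grid's resolution, not finer.
- Threshold localization is the weakest recovery property at desk scale. A
  model with a smaller stmin nests the behavior of any larger one (the
  endogenous walk can emulate the suppressed response), so the profiled
  lppd favors low thresholds and only the effective-parameter penalty and
  the walk's smoothness prior push back. With two years of data the
  resulting profile is shallow: the scan localizes the generating threshold
  within the grid step for some simulated studies and slides to the grid
  edge for others. Sharper real phenology, longer records, or tighter
  priors on the walk scales all strengthen the contrast.
- Mortality γ is weakly identified from production-only data (the ridge
  above); its posterior is prior-sensitive, and the covering intervals are
  wide. This mirrors the structure of the real design, where b₁'s prior is
  set from the first scan for the same reason.
- Scan-interval rates are attributed to dekads by interval-overlap
  weighting, which conserves time-integrated production per image; missing
  dekads stay absent and are never imputed or zero-filled.
- The disturbance window after scanner installation (307 days cypress, 68
  days oak by default) is an exclusion filter on scan age, not a model
  component.
- The moisture-sensitivity report `100((ST − stmin)^βsm − 1)` neglects the
  additive βbase term; the exact variant (carrying βbase and the current
  exogenous level) is available behind a flag and agrees to ~0.1% wherever
  production is appreciable.
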