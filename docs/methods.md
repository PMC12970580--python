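# Methods

`stockprod` implements a four-stage analysis of marine fishery stock
productivity — hindcast, latent-trend extraction, driver attribution,
and climate-scenario forecast — as a tested pipeline driven by synthetic
data with known ground truth. This note records the models, the choices
that were genuinely open, the numerical decisions, and what the
synthetic experiments do and do not demonstrate.

## Productivity proxy

Stock productivity is surplus production per unit biomass:
`SP_t = B_{t+1} − B_t + C_t` and `P_t = SP_t / B_t`, with `B` total
stock biomass and `C` catch. `P` integrates growth, recruitment and
natural mortality into one rate (units 1/yr) and is invariant to joint
rescaling of biomass and catch. The last biomass year has no `P` value;
the series is indexed to the first year of each difference.

## State-space surplus-production hindcast

Biomass follows the Pella–Tomlinson family

    B_1     = psi K
    B_{t+1} = (B_t + SP(B_t) − C_t) · exp(eta_t),   eta_t ~ N(0, sigma_p^2)
    SP(B)   = (r/(m−1)) · B · (1 − (B/K)^(m−1))

with the Schaefer model at m = 2 and the Fox model as the m → 1 limit
(`SP = r B ln(K/B)`). Abundance indices are lognormal around `q_i B_t`
with per-index variance `fixed_obs_var + a_i`, where the floor defaults
to 0.1 on the log scale and `a_i` is estimated. The floor is interpreted
as a variance; it is configurable because the convention is ambiguous in
assessment practice.

Priors: lognormal for `r`, `K`, `psi` (and `m`, centred at 1.2, for
Pella–Tomlinson), elicited from resilience categories, catch history and
qualitative stock-size rules; inverse-gamma(0.001, 0.001) for the
process variance and the additional observation variances; weak
lognormal for `q_i` centred on a crude index-scale guess (log-sd 2).
`psi` is truncated at 1.2 rather than 1.0 to avoid boundary pathologies
in sampling; the elicitation itself caps the prior limits at 1.0.

Boundary conventions in the elicitation follow the printed rules
exactly: the `≥` rule wins at the exact cut-points (B/B_MSY = 1.75 is
"Close to unexploited"; C/C_MAX = 0.80 is "Very small"), majority votes
across abundance indices resolve ties precautionarily (terminal biomass
"Low"; the more-depleted category for initial size).

### Sampling

The posterior is explored by Metropolis-within-Gibbs:

- adaptive Gaussian random-walk Metropolis on (log r, log K, log psi
  [, log m]) with Haario-style covariance adaptation, a Robbins–Monro
  scale targeting 0.30 acceptance, and a proposal-covariance floor at
  5% of the prior scales so weakly informed directions keep exploring;
- an occasional independence proposal from the prior for one of those
  components (prior density cancels in the ratio), which restores exact
  prior sampling for unidentified parameters;
- exact conjugate Gibbs draws for each log-catchability;
- univariate slice sampling for the additional observation variances
  (sufficient-statistics form) and, on alternating iterations, the
  process variance;
- elliptical slice sampling for the non-centred process innovations
  `z = eta / sigma_p`, so the state equation holds by construction in
  every retained draw.

Desk-scale default: 3 chains × 20,000 iterations, 10,000 burn-in,
thinning 5 — 6,000 retained parameter sets, the same count as the
reference assessment settings (3 × 200,000 / 100,000 / 50), which remain
available by configuration. One 40-year, one-index fit takes a few
seconds on one CPU.

Known limitation: with very small observation error the posterior
concentrates on a thin curved (r, K) ridge that the random-walk kernel
traverses slowly; R-hat flags this honestly. Under the moderate noise
of the study conditions (index sd ≈ 0.15, floor 0.1) chains converge
well (R-hat ≈ 1.0–1.2).

### Diagnostics

Rank-normalized split R-hat (< 1.05 passes) via ArviZ; Hartigan's dip
test of posterior unimodality (p > 0.05 passes), with the dip statistic
implemented from the published algorithm and validated against an exact
linear-programming formulation at small n, and a seeded Monte-Carlo
uniform null; DIC in the Spiegelhalter form with the conditional
(given-states) observation deviance — the quantity a JAGS-style sampler
reports — and a plug-in at posterior means of the log-scale quantities.
Posterior-to-prior mean and variance ratios (PPMR/PPVR) discriminate
data-driven from prior-driven fits; the default "close to 1" band is
|log ratio| < log 1.25, configurable.

DIC model selection between production variants is only informative
when the process error is pinned (concentrated inverse-gamma prior) and
several indices constrain the trajectory: with a loose process prior
the states absorb the production-curve shape and the conditional
deviance cannot separate Schaefer from Fox. The variant-selection test
uses that design.

## Productivity ensembles and trends

1,000 of the 6,000 retained draws are sampled without replacement
(seeded); each member's `P` series uses that draw's biomass trajectory
with the observed catch. Long-term patterns are classified by OLS of
`P` on year over 1981–2022: positive/negative iff the 95% t-interval of
the slope excludes zero; zero-variance series are neutral by guard.
Trend classification defaults to the ensemble-mean series; per-member
pooling is available.

## Dynamic factor analysis

Per area, the stock × year productivity panel (rows standardized) is
reduced to 1–2 latent random-walk trends with `Q = I`, upper-triangular
zero constraint on the loadings, `x_1 ~ N(0, 5 I)`, and three error
structures: equal variances/no covariance, unequal variances/no
covariance, equal variances and covariances. Estimation is ECM around a
Kalman filter/smoother (exact conditional M-steps; the
compound-symmetry R update uses its eigen-decomposition and is exact on
complete panels; with partially missing rows it is an approximation).
Model selection uses AICc with `n_eff` = the number of non-missing
cells. EM stops on an absolute log-likelihood change below 1e-4
(monotonicity asserted to 1e-8 in tests).

Loading uncertainty: EM creeps along the weakly identified common-scale
direction of the loadings, so before computing confidence intervals the
solution is polished by L-BFGS on the marginal likelihood; standard
errors then come from the observed information (finite differences),
with a sign-aligned parametric bootstrap as fallback when the Hessian is
not positive definite. Each trend is flipped so its significant
loadings sum positive; the likelihood is invariant to that gauge.

The DFA coverage window keeps the maximal contiguous year range where
more than 60% of stocks have data.

## Student-t mixed models

Eight structures relate `P` to temperature, chlorophyll and mixed-layer
depth with all three fixed slopes and species-level random terms from
none up to intercept + two slopes (see `glmm.STRUCTURES`; the menu
includes random MLD slopes in structures 5, 7 and 8). Residuals are
Student-t with identity link; `nu` is shared across species and floored
at 2.01; drivers are centred per stock so species intercepts absorb
level differences (toggleable).

The marginal likelihood integrates species effects by a Laplace
approximation: damped Newton with curvature clipping finds each
species' conditional mode (vectorized across species), and the
observed-curvature determinant is used at the mode (clipped fallback if
indefinite). The outer optimization is Nelder-Mead over
(beta, log random sds, log scale, log(nu − 2.01)), warm-started across
ensemble members. The Gaussian limit (nu fixed large) matches a
maximum-likelihood linear mixed model to 1e-3, and the no-random-effects
structure matches a directly optimized t regression.

Ensemble propagation follows the hindcast design exactly: each
productivity candidate is fitted separately (all structures), ΔAIC/ΔBIC
are computed within member against that member's best, the best overall
structure minimizes the median ΔAIC, and species-slope intervals (66%,
95%) come only from the spread across members — per-fit parameter
uncertainty is deliberately not propagated, since it would widen the
intervals without moving the means.

Collinearity screening computes per-stock Pearson correlations among
drivers and compares them to the critical values
`t_crit / sqrt(t_crit^2 + df)`; at 26 degrees of freedom these are
0.374 (p = 0.05) and 0.4785 (p = 0.01; printed as 0.478 in standard
tables, which truncate).

## Forecast

Scenario driver series (2021–2100) are synthetic trend + AR(1)
extensions of each stock's historical drivers (e.g. +1.5 / +4.5 °C by
2100 for mild/harsh scenarios). Projections are central: each ensemble
member contributes its fixed + species-conditional linear predictor at
the (re-centred) future drivers, with no residual resampling, so the
per-year interval reflects hindcast-propagated parameter spread only.
Projection is exactly linear in each driver.

Decade contrasts compare 2091–2100 against 2021–2030 (the forecast
window's first and last decades), member-wise: `Δ = mean(focus) −
mean(ref)` and `100 Δ / mean(ref)`, summarized by the ensemble mean and
95% percentile interval. A stock is a winner/loser iff its 95% interval
of Δ lies entirely above/below zero. Landings equivalents multiply a
proxy change by 3,300 Mt of exploited biomass. Regional and global
aggregation averages stocks unweighted within each member; intervals
come from the member spread of the cross-stock mean.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis
assumes: state-space biomass dynamics with lognormal process and
observation error; hump-shaped "development then decline" exploitation
histories; annual driver series as trend + AR(1) noise (defaults:
temperature 12 °C baseline, +0.02 °C/yr, sd 0.25 °C; chlorophyll
1 mg m⁻³, ~20% interannual CV; mixed-layer depth 50 m, ~10% CV — chosen
once as realistic interannual variability for shelf seas); community
productivity panels that follow the random-slope mixed model with
Student-t noise; and gridded fields with depth layers for the
polygon-mean extraction (< 50 m unweighted vertical average, even–odd
point-in-polygon on cell centres — cells and layers are unweighted
because no weighting rule is specified by the source data conventions).

It does not emulate: real assessment-database schema quirks, biased or
autocorrelated index errors, catch misreporting, curvilinear ESM grids,
species interactions, or any feedback of drivers on biomass dynamics
(the hindcast fleet's drivers are independent of its biomass paths, so
pipeline-level attribution runs exercise plumbing, not effect
recovery — effect recovery is tested at the community-generator level,
where truth is known). Passing tests therefore demonstrate internal
correctness and calibration under the assumed model, not robustness to
real-data violations of it.

## Problem sizes used by tests and the acceptance script

Recovery calibration: 20 seeded replicates of a 40-year, one-index
Schaefer stock at the desk-scale MCMC settings. Variant selection: 8
replicates, 50 years, three indices. Random-slope recovery: 50 species
× 2 stocks × 28 years. Ensemble demonstrations: 8–10 members. The
community forecast experiments use 16 species × 2 stocks, 8 members,
pooled over 8–12 seeds. These sizes are the package's desk-scale
defaults; the full-scale settings of the reference analysis remain
available through configuration.
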