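# stockprod

Hindcasting and climate-scenario forecasting of marine fishery **stock
productivity** — surplus production per unit of stock biomass,
`P_t = (B_{t+1} − B_t + C_t) / B_t` — for researchers in fishery
oceanography and stock assessment who want a tested, reproducible
implementation of the full analysis chain on data with known ground
truth.

The pipeline has four stages:

1. **Hindcast.** Bayesian state-space surplus-production models
   (Schaefer, Fox, Pella–Tomlinson) are fitted by MCMC to catch and
   abundance-index series, with lognormal priors for the intrinsic rate
   `r`, carrying capacity `K` and initial depletion `ψ` elicited from
   resilience categories, catch history and qualitative stock-size
   rules. Variants are compared by DIC; convergence and unimodality are
   checked with rank-normalized R-hat and Hartigan's dip test; 1,000
   posterior draws per stock become an ensemble of productivity
   candidate series.
2. **Latent trends.** Dynamic factor analysis (random-walk trends,
   `Q = I`, three error-covariance structures, AICc selection) extracts
   one or two common productivity trends per area, with loading
   confidence intervals from the observed information.
3. **Attribution.** Eight generalized linear mixed models with
   Student-t errors relate productivity to temperature, chlorophyll and
   mixed-layer depth, with species-level random intercepts and slopes;
   all 1,000 ensemble members are refitted and only the member spread
   forms the confidence intervals.
4. **Forecast.** The fitted model ensemble is projected through
   scenario driver series (2021–2100); stocks are classified as
   climate *winners* or *losers* by whether the 95% interval of their
   end-of-century productivity change excludes zero, and proxy changes
   convert to landings equivalents against 3,300 Mt of exploited
   biomass.

All inputs are produced by the `synthetic` module (first-class, tested
code): state-space stock dynamics, trending AR(1) driver panels, gridded
fields with depth layers, and mixed-model community panels — each with
stored truth so every stage has a parameter-recovery test surface.

## Worked example

```python
import numpy as np
from stockprod import priors, productivity, spm, synthetic

params = synthetic.TrueStockParams(r=0.4, K=1000.0, psi=0.9, q=(0.005,),
                                   sigma_proc=0.05, sigma_obs=(0.15,))
stock = synthetic.simulate_stock(params, synthetic.development_decline(0.3, 15, 40),
                                 n_years=40, seed=7, resilience="Medium")

r_prior = priors.r_prior_from_resilience("Medium")
k_prior = priors.k_prior(stock.catch, r_prior, priors.biomass_level_end(stock))
psi_prior = priors.psi_prior(priors.qualitative_stock_size(stock))

post = spm.fit_spm(stock, spm.SPMPriors(r_prior, k_prior, psi_prior),
                   spm.SPMConfig(variant="Schaefer"), seed=11)
for name in ("r", "K", "psi"):
    lo, mid, hi = np.percentile(post.draws(name), [2.5, 50, 97.5])
    print(f"{name:3s} {mid:8.3f}  [{lo:.3f}, {hi:.3f}]  Rhat {post.rhat[name]:.3f}")

ens = productivity.build_ensemble(post, stock.catch, n_members=1000, seed=3)
trend = productivity.classify_linear_trend(ens.mean, ens.years)
print(f"productivity trend: {trend.label} (slope {trend.slope:.5f}/yr)")
```

Output:

```
r      0.311  [0.196, 0.407]  Rhat 1.069
K   1143.797  [890.198, 1805.762]  Rhat 1.073
psi    0.869  [0.757, 0.994]  Rhat 1.008
productivity trend: positive (slope 0.00402/yr)
```

The true `r = 0.4`, `K = 1000` and `ψ = 0.9` all lie inside their 95%
credible intervals; the positive productivity trend reflects this
stock's simulated recovery after peak exploitation. A full synthetic
fleet runs end-to-end (priors → MCMC → ensembles → DFA → GLMM →
forecast) through `stockprod.pipeline.run_pipeline`, which caches each
stage on disk and is byte-reproducible for a fixed seed.

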