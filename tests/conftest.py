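import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stockprod import priors as pr
from stockprod import spm, synthetic as syn

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schaefer_stock():
    """A 40-year Schaefer stock with moderate noise and known truth."""
    params = syn.TrueStockParams(
        r=0.4, K=1000.0, psi=0.9, q=(0.005,), sigma_proc=0.05, sigma_obs=(0.15,)
    )
    rec = syn.simulate_stock(
        params, syn.development_decline(0.3, 15, 40), 40, seed=7,
        resilience="Medium",
    )
    return rec, params


@pytest.fixture(scope="session")
def schaefer_priors(schaefer_stock):
    rec, _ = schaefer_stock
    rprior = pr.r_prior_from_resilience("Medium")
    kprior = pr.k_prior(rec.catch, rprior, pr.biomass_level_end(rec))
    psiprior = pr.psi_prior(pr.qualitative_stock_size(rec))
    return spm.SPMPriors(r=rprior, K=kprior, psi=psiprior)


@pytest.fixture(scope="session")
def schaefer_posterior(schaefer_stock, schaefer_priors):
    """One desk-scale SPM fit shared across tests (seeded, ~6 s)."""
    rec, _ = schaefer_stock
    cfg = spm.SPMConfig(variant="Schaefer")
    return spm.fit_spm(rec, schaefer_priors, cfg, seed=11)


@pytest.fixture(scope="session")
def community_with_slopes():
    """Community panel with random T/CHL slopes (structure-6 truth)."""
    panel, truth = syn.simulate_community(
        n_species=24, stocks_per_species=2,
        fixed_betas={"alpha": 0.12, "T": 0.015, "CHL": 0.04, "MLD": -0.001},
        random_slope_sds={"alpha": 0.04, "T": 0.02, "CHL": 0.02},
        resid_scale=0.02, resid_df=8.0, seed=21,
    )
    return panel, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
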