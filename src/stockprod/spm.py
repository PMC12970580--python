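"""Bayesian state-space surplus-production models (SPMs).

The biomass dynamics follow the Pella–Tomlinson family::

    B_1     = psi * K
    B_{t+1} = (B_t + SP(B_t) - C_t) * exp(eta_t),   eta_t ~ N(0, sigma_proc^2)
    I_{i,t} = q_i * B_t * exp(eps_{i,t}),           eps   ~ N(0, tau_i^2)

with surplus production SP(B) = (r/(m-1)) B (1 - (B/K)^(m-1)); the
Schaefer model is the case m = 2 and the Fox model the limit m -> 1,
SP(B) = r B ln(K/B).  Observation variance per index is a fixed floor
plus an estimated additional component, as in catch-and-index biomass
dynamics assessments.

Sampling is by adaptive random-walk Metropolis on the structural
parameters combined with elliptical slice sampling on the non-centred
process innovations, run as independent chains; only the chain /
burn-in / thinning bookkeeping is contractual, not the kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import gammaln

from .diagnostics import compute_dic, dip_test, rhat
from .priors import LognormalPrior

__all__ = [
    "SPMConfig",
    "SPMPriors",
    "PosteriorEnsemble",
    "SPMFitError",
    "surplus_production",
    "b_msy",
    "msy",
    "log_posterior",
    "fit_spm",
]

_VARIANTS = {"Schaefer": 0, "Fox": 1, "PellaTomlinson": 2}


class SPMFitError(RuntimeError):
    """Raised when no finite starting point or chain can be found."""


def surplus_production(B, r, K, m: float = 2.0, variant: str = "Schaefer"):
    """Annual surplus production at biomass ``B``.

    Pella–Tomlinson: SP = (r/(m-1)) B (1 - (B/K)^(m-1)); ``Schaefer`` is
    m = 2 and ``Fox`` the m -> 1 limit, SP = r B ln(K/B).
    """
    if variant not in _VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; valid: {sorted(_VARIANTS)}")
    B = np.asarray(B, dtype=float)
    if np.any(B < 0) or K <= 0:
        raise ValueError("require B >= 0 and K > 0")
    if variant == "Schaefer":
        return r * B * (1.0 - B / K)
    if variant == "Fox":
        with np.errstate(divide="ignore", invalid="ignore"):
            sp = np.where(B > 0, r * B * np.log(K / np.maximum(B, 1e-300)), 0.0)
        return sp if sp.ndim else float(sp)
    if m == 1.0:
        raise ValueError("Pella-Tomlinson with m = 1 is singular; use variant='Fox'")
    return (r / (m - 1.0)) * B * (1.0 - (B / K) ** (m - 1.0))


def b_msy(r: float, K: float, m: float = 2.0, variant: str = "Schaefer") -> float:
    """Biomass at maximum surplus production."""
    if variant == "Schaefer":
        return K / 2.0
    if variant == "Fox":
        return K / math.e
    return K * m ** (1.0 / (1.0 - m))


def msy(r: float, K: float, m: float = 2.0, variant: str = "Schaefer") -> float:
    """Maximum surplus production (rK/4 for Schaefer)."""
    return float(surplus_production(b_msy(r, K, m, variant), r, K, m, variant))


@dataclass(frozen=True)
class SPMConfig:
    """MCMC settings for one surplus-production fit.

    The reference assessment settings are 3 chains x 200,000 iterations,
    100,000 burn-in, thinning 50 (6,000 saved parameter sets); the desk
    default uses 3 x 20,000 / 10,000 / 5, retaining the same 6,000 sets.
    """

    variant: str = "Schaefer"
    n_chains: int = 3
    n_iter: int = 20_000
    n_burnin: int = 10_000
    thin: int = 5
    fixed_obs_var: float = 0.1  # floor on the log-scale observation variance
    proc_var_prior: tuple[float, float] = (0.001, 0.001)  # inverse-gamma
    add_obs_var_prior: tuple[float, float] = (0.001, 0.001)
    psi_max: float = 1.2  # soft truncation above "unexploited"

    def __post_init__(self):
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if not self.n_iter > self.n_burnin:
            raise ValueError("n_iter must exceed n_burnin")
        if self.thin < 1 or self.fixed_obs_var < 0:
            raise ValueError("thin >= 1 and fixed_obs_var >= 0 required")

    @property
    def n_saved(self) -> int:
        """Total retained parameter sets across chains."""
        return self.n_chains * ((self.n_iter - self.n_burnin) // self.thin)


@dataclass
class SPMPriors:
    """Priors for one stock's SPM fit.

    ``q`` priors default to a very weak lognormal centred on a crude
    index-scale guess; ``m`` is only used by the Pella–Tomlinson variant
    (weakly informative, centred at 1.2).
    """

    r: LognormalPrior
    K: LognormalPrior
    psi: LognormalPrior
    q: list[LognormalPrior] | None = None
    m: LognormalPrior = field(
        default_factory=lambda: LognormalPrior(1.2 * math.exp(-1.96 * 0.3), 1.2 * math.exp(1.96 * 0.3))
    )


@dataclass
class PosteriorEnsemble:
    """Retained draws, biomass states and diagnostics of one SPM fit."""

    variant: str
    param_names: list[str]
    chain_draws: dict  # name -> (n_chains, n_per_chain)
    states: np.ndarray  # (n_saved, T) biomass trajectories
    loglik: np.ndarray  # (n_saved,) observation log-likelihood per draw
    years: np.ndarray
    dic: float
    rhat: dict
    dip_p: dict
    ppmr: dict
    ppvr: dict
    config: SPMConfig

    @property
    def n_saved(self) -> int:
        return self.states.shape[0]

    def draws(self, name: str) -> np.ndarray:
        """Pooled draws for one parameter (flattened across chains)."""
        return self.chain_draws[name].reshape(-1)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({n: self.draws(n) for n in self.param_names})

    def converged(self, rhat_limit: float = 1.05, dip_alpha: float = 0.05) -> bool:
        """Paper-style pass: all R-hat < limit and all dip p-values > alpha."""
        core = [n for n in ("r", "K", "psi") if n in self.rhat]
        return all(self.rhat[n] < rhat_limit for n in core) and all(
            self.dip_p[n] > dip_alpha for n in core
        )


# --- numba core ------------------------------------------------------------


@njit(cache=True)
def _traj_obsll(
    logr, logK, psi, m, variant, sigma_proc, z, catch, logI, logq, totvar
):
    """Biomass recursion + observation log-likelihood.

    Returns (ok, logB, obs_ll). ok = False when the catch drives the
    population non-positive or values overflow.
    """
    T = catch.shape[0]
    logB = np.empty(T)
    r = math.exp(logr)
    K = math.exp(logK)
    B = psi * K
    if not (B > 0.0) or not math.isfinite(B):
        return False, logB, 0.0
    logB[0] = math.log(B)
    for t in range(T - 1):
        if variant == 0:
            sp = r * B * (1.0 - B / K)
        elif variant == 1:
            sp = r * B * math.log(K / B)
        else:
            sp = (r / (m - 1.0)) * B * (1.0 - (B / K) ** (m - 1.0))
        nxt = B + sp - catch[t]
        if not (nxt > 0.0) or not math.isfinite(nxt):
            return False, logB, 0.0
        B = nxt * math.exp(sigma_proc * z[t])
        if not math.isfinite(B):
            return False, logB, 0.0
        logB[t + 1] = math.log(B)
    ll = 0.0
    n_idx = logI.shape[0]
    for i in range(n_idx):
        v = totvar[i]
        c = -0.5 * math.log(2.0 * math.pi * v)
        for t in range(T):
            y = logI[i, t]
            if not math.isnan(y):
                resid = y - logq[i] - logB[t]
                ll += c - 0.5 * resid * resid / v
    return True, logB, ll


class _Model:
    """Packed data + parameter transform for one stock/variant fit."""

    def __init__(self, record, priors: SPMPriors, config: SPMConfig):
        self.config = config
        self.variant = _VARIANTS[config.variant]
        self.estimate_m = config.variant == "PellaTomlinson"
        self.catch = np.asarray(record.catch, dtype=float)
        self.years = np.asarray(record.years)
        self.T = self.catch.size
        idx = np.atleast_2d(np.asarray(record.indices, dtype=float))
        with np.errstate(divide="ignore", invalid="ignore"):
            self.logI = np.where(idx > 0, np.log(np.where(idx > 0, idx, 1.0)), np.nan)
        self.k = self.logI.shape[0]
        self.priors = priors
        if priors.q is None:
            # weak empirical prior: centre q near median(I)/(psi_med * K_med)
            qp = []
            b0 = priors.psi.median * priors.K.median
            for i in range(self.k):
                obs = idx[i][np.isfinite(idx[i]) & (idx[i] > 0)]
                q0 = (np.median(obs) / b0) if obs.size else 1.0
                qp.append(LognormalPrior(q0 * math.exp(-1.96 * 2.0), q0 * math.exp(1.96 * 2.0)))
            self.q_priors = qp
        else:
            self.q_priors = list(priors.q)
        # theta layout: logr, logK, logpsi, logq_1..k, log_pv, log_av_1..k [, logm]
        self.dim = 3 + self.k + 1 + self.k + (1 if self.estimate_m else 0)
        # per-component prior scales, used to regularize proposal adaptation
        self.prior_scales = np.concatenate([
            [priors.r.log_sd, priors.K.log_sd, priors.psi.log_sd],
            [qp.log_sd for qp in self.q_priors],
            [2.0], np.full(self.k, 2.0),
            [priors.m.log_sd] if self.estimate_m else [],
        ])
        # components with (log-)normal priors, usable for independence moves
        self.normal_components = [
            (0, priors.r.log_mean, priors.r.log_sd),
            (1, priors.K.log_mean, priors.K.log_sd),
            (2, priors.psi.log_mean, priors.psi.log_sd),
        ] + (
            [(4 + 2 * self.k, priors.m.log_mean, priors.m.log_sd)]
            if self.estimate_m else []
        )
        # the adaptive random-walk block: r, K, psi (and m for PT);
        # q is Gibbs-conjugate and the variances are slice-sampled
        self.core_idx = np.array(
            [0, 1, 2] + ([4 + 2 * self.k] if self.estimate_m else [])
        )

    def gibbs_q(self, theta, logB, rng):
        """Exact conditional draw of each log-catchability.

        Given states and variances, log q_i is conjugate normal:
        log I - log B = log q + eps with eps ~ N(0, v_i).
        """
        k = self.k
        for i in range(k):
            obs = np.isfinite(self.logI[i])
            n_i = int(obs.sum())
            if n_i == 0:
                prior = self.q_priors[i]
                theta[3 + i] = prior.log_mean + prior.log_sd * rng.standard_normal()
                continue
            v = self.config.fixed_obs_var + math.exp(theta[4 + k + i])
            d = self.logI[i][obs] - logB[obs]
            prior = self.q_priors[i]
            prec = 1.0 / prior.log_sd**2 + n_i / v
            mean = (prior.log_mean / prior.log_sd**2 + np.sum(d) / v) / prec
            theta[3 + i] = mean + rng.standard_normal() / math.sqrt(prec)

    def slice_add_var(self, theta, logB, rng):
        """Slice-sample each additional observation variance (log scale)."""
        k = self.k
        a, b = self.config.add_obs_var_prior
        c = self.config.fixed_obs_var
        for i in range(k):
            obs = np.isfinite(self.logI[i])
            n_i = int(obs.sum())
            ss = float(np.sum(
                (self.logI[i][obs] - theta[3 + i] - logB[obs]) ** 2
            )) if n_i else 0.0

            def logf(u):
                if not -40.0 < u < 40.0:  # truncate the near-flat prior
                    return -np.inf
                v = c + math.exp(u)
                return (_invgamma_logpdf_on_log(u, a, b)
                        - 0.5 * n_i * math.log(2 * math.pi * v)
                        - 0.5 * ss / v)

            theta[4 + k + i] = _slice_1d(logf, theta[4 + k + i], rng)

    def slice_proc_var(self, theta, z, rng):
        """Slice-sample the process variance (log scale)."""
        a, b = self.config.proc_var_prior
        idx = 3 + self.k

        def logf(u):
            if not -40.0 < u < 40.0:
                return -np.inf
            th = theta.copy()
            th[idx] = u
            ll, _ = self.obs_loglik(th, z)
            return _invgamma_logpdf_on_log(u, a, b) + ll

        theta[idx] = _slice_1d(logf, theta[idx], rng)
        self.names = (
            ["r", "K", "psi"]
            + [f"q_{i + 1}" for i in range(self.k)]
            + ["proc_var"]
            + [f"add_obs_var_{i + 1}" for i in range(self.k)]
            + (["m"] if self.estimate_m else [])
        )

    def unpack(self, theta):
        k = self.k
        logr, logK, logpsi = theta[0], theta[1], theta[2]
        logq = theta[3 : 3 + k]
        log_pv = theta[3 + k]
        log_av = theta[4 + k : 4 + 2 * k]
        m = math.exp(theta[4 + 2 * k]) if self.estimate_m else 2.0
        return logr, logK, logpsi, logq, log_pv, log_av, m

    def log_prior(self, theta) -> float:
        pr = self.priors
        logr, logK, logpsi, logq, log_pv, log_av, m = self.unpack(theta)
        if logpsi > math.log(self.config.psi_max):
            return -np.inf
        lp = 0.0
        for val, prior in ((logr, pr.r), (logK, pr.K), (logpsi, pr.psi)):
            lp += _norm_logpdf(val, prior.log_mean, prior.log_sd)
        for i in range(self.k):
            lp += _norm_logpdf(logq[i], self.q_priors[i].log_mean, self.q_priors[i].log_sd)
        a, b = self.config.proc_var_prior
        lp += _invgamma_logpdf_on_log(log_pv, a, b)
        aa, ab = self.config.add_obs_var_prior
        for i in range(self.k):
            lp += _invgamma_logpdf_on_log(log_av[i], aa, ab)
        if self.estimate_m:
            lp += _norm_logpdf(math.log(m), pr.m.log_mean, pr.m.log_sd)
        return lp

    def obs_loglik(self, theta, z):
        logr, logK, logpsi, logq, log_pv, log_av, m = self.unpack(theta)
        sigma = math.sqrt(math.exp(log_pv))
        totvar = self.config.fixed_obs_var + np.exp(log_av)
        ok, logB, ll = _traj_obsll(
            logr, logK, math.exp(logpsi), m, self.variant, sigma, z,
            self.catch, self.logI, logq, totvar,
        )
        return (ll if ok else -np.inf), logB

    def log_post(self, theta, z) -> float:
        lp = self.log_prior(theta)
        if not np.isfinite(lp):
            return -np.inf
        ll, _ = self.obs_loglik(theta, z)
        return lp + ll - 0.5 * float(z @ z)


def _norm_logpdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)


def _invgamma_logpdf_on_log(u, a, b):
    """log density of log(V) where V ~ InvGamma(a, b) (includes Jacobian)."""
    return a * math.log(b) - gammaln(a) - a * u - b * math.exp(-u)


def log_posterior(params: dict, record, priors: SPMPriors, config: SPMConfig) -> float:
    """Log posterior density at natural-scale parameter values.

    ``params`` holds r, K, psi, q (sequence), proc_var, add_obs_var
    (sequence), optionally m, and optionally ``innovations`` (the
    standardized process deviations; default zero). Raises if the density
    is not finite, naming the offending component.
    """
    model = _Model(record, priors, config)
    k = model.k
    theta = np.empty(model.dim)
    theta[0] = math.log(params["r"])
    theta[1] = math.log(params["K"])
    theta[2] = math.log(params["psi"])
    theta[3 : 3 + k] = np.log(np.atleast_1d(params["q"]))
    theta[3 + k] = math.log(params["proc_var"])
    theta[4 + k : 4 + 2 * k] = np.log(np.atleast_1d(params["add_obs_var"]))
    if model.estimate_m:
        theta[4 + 2 * k] = math.log(params["m"])
    z = np.asarray(params.get("innovations", np.zeros(model.T - 1)), dtype=float)
    lp = model.log_prior(theta)
    if not np.isfinite(lp):
        raise ValueError("non-finite prior density (parameter outside support)")
    ll, _ = model.obs_loglik(theta, z)
    if not np.isfinite(ll):
        raise ValueError(
            "non-finite likelihood: biomass trajectory collapses under the catch"
        )
    return lp + ll - 0.5 * float(z @ z)


def _slice_1d(logf, x0, rng, w: float = 1.0, max_steps: int = 20):
    """Univariate slice sampler with stepping-out and shrinkage."""
    f0 = logf(x0)
    if not np.isfinite(f0):
        return x0
    logy = f0 + math.log(rng.uniform())
    u = rng.uniform()
    lo, hi = x0 - w * u, x0 + w * (1.0 - u)
    for _ in range(max_steps):
        if logf(lo) <= logy:
            break
        lo -= w
    for _ in range(max_steps):
        if logf(hi) <= logy:
            break
        hi += w
    for _ in range(100):
        x1 = rng.uniform(lo, hi)
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


def _ess_step(z, ll_fun, ll_cur, rng):
    """One elliptical slice sampling update of the innovation vector."""
    nu = rng.standard_normal(z.size)
    logu = ll_cur + math.log(rng.uniform())
    theta = rng.uniform(0.0, 2.0 * math.pi)
    tmin, tmax = theta - 2.0 * math.pi, theta
    for _ in range(100):
        znew = z * math.cos(theta) + nu * math.sin(theta)
        ll = ll_fun(znew)
        if ll > logu:
            return znew, ll
        if theta < 0.0:
            tmin = theta
        else:
            tmax = theta
        theta = rng.uniform(tmin, tmax)
    return z, ll_cur


def _init_theta(model: _Model, rng) -> np.ndarray:
    """Draw starting values from the priors until the posterior is finite."""
    pr, cfg = model.priors, model.config
    z0 = np.zeros(model.T - 1)
    for attempt in range(300):
        jitter = 0.0 if attempt == 0 else 0.5
        theta = np.empty(model.dim)
        theta[0] = pr.r.log_mean + jitter * pr.r.log_sd * rng.standard_normal()
        theta[1] = pr.K.log_mean + jitter * pr.K.log_sd * rng.standard_normal()
        # start near-unexploited: high initial biomass rarely collapses
        theta[2] = min(
            pr.psi.log_mean + jitter * pr.psi.log_sd * rng.standard_normal(),
            math.log(cfg.psi_max) - 1e-6,
        )
        if attempt > 150:  # push K upward if the catch keeps crashing the stock
            theta[1] += 0.01 * attempt
        for i in range(model.k):
            theta[3 + i] = model.q_priors[i].log_mean
        theta[3 + model.k] = math.log(0.01)
        theta[4 + model.k : 4 + 2 * model.k] = math.log(0.01)
        if model.estimate_m:
            theta[4 + 2 * model.k] = pr.m.log_mean
        if np.isfinite(model.log_post(theta, z0)):
            return theta
    raise SPMFitError("no finite starting point found (stock collapses under catch)")


def fit_spm(record, priors: SPMPriors, config: SPMConfig, seed: int) -> PosteriorEnsemble:
    """Fit one state-space SPM by MCMC and assemble draws + diagnostics."""
    if np.asarray(record.catch).size < 15:
        raise ValueError("selection criterion: catch series must span >= 15 years")
    model = _Model(record, priors, config)
    if model.k < 1 or not np.any(np.isfinite(model.logI)):
        raise ValueError("selection criterion: at least one abundance index required")

    n_per_chain = (config.n_iter - config.n_burnin) // config.thin
    d = model.dim
    chain_theta = np.empty((config.n_chains, n_per_chain, d))
    chain_states = np.empty((config.n_chains, n_per_chain, model.T))
    chain_ll = np.empty((config.n_chains, n_per_chain))

    core = model.core_idx
    dc = core.size
    for c in range(config.n_chains):
        rng = np.random.default_rng([seed % (2**31), c])
        theta = _init_theta(model, rng)
        z = np.zeros(model.T - 1)
        obs_ll, logB = model.obs_loglik(theta, z)
        lp_theta = model.log_prior(theta) + obs_ll

        mean = theta[core].copy()
        cov = np.zeros((dc, dc))
        log_lam = 0.0
        chol = None
        i_save = 0
        for it in range(config.n_iter):
            # --- adaptive RW Metropolis on the core block (r, K, psi[, m])
            if it >= 200 and it % 25 == 0:
                lam = (2.38**2 / dc) * math.exp(log_lam)
                # floor the adapted covariance at a fraction of the prior
                # scales so prior-dominated directions keep exploring
                reg = np.diag((0.05 * model.prior_scales[core]) ** 2)
                try:
                    chol = np.linalg.cholesky(lam * (cov / max(it, 1) + reg))
                except np.linalg.LinAlgError:
                    chol = None
            prop = theta.copy()
            if chol is not None:
                prop[core] = theta[core] + chol @ rng.standard_normal(dc)
            else:
                prop[core] = theta[core] + 0.05 * math.exp(log_lam) * (
                    model.prior_scales[core] * rng.standard_normal(dc)
                )
            lp_prop = model.log_prior(prop)
            if np.isfinite(lp_prop):
                ll_prop, logB_prop = model.obs_loglik(prop, z)
                lp_prop = lp_prop + ll_prop
            acc = np.isfinite(lp_prop) and (
                lp_prop - lp_theta > math.log(rng.uniform())
            )
            if acc:
                theta, lp_theta, logB = prop, lp_prop, logB_prop
                obs_ll = ll_prop
            gamma = 2.0 * (it + 1.0) ** -0.6
            log_lam += gamma * ((1.0 if acc else 0.0) - 0.30)
            delta = theta[core] - mean
            mean += delta / (it + 1.0)
            cov += np.outer(delta, theta[core] - mean)

            # occasional independence refresh of one core component
            # (proposal density = prior, so the ratio reduces to the
            # likelihood ratio; helps escape local ridge positions)
            if it % 7 == 3:
                j, mu_j, sd_j = model.normal_components[
                    rng.integers(len(model.normal_components))
                ]
                prop = theta.copy()
                prop[j] = mu_j + sd_j * rng.standard_normal()
                lp_prop = model.log_prior(prop)
                if np.isfinite(lp_prop):
                    ll_prop, logB_prop = model.obs_loglik(prop, z)
                    lp_prop = lp_prop + ll_prop
                    log_ratio = (lp_prop - lp_theta) - (
                        _norm_logpdf(prop[j], mu_j, sd_j)
                        - _norm_logpdf(theta[j], mu_j, sd_j)
                    )
                    if log_ratio > math.log(rng.uniform()):
                        theta, lp_theta, logB = prop, lp_prop, logB_prop
                        obs_ll = ll_prop

            # --- Gibbs draw of catchabilities, slice updates of variances
            # (the process variance scan alternates iterations: its
            # conditional needs a trajectory recursion per evaluation)
            model.gibbs_q(theta, logB, rng)
            model.slice_add_var(theta, logB, rng)
            if it % 2 == 0:
                model.slice_proc_var(theta, z, rng)
            obs_ll, logB = model.obs_loglik(theta, z)

            # --- elliptical slice update of the innovations
            cell = [logB]

            def _llz(znew, _theta=theta, _cell=cell):
                ll, lb = model.obs_loglik(_theta, znew)
                if np.isfinite(ll):
                    _cell[0] = lb
                return ll

            z_new, ll_new = _ess_step(z, _llz, obs_ll, rng)
            if z_new is not z:
                obs_ll = ll_new
                logB = cell[0]
                z = z_new
            lp_theta = model.log_prior(theta) + obs_ll

            if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
                chain_theta[c, i_save] = theta
                chain_states[c, i_save] = np.exp(logB)
                chain_ll[c, i_save] = obs_ll
                i_save += 1
        if not np.isfinite(lp_theta):
            raise SPMFitError(f"chain {c} ended at a non-finite posterior")

    # --- assemble natural-scale draws
    k = model.k
    nat = {}
    th = chain_theta
    nat["r"] = np.exp(th[:, :, 0])
    nat["K"] = np.exp(th[:, :, 1])
    nat["psi"] = np.exp(th[:, :, 2])
    for i in range(k):
        nat[f"q_{i + 1}"] = np.exp(th[:, :, 3 + i])
    nat["proc_var"] = np.exp(th[:, :, 3 + k])
    for i in range(k):
        nat[f"add_obs_var_{i + 1}"] = np.exp(th[:, :, 4 + k + i])
    if model.estimate_m:
        nat["m"] = np.exp(th[:, :, 4 + 2 * k])

    states = chain_states.reshape(-1, model.T)
    loglik = chain_ll.reshape(-1)

    # --- diagnostics
    rh, dip_p = {}, {}
    rng_d = np.random.default_rng([seed % (2**31), 10_007])
    for name in ("r", "K", "psi") + (("m",) if model.estimate_m else ()):
        rh[name] = rhat(np.log(nat[name]))
        pooled = nat[name].reshape(-1)
        sub = pooled if pooled.size <= 1000 else rng_d.choice(pooled, 1000, replace=False)
        dip_p[name] = dip_test(sub, n_boot=101, seed=int(rng_d.integers(2**31)))

    mean_logB = np.mean(np.log(states), axis=0)
    mean_logq = np.array([np.mean(np.log(nat[f"q_{i + 1}"])) for i in range(k)])
    mean_av = np.array([np.mean(nat[f"add_obs_var_{i + 1}"]) for i in range(k)])
    plug_ll = 0.0
    for i in range(k):
        v = config.fixed_obs_var + mean_av[i]
        obs = np.isfinite(model.logI[i])
        resid = model.logI[i][obs] - mean_logq[i] - mean_logB[obs]
        plug_ll += np.sum(-0.5 * np.log(2 * np.pi * v) - 0.5 * resid**2 / v)
    dic = compute_dic(loglik, float(plug_ll))

    from .diagnostics import ppmr_ppvr

    ppmr, ppvr = {}, {}
    for name, prior in (("r", priors.r), ("K", priors.K), ("psi", priors.psi)):
        ppmr[name], ppvr[name] = ppmr_ppvr(prior, nat[name].reshape(-1))

    return PosteriorEnsemble(
        variant=config.variant,
        param_names=model.names,
        chain_draws=nat,
        states=states,
        loglik=loglik,
        years=model.years,
        dic=dic,
        rhat=rh,
        dip_p=dip_p,
        ppmr=ppmr,
        ppvr=ppvr,
        config=config,
    )
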