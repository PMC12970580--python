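"""MCMC and posterior diagnostics: R-hat, DIC, Hartigan's dip, PPMR/PPVR."""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["rhat", "compute_dic", "dip_statistic", "dip_test", "ppmr_ppvr"]


def rhat(chains) -> float:
    """Rank-normalized split R-hat for one parameter.

    Parameters
    ----------
    chains : array-like, shape (n_chains, n_draws)
        Draws for a single parameter; requires >= 2 chains and >= 4 draws.
        Convergence is conventionally declared below 1.05.
    """
    arr = np.atleast_2d(np.asarray(chains, dtype=float))
    if arr.shape[0] < 2:
        raise ValueError("rhat requires at least 2 chains")
    if arr.shape[1] < 4:
        raise ValueError("rhat requires at least 4 draws per chain")
    if np.allclose(arr, arr.flat[0]):
        return 1.0  # zero-variance guard: identical chains count as converged
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(arr, method="rank"))


def compute_dic(loglik_draws, loglik_at_posterior_mean: float) -> float:
    """Deviance Information Criterion, Spiegelhalter form.

    DIC = D_bar + pD with D = -2 loglik and pD = D_bar - D(theta_bar).
    """
    ll = np.asarray(loglik_draws, dtype=float)
    if ll.size < 2:
        raise ValueError("need at least 2 log-likelihood draws")
    d_bar = float(-2.0 * np.mean(ll))
    d_hat = float(-2.0 * loglik_at_posterior_mean)
    return d_bar + (d_bar - d_hat)


def ppmr_ppvr(prior, posterior_draws) -> tuple[float, float]:
    """Posterior-to-prior mean and variance ratios on the natural scale.

    ``prior`` is a :class:`~stockprod.priors.LognormalPrior`; its moments
    are available in closed form. Ratios near 1 indicate a prior-driven
    fit (the data did not update the prior).
    """
    draws = np.asarray(posterior_draws, dtype=float)
    if draws.size < 2:
        raise ValueError("need at least 2 posterior draws")
    return (
        float(np.mean(draws) / prior.mean),
        float(np.var(draws, ddof=1) / prior.variance),
    )


# ---------------------------------------------------------------------------
# Hartigan & Hartigan's dip statistic (AS 217 algorithm).
#
# The dip is the maximum difference between the empirical cdf and the
# closest unimodal cdf, and is computed by iteratively narrowing a candidate
# modal interval while tracking the greatest convex minorant (GCM) and least
# concave majorant (LCM) of the empirical cdf.  Distances are carried in
# count units (2*n*dip) and rescaled at the end.
# ---------------------------------------------------------------------------


def dip_statistic(samples) -> float:
    """Hartigan's dip statistic of a univariate sample."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2 or x[-1] == x[0]:
        return 0.0
    if n == 2:
        return 0.25

    low, high = 0, n - 1
    dip = 1.0  # minimal dip is 1/(2n) after rescaling
    mn = np.empty(n, dtype=np.int64)
    mj = np.empty(n, dtype=np.int64)

    while True:
        # GCM of the points (x_i, i) on [low, high]: mn[j] = previous vertex
        mn[low] = low
        for j in range(low + 1, high + 1):
            mn[j] = j - 1
            while True:
                mnj = mn[j]
                mnmnj = mn[mnj]
                if mnj == low or (
                    (x[j] - x[mnj]) * (mnj - mnmnj)
                    < (x[mnj] - x[mnmnj]) * (j - mnj)
                ):
                    break
                mn[j] = mnmnj
        # LCM: mj[k] = next vertex
        mj[high] = high
        for k in range(high - 1, low - 1, -1):
            mj[k] = k + 1
            while True:
                mjk = mj[k]
                mjmjk = mj[mjk]
                if mjk == high or (
                    (x[k] - x[mjk]) * (mjk - mjmjk)
                    < (x[mjk] - x[mjmjk]) * (k - mjk)
                ):
                    break
                mj[k] = mjmjk

        # gcm: vertex indices descending from high to low
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(int(mn[gcm[-1]]))
        l_gcm = len(gcm)
        # lcm: vertex indices ascending from low to high
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(int(mj[lcm[-1]]))
        l_lcm = len(lcm)
        gcm = [0] + gcm  # shift to 1-based to mirror the published algorithm
        lcm = [0] + lcm

        ig, ih = l_gcm, l_lcm
        ix, iv = l_gcm - 1, 2
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    # next vertex along the scan comes from the LCM
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig, ih = ix + 1, iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                        x[lcmiv] - x[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx > d:
                        d = dx
                        ig, ih = ix + 1, iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d < dip:
            break

        # largest deviation of the ecdf above the GCM within [gcm[ig]..high]
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb, je = gcm[j + 1], gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t
        # largest deviation of the ecdf below the LCM within [low..lcm[ih]]
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = max(dip_l, dip_u)
        if dip < dipnew:
            dip = dipnew
        if low == gcm[ig] and high == lcm[ih]:
            break
        low, high = gcm[ig], lcm[ih]

    return dip / (2.0 * n)


def dip_test(samples, n_boot: int = 200, seed: int = 0) -> float:
    """Monte-Carlo p-value of Hartigan's dip test of unimodality.

    The null distribution is calibrated on uniform samples of the same
    size (the asymptotically least-favourable unimodal case). A p-value
    above 0.05 is conventionally read as "no evidence against
    unimodality".
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 10:
        raise ValueError("dip test needs at least 10 samples")
    if np.all(x == x[0]):
        raise ValueError("constant sample: dip test undefined")
    d = dip_statistic(x)
    rng = np.random.default_rng(seed)
    boot = np.array(
        [dip_statistic(rng.uniform(size=x.size)) for _ in range(n_boot)]
    )
    return float((1.0 + np.sum(boot >= d)) / (n_boot + 1.0))
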