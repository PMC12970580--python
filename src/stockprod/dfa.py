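"""Dynamic factor analysis of multivariate productivity panels.

The model reduces an N-stock panel to one or two latent random-walk
trends::

    x_{i,t+1} = x_{i,t} + w_{i,t},   w_t ~ MVN(0, I)   (Q fixed identity)
    y_{j,t}   = sum_i Z_{j,i} x_{i,t} + e_{j,t},  e_t ~ MVN(0, R)

with Z upper-triangle constrained to zero for identifiability and three
candidate error structures for R: equal variances with no covariance
("diag-equal"), unequal variances with no covariance ("diag-unequal"),
and equal variances with equal covariances ("equalvar-equalcov").
Estimation is by an expectation/conditional-maximization (ECM) scheme
around a Kalman filter/smoother; model selection across the 2-trend x
3-structure grid uses the sample-size-corrected AICc with the number of
non-missing observations as the effective sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DFAModel",
    "R_STRUCTURES",
    "coverage_window",
    "kalman_loglik",
    "fit_dfa",
    "fit_dfa_grid",
    "aicc",
    "summarize_loadings",
]

R_STRUCTURES = ("diag-equal", "diag-unequal", "equalvar-equalcov")

_KAPPA = 5.0  # variance of the x_1 ~ N(0, kappa I) initial state


@dataclass
class DFAModel:
    """One fitted DFA candidate."""

    n_trends: int
    R_structure: str
    Z: np.ndarray  # (N, m) loadings
    Z_se: np.ndarray
    Z_ci: tuple  # (lower, upper) arrays, 95%
    x: np.ndarray  # (m, T) smoothed trends
    x_se: np.ndarray
    logLik: float
    AICc: float
    n_params: int
    n_eff: int
    converged: bool
    n_iter: int
    stock_ids: list
    years: np.ndarray
    ci_method: str = "hessian"


def aicc(logLik: float, k: int, n_eff: int) -> float:
    """Sample-size-corrected AIC: -2 logLik + 2k + 2k(k+1)/(n_eff - k - 1)."""
    if n_eff <= k + 1:
        raise ValueError(f"n_eff={n_eff} must exceed k+1={k + 1}")
    return -2.0 * logLik + 2.0 * k + 2.0 * k * (k + 1.0) / (n_eff - k - 1.0)


def coverage_window(panel: pd.DataFrame, threshold: float = 0.6) -> tuple:
    """Maximal contiguous year range with data coverage above ``threshold``.

    ``panel`` is stocks (rows) x years (columns); coverage per year is the
    fraction of stocks with a non-missing value.
    """
    if panel.size == 0:
        raise ValueError("empty panel")
    years = np.asarray(panel.columns)
    cov = panel.notna().sum(axis=0).to_numpy() / panel.shape[0]
    ok = cov > threshold
    if not ok.any():
        raise ValueError(f"no year exceeds coverage threshold {threshold}")
    best, cur, start = None, 0, 0
    for i, flag in enumerate(ok):
        if flag:
            if cur == 0:
                start = i
            cur += 1
            if best is None or cur > best[1]:
                best = (start, cur)
        else:
            cur = 0
    i0, length = best
    return years[i0], years[i0 + length - 1]


def _build_R(structure: str, params, N: int) -> np.ndarray:
    if structure == "diag-equal":
        return params[0] * np.eye(N)
    if structure == "diag-unequal":
        return np.diag(params)
    v, c = params
    return v * np.eye(N) + c * (np.ones((N, N)) - np.eye(N))


def _n_r_params(structure: str, N: int) -> int:
    return {"diag-equal": 1, "diag-unequal": N, "equalvar-equalcov": 2}[structure]


def kalman_loglik(y: np.ndarray, Z: np.ndarray, R: np.ndarray, smooth: bool = False):
    """Gaussian log-likelihood (and optionally smoothed states) of the DFA.

    ``y`` is (N, T) with NaN for missing; states follow an identity-
    transition random walk with Q = I and x_1 ~ N(0, kappa I).
    """
    N, T = y.shape
    m = Z.shape[1]
    a = np.zeros(m)
    P = _KAPPA * np.eye(m)
    ll = 0.0
    a_pred = np.empty((T, m))
    P_pred = np.empty((T, m, m))
    a_filt = np.empty((T, m))
    P_filt = np.empty((T, m, m))
    for t in range(T):
        if t > 0:
            a = a_filt[t - 1]
            P = P_filt[t - 1] + np.eye(m)
        a_pred[t], P_pred[t] = a, P
        o = np.isfinite(y[:, t])
        if o.any():
            Zo = Z[o]
            Ro = R[np.ix_(o, o)]
            F = Zo @ P @ Zo.T + Ro
            v = y[o, t] - Zo @ a
            try:
                cF = np.linalg.cholesky(F)
            except np.linalg.LinAlgError:
                return (-np.inf, None, None) if smooth else -np.inf
            sol = np.linalg.solve(cF, v)
            ll += -0.5 * (
                o.sum() * np.log(2 * np.pi)
                + 2.0 * np.sum(np.log(np.diag(cF)))
                + sol @ sol
            )
            K = P @ Zo.T @ np.linalg.inv(F)
            a = a + K @ v
            P = P - K @ Zo @ P
            P = 0.5 * (P + P.T)
        a_filt[t], P_filt[t] = a, P
    if not smooth:
        return float(ll)
    xs = np.empty((T, m))
    Vs = np.empty((T, m, m))
    xs[-1], Vs[-1] = a_filt[-1], P_filt[-1]
    for t in range(T - 2, -1, -1):
        J = P_filt[t] @ np.linalg.inv(P_pred[t + 1])
        xs[t] = a_filt[t] + J @ (xs[t + 1] - a_pred[t + 1])
        Vs[t] = P_filt[t] + J @ (Vs[t + 1] - P_pred[t + 1]) @ J.T
        Vs[t] = 0.5 * (Vs[t] + Vs[t].T)
    return float(ll), xs, Vs


def _free_entries(N: int, m: int):
    """Free (row, col) loading positions: Z_{j,i} = 0 for i > j."""
    return [(j, i) for j in range(N) for i in range(m) if i <= j]


def _m_step_Z(y, Z, Rinv_cache, R, xs, Vs, free):
    """Exact conditional maximization for the free loadings given R."""
    N, T = y.shape
    m = Z.shape[1]
    P = len(free)
    pos = {fe: p for p, fe in enumerate(free)}
    A = np.zeros((P, P))
    b = np.zeros(P)
    for t in range(T):
        o = np.isfinite(y[:, t])
        if not o.any():
            continue
        key = o.tobytes()
        if key not in Rinv_cache:
            Rinv_cache[key] = np.linalg.inv(R[np.ix_(o, o)])
        Ri = Rinv_cache[key]
        rows = np.flatnonzero(o)
        Exx = Vs[t] + np.outer(xs[t], xs[t])
        for aj, j in enumerate(rows):
            for ai, jp in enumerate(rows):
                w = Ri[aj, ai]
                if w == 0.0:
                    continue
                for i in range(min(j, m - 1) + 1):
                    pj = pos[(j, i)]
                    b[pj] += w * y[jp, t] * xs[t][i]
                    for ip in range(min(jp, m - 1) + 1):
                        A[pj, pos[(jp, ip)]] += w * Exx[i, ip]
    sol = np.linalg.solve(A + 1e-10 * np.eye(P), b)
    Z_new = np.zeros_like(Z)
    for (j, i), p in pos.items():
        Z_new[j, i] = sol[p]
    return Z_new


def _m_step_R(y, Z, xs, Vs, structure):
    """Structure-projected conditional maximization for R given Z."""
    N, T = y.shape
    S = np.zeros((N, N))
    cnt = np.zeros((N, N))
    for t in range(T):
        o = np.isfinite(y[:, t])
        if not o.any():
            continue
        rows = np.flatnonzero(o)
        resid = y[rows, t] - Z[rows] @ xs[t]
        E = np.outer(resid, resid) + Z[rows] @ Vs[t] @ Z[rows].T
        S[np.ix_(rows, rows)] += E
        cnt[np.ix_(rows, rows)] += 1.0
    if structure == "diag-equal":
        d = np.diag(S)
        return (float(np.sum(d) / np.sum(np.diag(cnt))),)
    if structure == "diag-unequal":
        return np.maximum(np.diag(S) / np.maximum(np.diag(cnt), 1.0), 1e-8)
    # equal variance, equal covariance: exact via the CS eigen-projection
    Sbar = S / np.maximum(cnt, 1.0)
    a = float(np.ones(N) @ Sbar @ np.ones(N)) / N
    bb = (np.trace(Sbar) - a) / (N - 1.0)
    a, bb = max(a, 1e-8), max(bb, 1e-8)
    v = (a + (N - 1.0) * bb) / N
    c = (a - bb) / N
    return (v, c)


def _params_to_R(structure, params, N):
    return _build_R(structure, np.atleast_1d(np.asarray(params, float)), N)


def fit_dfa(
    panel,
    n_trends: int,
    R_structure: str,
    max_em_iter: int = 300,
    tol: float = 1e-4,
    seed: int = 0,
    standardize: bool = True,
    compute_ci: bool = True,
) -> DFAModel:
    """Fit one DFA candidate by ECM and return loadings, trends and fit stats.

    ``panel``: DataFrame (stocks x years) or 2-d array; rows are
    standardized to zero mean / unit variance unless ``standardize`` is
    False. Non-convergence within ``max_em_iter`` returns the last
    iterate flagged ``converged=False``.
    """
    if n_trends not in (1, 2):
        raise ValueError("n_trends must be 1 or 2")
    if R_structure not in R_STRUCTURES:
        raise ValueError(f"R_structure must be one of {R_STRUCTURES}")
    if isinstance(panel, pd.DataFrame):
        stock_ids = list(panel.index)
        years = np.asarray(panel.columns)
        y = panel.to_numpy(dtype=float)
    else:
        y = np.asarray(panel, dtype=float)
        stock_ids = [f"stock_{j + 1}" for j in range(y.shape[0])]
        years = np.arange(y.shape[1])
    N, T = y.shape
    if standardize:
        mu = np.nanmean(y, axis=1, keepdims=True)
        sd = np.nanstd(y, axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        y = (y - mu) / sd
    m = n_trends
    free = _free_entries(N, m)

    # PCA initialization on the zero-filled panel
    y0 = np.nan_to_num(y)
    u, s, vt = np.linalg.svd(y0, full_matrices=False)
    Z = u[:, :m] * (s[:m] / np.sqrt(T))
    for j, i in ((j, i) for j in range(N) for i in range(m) if i > j):
        Z[j, i] = 0.0
    r_params = _m_step_R(y, Z, np.zeros((T, m)), np.tile(np.eye(m), (T, 1, 1)), R_structure)
    R = _params_to_R(R_structure, r_params, N)

    eff_tol = min(tol, 1e-5) if compute_ci else tol
    eff_max_iter = max(max_em_iter, 400) if compute_ci else max_em_iter

    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, eff_max_iter + 1):
        ll, xs, Vs = kalman_loglik(y, Z, R, smooth=True)
        if not np.isfinite(ll):
            break
        if ll - ll_prev < eff_tol and it > 2:
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
        cache: dict = {}
        Z = _m_step_Z(y, Z, cache, R, xs, Vs, free)
        r_params = _m_step_R(y, Z, xs, Vs, R_structure)
        R = _params_to_R(R_structure, r_params, N)

    if compute_ci:
        # land exactly on the MLE so the observed information is PD there
        Z, r_params, _ = _polish_mle(y, Z, r_params, R_structure, free)
        R = _params_to_R(R_structure, r_params, N)
    ll, xs, Vs = kalman_loglik(y, Z, R, smooth=True)
    n_eff = int(np.isfinite(y).sum())
    k = len(free) + _n_r_params(R_structure, N)

    # --- loading uncertainty from the observed information matrix
    se = np.full((N, m), np.nan)
    ci_method = "none"
    if compute_ci:
        se, ci_method = _loading_se(y, Z, r_params, R_structure, free, seed)
    lo = Z - 1.96 * se
    hi = Z + 1.96 * se

    # sign convention: each trend flipped so its significant loadings sum > 0
    for i in range(m):
        sig = (lo[:, i] > 0) | (hi[:, i] < 0)
        ref = Z[sig, i].sum() if sig.any() else Z[:, i].sum()
        if ref < 0:
            Z[:, i] *= -1
            xs[:, i] *= -1
            lo[:, i], hi[:, i] = -hi[:, i].copy(), -lo[:, i].copy()

    x_se = np.sqrt(np.maximum(np.array([np.diag(V) for V in Vs]), 0.0)).T
    return DFAModel(
        n_trends=m,
        R_structure=R_structure,
        Z=Z,
        Z_se=se,
        Z_ci=(lo, hi),
        x=xs.T,
        x_se=x_se,
        logLik=float(ll),
        AICc=aicc(float(ll), k, n_eff),
        n_params=k,
        n_eff=n_eff,
        converged=converged,
        n_iter=it,
        stock_ids=stock_ids,
        years=years,
        ci_method=ci_method,
    )


def _pack(Z, r_params, free):
    return np.concatenate([[Z[j, i] for j, i in free], np.log(np.atleast_1d(r_params))])


def _phi_to_model(phi, free, structure, N, m):
    """Unpack the flat parameter vector used for polishing and the Hessian.

    The compound-symmetry R is parametrized by its two (positive)
    eigenvalues so the search space is unconstrained.
    """
    Z = np.zeros((N, m))
    for p, (j, i) in enumerate(free):
        Z[j, i] = phi[p]
    rp = np.exp(phi[len(free):])
    if structure == "equalvar-equalcov":
        a, bb = rp
        v = (a + (N - 1) * bb) / N
        c = (a - bb) / N
        R = _build_R(structure, (v, c), N)
        r_params = (v, c)
    else:
        R = _build_R(structure, rp, N)
        r_params = tuple(rp)
    return Z, R, r_params


def _phi_from_model(Z, r_params, structure, free, N):
    if structure == "equalvar-equalcov":
        v, c = r_params
        a, bb = v + (N - 1) * c, v - c
        return np.concatenate(
            [[Z[j, i] for j, i in free], np.log([max(a, 1e-8), max(bb, 1e-8)])]
        )
    return _pack(Z, r_params, free)


def _polish_mle(y, Z, r_params, structure, free):
    """Quasi-Newton refinement of the EM solution on the marginal likelihood.

    EM creeps along the weakly identified common-scale direction of the
    loadings; a few BFGS steps land on the optimum so the observed
    information is positive definite there.
    """
    from scipy.optimize import minimize

    N, m = Z.shape

    def negll(phi):
        Zl, R, _ = _phi_to_model(phi, free, structure, N, m)
        val = -kalman_loglik(y, Zl, R)
        return val if np.isfinite(val) else 1e12

    phi0 = _phi_from_model(Z, r_params, structure, free, N)
    res = minimize(negll, phi0, method="L-BFGS-B",
                   options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-7})
    phi = res.x if res.fun <= negll(phi0) else phi0
    Z_new, _, r_new = _phi_to_model(phi, free, structure, N, m)
    return Z_new, r_new, -negll(phi)


def _loading_se(y, Z, r_params, structure, free, seed):
    """Standard errors for the free loadings via the observed information;
    parametric bootstrap fallback when the Hessian is ill-conditioned."""
    N, T = y.shape
    m = Z.shape[1]
    nr = len(np.atleast_1d(np.asarray(r_params, float)))

    def negll(phi):
        Zl = np.zeros((N, m))
        for p, (j, i) in enumerate(free):
            Zl[j, i] = phi[p]
        rp = np.exp(phi[len(free):])
        if structure == "equalvar-equalcov":
            # parametrize CS by its two positive eigenvalues (a, b)
            a, bb = rp
            v = (a + (N - 1) * bb) / N
            c = (a - bb) / N
            R = _build_R(structure, (v, c), N)
        else:
            R = _build_R(structure, rp, N)
        return -kalman_loglik(y, Zl, R)

    if structure == "equalvar-equalcov":
        v, c = r_params
        a, bb = v + (N - 1) * c, v - c
        phi0 = np.concatenate([[Z[j, i] for j, i in free], np.log([max(a, 1e-8), max(bb, 1e-8)])])
    else:
        phi0 = _pack(Z, r_params, free)
    p = phi0.size
    h = 1e-4 * np.maximum(1.0, np.abs(phi0))
    H = np.empty((p, p))
    f0 = negll(phi0)
    fp = np.empty(p)
    fmm = np.empty(p)
    for i in range(p):
        e = np.zeros(p); e[i] = h[i]
        fp[i] = negll(phi0 + e)
        fmm[i] = negll(phi0 - e)
        H[i, i] = (fp[i] - 2 * f0 + fmm[i]) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                negll(phi0 + ei + ej) - fp[i] - fp[j] + 2.0 * f0
                - fmm[i] - fmm[j] + negll(phi0 - ei - ej)
            ) / (2.0 * h[i] * h[j])
    se = np.full((N, m), np.nan)
    H = 0.5 * (H + H.T)
    evals = np.linalg.eigvalsh(H)
    if evals[0] > 1e-10 * max(evals[-1], 1.0):
        cov = np.linalg.inv(H)
        d = np.diag(cov)[: len(free)]
        if np.all(d > 0):
            for pidx, (j, i) in enumerate(free):
                se[j, i] = np.sqrt(d[pidx])
            return se, "hessian"
    # fallback: parametric bootstrap from the fitted model
    rng = np.random.default_rng(seed)
    R = _params_to_R(structure, r_params, N)
    cR = np.linalg.cholesky(R + 1e-10 * np.eye(N))
    boots = []
    for _ in range(24):
        x = np.cumsum(rng.standard_normal((T, m)), axis=0)
        x[0] += np.sqrt(_KAPPA) * rng.standard_normal(m)
        yb = (Z @ x.T) + cR @ rng.standard_normal((N, T))
        yb[~np.isfinite(y)] = np.nan
        fb = fit_dfa(yb, m, structure, max_em_iter=60, standardize=False,
                     compute_ci=False)
        Zb = fb.Z.copy()
        for i in range(m):  # undo the sign gauge before aggregating
            if Zb[:, i] @ Z[:, i] < 0:
                Zb[:, i] *= -1
        boots.append(Zb)
    se_b = np.std(np.array(boots), axis=0, ddof=1)
    return se_b, "bootstrap"


def fit_dfa_grid(panel, seed: int = 0, **kwargs) -> pd.DataFrame:
    """Fit the six-candidate grid (1-2 trends x 3 R structures).

    Returns a comparison table with one row per candidate (n_trends,
    R_structure, logLik, AICc, converged) and the fitted models in the
    ``model`` column, sorted by AICc.
    """
    rows = []
    for m in (1, 2):
        for structure in R_STRUCTURES:
            fit = fit_dfa(panel, m, structure, seed=seed, **kwargs)
            rows.append(
                {"n_trends": m, "R_structure": structure, "logLik": fit.logLik,
                 "AICc": fit.AICc, "converged": fit.converged, "model": fit}
            )
    return pd.DataFrame(rows).sort_values("AICc").reset_index(drop=True)


def summarize_loadings(model: DFAModel) -> dict:
    """Counts of significantly positive / negative loadings per trend."""
    lo, hi = model.Z_ci
    out = {}
    for i in range(model.n_trends):
        out[f"trend_{i + 1}"] = (
            int(np.sum(lo[:, i] > 0)),
            int(np.sum(hi[:, i] < 0)),
        )
    return out
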