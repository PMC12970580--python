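"""Driver attribution: Student-t GLMMs with species random effects.

Eight model structures relate stock productivity P to temperature (T),
chlorophyll (CHL) and mixed-layer depth (MLD), always with all three
fixed slopes and differing in the species-level random terms::

    1  none                          5  intercept + MLD slope
    2  intercept                     6  intercept + T and CHL slopes
    3  intercept + T slope           7  intercept + T and MLD slopes
    4  intercept + CHL slope         8  intercept + CHL and MLD slopes

Residuals are Student-t with an identity link; random effects are
independent zero-mean normals per term.  The marginal likelihood
integrates the species effects by a Laplace approximation (damped Newton
inner optimization, vectorized across species); the outer optimization
is Nelder-Mead on (beta, log random sds, log scale, log(nu - 2.01)).

Ensemble uncertainty follows the hindcast design: each productivity
candidate series is fitted separately and only the spread across members
forms the intervals — per-fit parameter uncertainty is intentionally not
propagated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

__all__ = [
    "STRUCTURES",
    "GLMMFit",
    "EnsembleGLMMResult",
    "critical_r",
    "collinearity_screen",
    "fit_glmm",
    "ensemble_fit",
]

DRIVERS = ("T", "CHL", "MLD")

#: Random-effect terms per structure id (the fixed part is always full).
STRUCTURES = {
    1: (),
    2: ("alpha",),
    3: ("alpha", "T"),
    4: ("alpha", "CHL"),
    5: ("alpha", "MLD"),
    6: ("alpha", "T", "CHL"),
    7: ("alpha", "T", "MLD"),
    8: ("alpha", "CHL", "MLD"),
}

_NU_FLOOR = 2.01


def critical_r(df: int, alpha: float) -> float:
    """Two-sided critical Pearson correlation at significance ``alpha``.

    r_crit = t_crit / sqrt(t_crit^2 + df) with t_crit the two-sided
    Student-t quantile at ``df`` degrees of freedom (n - 2 for n pairs).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t / math.sqrt(t * t + df))


def collinearity_screen(driver_panels, alphas=(0.05, 0.01)) -> tuple:
    """Pairwise Pearson correlations among drivers, per stock.

    Returns ``(table, summary)``: the per-stock correlation table
    (stock_id, pair, n, r) and a per-pair summary with the critical
    values at each alpha (df = n - 2) and counts of stocks whose |r|
    stays below them.
    """
    rows = []
    for panel in driver_panels:
        n = panel.years.size
        if n < 3:
            raise ValueError(f"stock {panel.stock_id}: window shorter than 3 years")
        for a, b in (("T", "CHL"), ("T", "MLD"), ("CHL", "MLD")):
            r = float(np.corrcoef(panel.driver(a), panel.driver(b))[0, 1])
            rows.append({"stock_id": panel.stock_id, "pair": f"{a}-{b}", "n": n, "r": r})
    table = pd.DataFrame(rows)
    summaries = []
    for pair, g in table.groupby("pair", sort=False):
        entry = {"pair": pair, "n_stocks": len(g),
                 "median_r": float(g["r"].median())}
        for alpha in alphas:
            crit = np.array([critical_r(n - 2, alpha) for n in g["n"]])
            entry[f"crit_{alpha}"] = float(np.mean(crit))
            entry[f"n_pass_{alpha}"] = int(np.sum(np.abs(g["r"].to_numpy()) < crit))
        summaries.append(entry)
    return table, pd.DataFrame(summaries)


@dataclass
class GLMMFit:
    """One fitted Student-t mixed model."""

    structure_id: int
    random_terms: tuple
    fixed: dict  # alpha, T, CHL, MLD
    random_sd: dict
    scale: float
    df: float
    logLik: float
    AIC: float
    BIC: float
    n_obs: int
    k_params: int
    converged: bool
    species_effects: pd.DataFrame  # conditional modes per species
    params_vector: np.ndarray = field(repr=False, default=None)

    def species_slope(self, species_id: str, driver: str) -> float:
        """Fixed slope plus the species' conditional deviation (if random)."""
        base = self.fixed[driver]
        if driver in self.random_terms:
            row = self.species_effects.set_index("species_id")
            base += float(row.loc[species_id, f"dev_{driver}"])
        return base


def _t_logpdf(u, scale, nu):
    return (
        gammaln((nu + 1.0) / 2.0)
        - gammaln(nu / 2.0)
        - 0.5 * np.log(nu * np.pi * scale * scale)
        - 0.5 * (nu + 1.0) * np.log1p(u * u / (nu * scale * scale))
    )


class _Inner:
    """Vectorized Laplace approximation over species random effects."""

    def __init__(self, y, X, Zmat, sp_idx, n_species):
        self.y = y
        self.X = X
        self.Z = Zmat  # (n, q) random-effect design
        self.sp = sp_idx
        self.S = n_species
        self.q = Zmat.shape[1] if Zmat is not None else 0
        if self.q:
            self.ZZ = Zmat[:, :, None] * Zmat[:, None, :]  # (n, q, q)
        self.b_cache = np.zeros((n_species, self.q)) if self.q else None

    def neg_marginal(self, beta, sig_u, scale, nu):
        y, X, Z, sp = self.y, self.X, self.Z, self.sp
        e = y - X @ beta
        if self.q == 0:
            return -float(np.sum(_t_logpdf(e, scale, nu)))
        q, S = self.q, self.S
        d_inv = 1.0 / np.maximum(sig_u, 1e-6) ** 2  # prior precision per term
        b = self.b_cache.copy()
        nu_s2 = nu * scale * scale

        def joint(bm):
            u = e - np.einsum("nq,nq->n", Z, bm[sp])
            ll = np.sum(_t_logpdf(u, scale, nu))
            pen = -0.5 * np.sum(bm * bm * d_inv[None, :]) - 0.5 * np.sum(
                np.log(2 * np.pi / d_inv)
            ) * S
            return ll + pen, u

        f_cur, u = joint(b)
        for _ in range(50):
            w = (nu + 1.0) * u / (nu_s2 + u * u)  # d logt / du
            c = (nu + 1.0) * (nu_s2 - u * u) / (nu_s2 + u * u) ** 2
            c_pos = np.where(c > 0, c, (nu + 1.0) / (nu_s2 + u * u))
            G = np.zeros((S, q))
            np.add.at(G, sp, w[:, None] * Z)
            G -= b * d_inv[None, :]
            H = np.zeros((S, q, q))
            np.add.at(H, sp, c_pos[:, None, None] * self.ZZ)
            H += np.diag(d_inv)[None, :, :]
            step = np.linalg.solve(H, G[:, :, None])[:, :, 0]
            if not np.all(np.isfinite(step)):
                break
            # global step halving on the joint objective
            lam = 1.0
            for _h in range(12):
                f_new, u_new = joint(b + lam * step)
                if f_new >= f_cur - 1e-12:
                    break
                lam *= 0.5
            b = b + lam * step
            improve = f_new - f_cur
            f_cur, u = f_new, u_new
            if abs(improve) < 1e-9 and np.max(np.abs(lam * step)) < 1e-7:
                break
        self.b_cache = b
        # observed-curvature Hessian at the mode for the Laplace determinant
        c = (nu + 1.0) * (nu_s2 - u * u) / (nu_s2 + u * u) ** 2
        H = np.zeros((S, q, q))
        np.add.at(H, sp, c[:, None, None] * self.ZZ)
        H += np.diag(d_inv)[None, :, :]
        sign, logdet = np.linalg.slogdet(H)
        if np.any(sign <= 0):  # non-PD at mode: fall back to clipped curvature
            c_pos = np.where(c > 0, c, (nu + 1.0) / (nu_s2 + u * u))
            H = np.zeros((S, q, q))
            np.add.at(H, sp, c_pos[:, None, None] * self.ZZ)
            H += np.diag(d_inv)[None, :, :]
            sign, logdet = np.linalg.slogdet(H)
        lap = f_cur + 0.5 * q * S * math.log(2 * math.pi) - 0.5 * float(np.sum(logdet))
        return -lap


def _prepare(panel: pd.DataFrame, random_terms, center_drivers: bool):
    df = panel.copy()
    if center_drivers:
        centers = df.groupby("stock_id")[list(DRIVERS)].transform("mean")
        for dname in DRIVERS:
            df[dname] = df[dname] - centers[dname]
    y = df["P"].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(df))] + [df[dname].to_numpy(dtype=float) for dname in DRIVERS]
    )
    codes, species = pd.factorize(df["species_id"], sort=True)
    cols = []
    for term in random_terms:
        cols.append(np.ones(len(df)) if term == "alpha"
                    else df[term].to_numpy(dtype=float))
    Zmat = np.column_stack(cols) if cols else None
    return df, y, X, Zmat, codes, list(species)


def fit_glmm(
    panel: pd.DataFrame,
    structure_id: int,
    fix_nu: float | None = None,
    center_drivers: bool = True,
    start: np.ndarray | None = None,
    maxiter: int = 4000,
    xatol: float = 1e-6,
    fatol: float = 1e-7,
) -> GLMMFit:
    """Fit one GLMM structure by maximum (Laplace) marginal likelihood.

    ``panel`` needs columns P, T, CHL, MLD, species_id, stock_id. Drivers
    are centred per stock by default (species intercepts absorb level
    differences).  ``start`` warm-starts the optimizer with a previous
    fit's ``params_vector``.
    """
    if structure_id not in STRUCTURES:
        raise ValueError(f"structure_id must be 1..8, got {structure_id}")
    random_terms = STRUCTURES[structure_id]
    if random_terms and panel["species_id"].nunique() < 2:
        raise ValueError("random-effect structures need >= 2 species")
    df, y, X, Zmat, codes, species = _prepare(panel, random_terms, center_drivers)
    S = len(species)
    inner = _Inner(y, X, Zmat, codes, S)
    q = len(random_terms)
    est_nu = fix_nu is None
    n_par = 4 + q + 1 + (1 if est_nu else 0)

    beta0, res0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid0 = y - X @ beta0
    s0 = max(float(np.std(resid0)), 1e-3)
    if start is not None and start.size == n_par:
        x0 = start.copy()
    else:
        x0 = np.concatenate(
            [beta0, np.log(np.full(q, 0.3 * s0 + 1e-4)), [math.log(s0)],
             [math.log(5.0 - _NU_FLOOR)] if est_nu else []]
        )

    def unpack(p):
        beta = p[:4]
        sig_u = np.exp(p[4 : 4 + q])
        scale = math.exp(p[4 + q])
        nu = _NU_FLOOR + math.exp(p[5 + q]) if est_nu else fix_nu
        return beta, sig_u, scale, nu

    def obj(p):
        beta, sig_u, scale, nu = unpack(p)
        if scale < 1e-8 or scale > 1e6 or (est_nu and nu > 1e7):
            return 1e12
        val = inner.neg_marginal(beta, sig_u, scale, nu)
        return val if np.isfinite(val) else 1e12

    res = optimize.minimize(
        obj, x0, method="Nelder-Mead",
        options={"maxiter": maxiter, "maxfev": maxiter,
                 "xatol": xatol, "fatol": fatol, "adaptive": True},
    )
    beta, sig_u, scale, nu = unpack(res.x)
    ll = -obj(res.x)  # refreshes the conditional modes at the optimum
    modes = inner.b_cache if q else np.zeros((S, 0))
    eff = pd.DataFrame({"species_id": species})
    for j, term in enumerate(random_terms):
        eff[f"dev_{term}"] = modes[:, j]
    n = y.size
    return GLMMFit(
        structure_id=structure_id,
        random_terms=random_terms,
        fixed={"alpha": float(beta[0]), "T": float(beta[1]),
               "CHL": float(beta[2]), "MLD": float(beta[3])},
        random_sd={t: float(s) for t, s in zip(random_terms, sig_u)},
        scale=float(scale),
        df=float(nu),
        logLik=float(ll),
        AIC=float(-2 * ll + 2 * n_par),
        BIC=float(-2 * ll + n_par * math.log(n)),
        n_obs=int(n),
        k_params=n_par,
        converged=bool(np.isfinite(ll)),
        species_effects=eff,
        params_vector=res.x.copy(),
    )


@dataclass
class EnsembleGLMMResult:
    """Member-wise fits of the eight structures plus aggregate summaries."""

    comparison: pd.DataFrame  # member, structure, logLik, AIC, BIC, dAIC, dBIC
    best_structure: int
    best_structure_bic: int
    effects: pd.DataFrame  # species x driver slope summaries over members
    fits: list  # best-structure GLMMFit per member
    centers: pd.DataFrame  # per-stock driver means used for centring
    n_failed: int


def _driver_window_panel(ensembles, drivers, species_map, member=None):
    rows = []
    for sid, ens in ensembles.items():
        panel = drivers[sid]
        common = np.intersect1d(ens.years, panel.years)
        if common.size == 0:
            continue
        iy = np.searchsorted(ens.years, common)
        ip = np.searchsorted(panel.years, common)
        P = ens.mean[iy] if member is None else ens.members[iy, member]
        rows.append(pd.DataFrame({
            "stock_id": sid, "species_id": species_map[sid], "year": common,
            "P": P, "T": panel.T[ip], "CHL": panel.CHL[ip], "MLD": panel.MLD[ip],
        }))
    if not rows:
        raise ValueError("no stock shares a window between ensemble and drivers")
    return pd.concat(rows, ignore_index=True)


def ensemble_fit(
    ensembles: dict,
    drivers: dict,
    species_map: dict,
    structures=tuple(range(1, 9)),
    n_members: int | None = None,
    fix_nu: float | None = None,
    seed: int = 0,
    max_failure_frac: float = 0.10,
) -> EnsembleGLMMResult:
    """Fit all GLMM structures to each productivity ensemble member.

    Per member, every structure is fitted and dAIC / dBIC to that
    member's best are recorded; the best overall structure minimizes the
    median dAIC.  Species slope summaries (mean, 66% and 95% intervals,
    significance) aggregate the best structure's species-conditional
    slopes across members.  Aborts if more than ``max_failure_frac`` of
    the member fits fail.
    """
    total_members = next(iter(ensembles.values())).n_members
    if n_members is None or n_members >= total_members:
        pick = np.arange(total_members)
    else:
        pick = np.random.default_rng(seed).choice(
            total_members, size=n_members, replace=False
        )
    warm: dict = {}
    records = []
    n_failed = 0
    fits_by_member: dict = {}
    for member in pick:
        panel = _driver_window_panel(ensembles, drivers, species_map, member=member)
        member_fits = {}
        bad = False
        for s in structures:
            try:
                fit = fit_glmm(panel, s, fix_nu=fix_nu, start=warm.get(s),
                               xatol=1e-5, fatol=1e-6)
            except Exception:
                bad = True
                break
            if not fit.converged:
                bad = True
                break
            warm[s] = fit.params_vector
            member_fits[s] = fit
        if bad:
            n_failed += 1
            continue
        best_aic = min(f.AIC for f in member_fits.values())
        best_bic = min(f.BIC for f in member_fits.values())
        for s, fit in member_fits.items():
            records.append({
                "member": int(member), "structure": s, "logLik": fit.logLik,
                "AIC": fit.AIC, "BIC": fit.BIC,
                "dAIC": fit.AIC - best_aic, "dBIC": fit.BIC - best_bic,
            })
        fits_by_member[int(member)] = member_fits
    if n_failed > max_failure_frac * len(pick):
        raise RuntimeError(
            f"{n_failed}/{len(pick)} ensemble members failed to fit"
        )
    comparison = pd.DataFrame(records)
    med = comparison.groupby("structure")[["dAIC", "dBIC"]].median()
    best_structure = int(med["dAIC"].idxmin())
    best_structure_bic = int(med["dBIC"].idxmin())

    fits = [mf[best_structure] for mf in fits_by_member.values()]
    species = sorted({species_map[s] for s in ensembles})
    eff_rows = []
    for sp in species:
        for drv in DRIVERS:
            slopes = np.array([f.species_slope(sp, drv) for f in fits])
            lo95, lo66, hi66, hi95 = np.percentile(slopes, [2.5, 17, 83, 97.5])
            eff_rows.append({
                "species_id": sp, "driver": drv, "mean": float(np.mean(slopes)),
                "lo66": lo66, "hi66": hi66, "lo95": lo95, "hi95": hi95,
                "significant": bool(lo95 > 0 or hi95 < 0),
            })
    full_panel = _driver_window_panel(ensembles, drivers, species_map)
    centers = full_panel.groupby("stock_id")[list(DRIVERS)].mean().reset_index()
    return EnsembleGLMMResult(
        comparison=comparison,
        best_structure=best_structure,
        best_structure_bic=best_structure_bic,
        effects=pd.DataFrame(eff_rows),
        fits=fits,
        centers=centers,
        n_failed=n_failed,
    )
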