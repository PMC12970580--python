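"""Synthetic fishery stocks, biophysical drivers and gridded fields.

Everything downstream of this module is exercised against data with a
known ground truth: stocks follow the same state-space biomass dynamics
the hindcast estimates, drivers are trending AR(1) series emulating
annual reanalysis extracts, and community productivity panels follow the
random-slope mixed model the attribution stage fits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spm import b_msy, surplus_production

__all__ = [
    "TrueStockParams",
    "StockRecord",
    "DriverPanel",
    "StockCollapseError",
    "simulate_stock",
    "simulate_driver_panel",
    "grid_area_mean",
    "simulate_community",
    "constant_harvest_rate",
    "constant_catch",
    "development_decline",
    "stocks_to_frame",
    "stocks_from_frame",
]

DRIVER_NAMES = ("T", "CHL", "MLD")
_POSITIVE_DRIVERS = ("CHL", "MLD")


class StockCollapseError(RuntimeError):
    """The catch policy drove the simulated biomass non-positive."""


@dataclass(frozen=True)
class TrueStockParams:
    """Ground-truth parameters of a simulated stock.

    r: intrinsic growth rate (1/yr); K: carrying capacity; m: production
    shape (2 = Schaefer); psi: initial depletion B_1/K; q: catchability
    per index; sigma_proc / sigma_obs: process and observation sd on the
    log scale.
    """

    r: float
    K: float
    m: float = 2.0
    psi: float = 1.0
    q: tuple = (1.0,)
    sigma_proc: float = 0.0
    sigma_obs: tuple = (0.0,)

    def __post_init__(self):
        if self.r <= 0 or self.K <= 0 or self.m <= 0:
            raise ValueError("require r > 0, K > 0, m > 0")
        if not (0 < self.psi <= 1):
            raise ValueError("require 0 < psi <= 1")
        if len(self.q) != len(self.sigma_obs):
            raise ValueError("q and sigma_obs must have one entry per index")
        if any(s < 0 for s in self.sigma_obs) or self.sigma_proc < 0:
            raise ValueError("standard deviations must be >= 0")

    @property
    def variant(self) -> str:
        if self.m == 2.0:
            return "Schaefer"
        return "PellaTomlinson"


@dataclass
class StockRecord:
    """One stock's observable history (plus simulator-only truth)."""

    stock_id: str
    species_id: str
    area_id: str
    years: np.ndarray
    catch: np.ndarray
    indices: np.ndarray  # (n_index, n_years), NaN = missing
    b_over_bmsy: np.ndarray | None = None
    resilience: str | None = None
    true_biomass: np.ndarray | None = None
    true_params: TrueStockParams | None = None

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.catch = np.asarray(self.catch, dtype=float)
        self.indices = np.atleast_2d(np.asarray(self.indices, dtype=float))
        if not np.all(np.diff(self.years) == 1):
            raise ValueError("years must be strictly increasing and contiguous")
        if np.any(self.catch[np.isfinite(self.catch)] < 0):
            raise ValueError("catch must be >= 0")
        if self.catch.size < 15:
            raise ValueError("catch series must span at least 15 years")

    @property
    def n_years(self) -> int:
        return self.years.size


@dataclass
class DriverPanel:
    """Annual biophysical drivers for one stock."""

    stock_id: str
    years: np.ndarray
    T: np.ndarray
    CHL: np.ndarray
    MLD: np.ndarray
    n_clipped: dict = field(default_factory=dict)

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        for name in _POSITIVE_DRIVERS:
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be strictly positive")

    def driver(self, name: str) -> np.ndarray:
        if name not in DRIVER_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stock_id": self.stock_id, "year": self.years,
             "T": self.T, "CHL": self.CHL, "MLD": self.MLD}
        )


# --- catch policies --------------------------------------------------------


def constant_harvest_rate(h: float):
    """C_t = h * B_t."""
    def policy(t, B):
        return h * B
    return policy


def constant_catch(c: float):
    def policy(t, B):
        return c
    return policy


def development_decline(peak_rate: float = 0.35, t_peak: int = 20, t_end: int = 40):
    """Fishery development then decline: harvest rate ramps linearly up to
    ``peak_rate`` at ``t_peak``, then back down to ``peak_rate``/4 by
    ``t_end`` — the hump-shaped exploitation history typical of assessed
    stocks."""
    def policy(t, B):
        if t <= t_peak:
            h = peak_rate * t / t_peak
        else:
            frac = min(1.0, (t - t_peak) / max(1, t_end - t_peak))
            h = peak_rate * (1.0 - 0.75 * frac)
        return h * B
    return policy


def simulate_stock(
    params: TrueStockParams,
    catch_policy,
    n_years: int,
    seed: int,
    stock_id: str = "S1",
    species_id: str = "sp1",
    area_id: str = "A1",
    start_year: int = 1981,
    resilience: str | None = None,
    with_bbmsy: bool = False,
) -> StockRecord:
    """Simulate one stock from the state-space production dynamics.

    B_1 = psi K; B_{t+1} = (B_t + SP_t - C_t) exp(eta_t); indices
    I_{i,t} = q_i B_t exp(eps_{i,t}).  Raises
    :class:`StockCollapseError` if the catch policy drives biomass
    non-positive.
    """
    if n_years < 15:
        raise ValueError("n_years must be >= 15")
    rng = np.random.default_rng(seed)
    B = np.empty(n_years)
    C = np.empty(n_years)
    B[0] = params.psi * params.K
    variant = "Schaefer" if params.m == 2.0 else "PellaTomlinson"
    for t in range(n_years):
        sp = float(surplus_production(B[t], params.r, params.K, params.m, variant))
        C[t] = float(catch_policy(t, B[t]))
        if C[t] < 0:
            raise ValueError("catch policy returned a negative catch")
        if t < n_years - 1:
            nxt = B[t] + sp - C[t]
            if nxt <= 0:
                raise StockCollapseError(
                    f"stock {stock_id}: collapse under catch policy at year {t}"
                )
            B[t + 1] = nxt * math.exp(params.sigma_proc * rng.standard_normal())
    k = len(params.q)
    indices = np.empty((k, n_years))
    for i in range(k):
        eps = params.sigma_obs[i] * rng.standard_normal(n_years)
        indices[i] = params.q[i] * B * np.exp(eps)
    bbmsy = None
    if with_bbmsy:
        bbmsy = B / b_msy(params.r, params.K, params.m, variant)
    return StockRecord(
        stock_id=stock_id,
        species_id=species_id,
        area_id=area_id,
        years=start_year + np.arange(n_years),
        catch=C,
        indices=indices,
        b_over_bmsy=bbmsy,
        resilience=resilience,
        true_biomass=B,
        true_params=params,
    )


def simulate_driver_panel(
    n_years: int,
    trend_per_year=None,
    ar1_coef: float = 0.5,
    noise_sd=None,
    baseline=None,
    seed: int = 0,
    stock_id: str = "S1",
    start_year: int = 1993,
) -> DriverPanel:
    """Trending AR(1) driver series (annual temperature, chlorophyll, MLD).

    Each driver is baseline + trend * (t - t0) + AR(1) noise (stationary
    initialization, innovation sd = ``noise_sd``). CHL and MLD are clipped
    at 1e-6 of their baseline; clip counts are recorded on the panel and
    reported with a warning.
    """
    defaults_baseline = {"T": 12.0, "CHL": 1.0, "MLD": 50.0}
    defaults_trend = {"T": 0.02, "CHL": -0.004, "MLD": 0.05}
    # interannual variability: ~2% (T in degC), ~20% CV (CHL), ~10% CV (MLD)
    defaults_noise = {"T": 0.25, "CHL": 0.2, "MLD": 5.0}
    baseline = {**defaults_baseline, **(baseline or {})}
    trend = {**defaults_trend, **(trend_per_year or {})}
    noise_sd = {**defaults_noise, **(noise_sd or {})}
    if not abs(ar1_coef) < 1:
        raise ValueError("|ar1_coef| must be < 1")
    for name in _POSITIVE_DRIVERS:
        if baseline[name] <= 0:
            raise ValueError(f"baseline for {name} must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(n_years)
    series, n_clipped = {}, {}
    for name in DRIVER_NAMES:
        sd = noise_sd[name]
        e = np.zeros(n_years)
        if sd > 0:
            e[0] = rng.normal(0.0, sd / math.sqrt(1.0 - ar1_coef**2))
            innov = rng.normal(0.0, sd, size=n_years)
            for i in range(1, n_years):
                e[i] = ar1_coef * e[i - 1] + innov[i]
        x = baseline[name] + trend[name] * t + e
        if name in _POSITIVE_DRIVERS:
            floor = 1e-6 * baseline[name]
            n_clipped[name] = int(np.sum(x < floor))
            x = np.maximum(x, floor)
        else:
            n_clipped[name] = 0
        series[name] = x
    if any(v > 0 for v in n_clipped.values()):
        warnings.warn(f"driver floor applied: {n_clipped}", stacklevel=2)
    return DriverPanel(
        stock_id=stock_id,
        years=start_year + t,
        T=series["T"],
        CHL=series["CHL"],
        MLD=series["MLD"],
        n_clipped=n_clipped,
    )


def grid_area_mean(field, polygon, depth_cut: float = 50.0) -> np.ndarray:
    """Polygon-mean of a gridded field after shallow-layer averaging.

    ``field`` is an xarray DataArray with dims (time, depth, lat, lon) or
    (time, lat, lon); depth layers at or deeper than ``depth_cut`` are
    excluded before an unweighted vertical mean. Cells whose centres fall
    inside ``polygon`` (a sequence of (lon, lat) vertices, even-odd rule)
    are averaged per time step; all-missing cells are excluded.
    """
    import xarray as xr
    from shapely.geometry import Point, Polygon

    if not isinstance(field, xr.DataArray):
        raise TypeError("field must be an xarray.DataArray")
    poly = Polygon(polygon)
    if len(polygon) < 3 or not poly.is_valid:
        raise ValueError("polygon needs >= 3 vertices and must be simple")
    if "depth" in field.dims:
        shallow = field.sel(depth=field["depth"] < depth_cut)
        if shallow.sizes["depth"] == 0:
            raise ValueError(f"no depth layer shallower than {depth_cut} m")
        field = shallow.mean("depth", skipna=True)
    lon = np.asarray(field["lon"])
    lat = np.asarray(field["lat"])
    inside = np.array(
        [[poly.contains(Point(x, y)) for x in lon] for y in lat], dtype=bool
    )
    if not inside.any():
        raise ValueError(
            f"polygon {list(poly.exterior.coords)[:-1]} encloses no grid-cell centre"
        )
    masked = field.where(xr.DataArray(inside, dims=("lat", "lon"),
                                      coords={"lat": lat, "lon": lon}))
    return masked.mean(("lat", "lon"), skipna=True).values


def simulate_community(
    n_species: int,
    stocks_per_species: int,
    fixed_betas: dict,
    random_slope_sds: dict | None,
    resid_scale: float,
    resid_df: float,
    driver_panels: list | None = None,
    seed: int = 0,
    n_years: int = 28,
) -> tuple[pd.DataFrame, dict]:
    """Community productivity panel from the random-slope mixed model.

    P = alpha + beta_T T + beta_CHL CHL + beta_MLD MLD
        + a_s + b_{T,s} T + b_{CHL,s} CHL (+ b_{MLD,s} MLD)
        + Student-t(resid_df, scale) noise,

    with species deviations a_s, b_{d,s} ~ N(0, sd^2). Returns the long
    panel (stock_id, species_id, year, P, T, CHL, MLD) and a truth table
    with the fixed effects and every species deviation.
    """
    if n_species < 2:
        raise ValueError("need >= 2 species")
    if resid_df <= 2:
        raise ValueError("resid_df must exceed 2 (finite variance)")
    random_slope_sds = dict(random_slope_sds or {})
    if any(sd > 0 for sd in random_slope_sds.values()) and stocks_per_species < 1:
        raise ValueError("random effects require at least one stock per species")
    rng = np.random.default_rng(seed)
    n_stocks = n_species * stocks_per_species
    if driver_panels is None:
        driver_panels = [
            simulate_driver_panel(n_years, seed=int(rng.integers(2**31)),
                                  stock_id=f"S{j + 1}")
            for j in range(n_stocks)
        ]
    if len(driver_panels) != n_stocks:
        raise ValueError("need one driver panel per stock")

    dev_names = ("alpha",) + DRIVER_NAMES
    devs = {
        name: rng.normal(0.0, random_slope_sds.get(name, 0.0), size=n_species)
        for name in dev_names
    }
    rows = []
    for j, panel in enumerate(driver_panels):
        s = j % n_species
        lin = np.full(panel.years.size, fixed_betas.get("alpha", 0.0) + devs["alpha"][s])
        for name in DRIVER_NAMES:
            lin = lin + (fixed_betas.get(name, 0.0) + devs[name][s]) * panel.driver(name)
        if resid_scale > 0:
            lin = lin + resid_scale * rng.standard_t(resid_df, size=lin.size)
        rows.append(
            pd.DataFrame(
                {"stock_id": panel.stock_id, "species_id": f"sp{s + 1}",
                 "year": panel.years, "P": lin, "T": panel.T,
                 "CHL": panel.CHL, "MLD": panel.MLD}
            )
        )
    truth = {
        "fixed_betas": dict(fixed_betas),
        "random_slope_sds": dict(random_slope_sds),
        "species_deviations": pd.DataFrame(
            {"species_id": [f"sp{s + 1}" for s in range(n_species)],
             **{f"dev_{n}": devs[n] for n in dev_names}}
        ),
        "resid_scale": resid_scale,
        "resid_df": resid_df,
    }
    return pd.concat(rows, ignore_index=True), truth


# --- tabular I/O -----------------------------------------------------------


def stocks_to_frame(records: list) -> pd.DataFrame:
    """Long-format stock table (one row per stock-year)."""
    frames = []
    for rec in records:
        df = pd.DataFrame(
            {"stock_id": rec.stock_id, "species_id": rec.species_id,
             "area_id": rec.area_id, "year": rec.years, "catch": rec.catch}
        )
        for i in range(rec.indices.shape[0]):
            df[f"index_{i + 1}"] = rec.indices[i]
        df["b_over_bmsy"] = rec.b_over_bmsy if rec.b_over_bmsy is not None else np.nan
        df["resilience"] = rec.resilience
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def stocks_from_frame(df: pd.DataFrame) -> list:
    """Inverse of :func:`stocks_to_frame` (truth columns are not restored)."""
    records = []
    idx_cols = sorted(c for c in df.columns if c.startswith("index_"))
    for sid, g in df.groupby("stock_id", sort=True):
        g = g.sort_values("year")
        bb = g["b_over_bmsy"].to_numpy(dtype=float)
        res = g["resilience"].iloc[0]
        records.append(
            StockRecord(
                stock_id=str(sid),
                species_id=str(g["species_id"].iloc[0]),
                area_id=str(g["area_id"].iloc[0]),
                years=g["year"].to_numpy(),
                catch=g["catch"].to_numpy(dtype=float),
                indices=np.vstack([g[c].to_numpy(dtype=float) for c in idx_cols]),
                b_over_bmsy=None if np.all(np.isnan(bb)) else bb,
                resilience=None if pd.isna(res) else str(res),
            )
        )
    return records
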