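"""End-to-end pipeline: fleet -> priors -> hindcast -> trends -> DFA ->
GLMM -> forecast, with file-backed stage caching and provenance.

Each stage persists its outputs (CSV for tables, NetCDF for arrays)
under the configured output directory together with a sidecar recording
the configuration hash and seed; a stage re-runs only when its outputs
are missing, its sidecar is stale, or an upstream stage re-ran.

Stocks, drivers and forcing are synthetic with known ground truth; the
pipeline exists to exercise the full analysis chain at desk scale, not
to mimic any real database's schema.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dfa as dfa_mod
from . import forecast as fc
from . import glmm as glmm_mod
from . import priors as pr
from . import productivity as prod
from . import spm as spm_mod
from . import synthetic as syn

__all__ = ["PipelineConfig", "select_stocks", "run_pipeline", "run_community_experiment"]


@dataclass
class PipelineConfig:
    """Settings for a full desk-scale pipeline run."""

    out_dir: str
    seed: int = 0
    # synthetic fleet
    n_species: int = 8
    stocks_per_species: int = 2
    n_stock_years: int = 42
    stock_start_year: int = 1981
    # analysis windows
    hindcast_trend_window: tuple = (1981, 2022)
    driver_window: tuple = (1993, 2020)
    forecast_window: tuple = (2021, 2100)
    # SPM / ensemble
    spm_n_iter: int = 20_000
    spm_n_burnin: int = 10_000
    spm_thin: int = 5
    spm_variant: str = "Schaefer"
    n_ensemble_members: int = 1000
    # GLMM
    n_glmm_members: int = 10
    glmm_structures: tuple = tuple(range(1, 9))
    glmm_fix_nu: float | None = 8.0
    # forecast scenarios: name -> warming (degC) by 2100
    scenarios: tuple = (("ssp-mild", 1.5), ("ssp-strong", 4.5))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def select_stocks(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the stock-selection criteria to a long stock table.

    Criteria: (1) a catch series and at least one abundance index;
    (2) catch spanning >= 15 years; (3) species-level identification;
    (4) marine realm (column ``marine`` if present, else assumed).
    Returns (kept table, exclusion report with one reason per stock).
    """
    idx_cols = [c for c in table.columns if c.startswith("index_")]
    kept, excluded = [], []
    for sid, g in table.groupby("stock_id", sort=True):
        try:
            n_catch = int(g["catch"].notna().sum())
            has_index = any(g[c].notna().any() for c in idx_cols)
        except KeyError as e:
            excluded.append({"stock_id": sid, "reason": f"malformed rows: {e}"})
            continue
        species = g["species_id"].iloc[0] if "species_id" in g else None
        if n_catch == 0 or not has_index:
            reason = "no catch series" if n_catch == 0 else "no abundance index"
        elif n_catch < 15:
            reason = "catch span < 15"
        elif species is None or pd.isna(species) or str(species).strip() == "" \
                or str(species).lower().endswith("spp."):
            reason = "not identified to species level"
        elif "marine" in g and not bool(g["marine"].iloc[0]):
            reason = "not marine"
        else:
            kept.append(g)
            continue
        excluded.append({"stock_id": sid, "reason": reason})
    kept_df = pd.concat(kept, ignore_index=True) if kept else table.iloc[0:0]
    return kept_df, pd.DataFrame(excluded, columns=["stock_id", "reason"])


# --- synthetic fleet -------------------------------------------------------

_RESILIENCES = ("Medium", "High", "Low")


def _make_fleet(cfg: PipelineConfig):
    """Simulated stocks plus matching driver panels with stored truth."""
    rng = np.random.default_rng([cfg.seed, 1])
    records, truths, drivers = [], [], {}
    n_total = cfg.n_species * cfg.stocks_per_species
    for s in range(cfg.n_species):
        resilience = _RESILIENCES[s % len(_RESILIENCES)]
        lo, hi = pr.R_PRIOR_LIMITS[resilience]
        r_sp = float(np.exp(rng.uniform(np.log(lo * 1.3), np.log(hi / 1.3))))
        for j in range(cfg.stocks_per_species):
            stock_id = f"S{s * cfg.stocks_per_species + j + 1:03d}"
            K = float(rng.uniform(500, 5000))
            params = syn.TrueStockParams(
                r=r_sp, K=K, psi=float(rng.uniform(0.7, 1.0)),
                q=(float(rng.uniform(0.001, 0.01)),),
                sigma_proc=0.05, sigma_obs=(0.15,),
            )
            policy = syn.development_decline(
                peak_rate=min(0.6 * r_sp, 0.35),
                t_peak=int(rng.integers(10, 20)), t_end=cfg.n_stock_years,
            )
            for attempt in range(20):
                try:
                    rec = syn.simulate_stock(
                        params, policy, cfg.n_stock_years,
                        seed=int(rng.integers(2**31)), stock_id=stock_id,
                        species_id=f"sp{s + 1}", area_id=f"A{(s % 2) + 1}",
                        start_year=cfg.stock_start_year, resilience=resilience,
                        with_bbmsy=(j % 2 == 0),
                    )
                    break
                except syn.StockCollapseError:
                    if attempt == 19:
                        raise
            records.append(rec)
            truths.append({"stock_id": stock_id, "r": params.r, "K": params.K,
                           "psi": params.psi, "q_1": params.q[0]})
            drivers[stock_id] = syn.simulate_driver_panel(
                cfg.driver_window[1] - cfg.driver_window[0] + 1,
                seed=int(rng.integers(2**31)), stock_id=stock_id,
                start_year=cfg.driver_window[0],
            )
    assert len(records) == n_total
    return records, pd.DataFrame(truths), drivers


class _Stage:
    """Sequential stage runner with sidecar-based caching."""

    def __init__(self, out: Path, conf_hash: str):
        self.out = out
        self.hash = conf_hash
        self.dirty = False
        self.log: dict = {}

    def run(self, name: str, outputs: list[str], compute, load):
        paths = [self.out / f for f in outputs]
        sidecar = self.out / f"{name}.meta.json"
        fresh = (
            not self.dirty
            and all(p.exists() for p in paths)
            and sidecar.exists()
            and json.loads(sidecar.read_text()).get("config_hash") == self.hash
        )
        if fresh:
            self.log[name] = "cached"
            return load()
        result = compute()
        sidecar.write_text(json.dumps({"config_hash": self.hash, "stage": name}))
        self.dirty = True
        self.log[name] = "computed"
        return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Run (or resume) the full pipeline; returns the report bundle."""
    import xarray as xr

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = _Stage(out, config.config_hash())
    cfg = config

    # ----- fleet
    def _fleet_compute():
        records, truth, drivers = _make_fleet(cfg)
        syn.stocks_to_frame(records).to_csv(out / "stocks.csv", index=False)
        truth.to_csv(out / "truth.csv", index=False)
        pd.concat([p.to_frame() for p in drivers.values()]).to_csv(
            out / "drivers.csv", index=False
        )
        return records, truth, drivers

    def _fleet_load():
        records = syn.stocks_from_frame(pd.read_csv(out / "stocks.csv"))
        truth = pd.read_csv(out / "truth.csv")
        ddf = pd.read_csv(out / "drivers.csv")
        drivers = {
            sid: syn.DriverPanel(sid, g["year"].to_numpy(), g["T"].to_numpy(),
                                 g["CHL"].to_numpy(), g["MLD"].to_numpy())
            for sid, g in ddf.groupby("stock_id")
        }
        return records, truth, drivers

    records, truth, drivers = stages.run(
        "fleet", ["stocks.csv", "truth.csv", "drivers.csv"],
        _fleet_compute, _fleet_load,
    )
    table, exclusions = select_stocks(syn.stocks_to_frame(records))
    keep_ids = set(table["stock_id"])
    records = [r for r in records if r.stock_id in keep_ids]
    by_id = {r.stock_id: r for r in records}
    species_map = {r.stock_id: r.species_id for r in records}
    area_map = {r.stock_id: r.area_id for r in records}

    # ----- priors
    def _priors_compute():
        rows = []
        for rec in records:
            rprior = pr.r_prior_from_resilience(rec.resilience)
            level = pr.biomass_level_end(rec)
            kprior = pr.k_prior(rec.catch, rprior, level)
            cat = pr.qualitative_stock_size(rec)
            psiprior = pr.psi_prior(cat)
            for pname, prior, method in (
                ("r", rprior, rec.resilience), ("K", kprior, level),
                ("psi", psiprior, f"{cat.label}/{cat.method}"),
            ):
                rows.append({"stock_id": rec.stock_id, "parameter": pname,
                             "lower": prior.lower, "upper": prior.upper,
                             "log_mean": prior.log_mean, "log_sd": prior.log_sd,
                             "method": method})
        df = pd.DataFrame(rows)
        df.to_csv(out / "priors.csv", index=False)
        return df

    priors_df = stages.run(
        "priors", ["priors.csv"], _priors_compute,
        lambda: pd.read_csv(out / "priors.csv"),
    )

    def _prior_set(sid):
        g = priors_df[priors_df["stock_id"] == sid].set_index("parameter")
        return spm_mod.SPMPriors(
            r=pr.LognormalPrior(g.loc["r", "lower"], g.loc["r", "upper"]),
            K=pr.LognormalPrior(g.loc["K", "lower"], g.loc["K", "upper"]),
            psi=pr.LognormalPrior(g.loc["psi", "lower"], g.loc["psi", "upper"]),
        )

    # ----- hindcast + productivity ensembles
    spm_cfg = spm_mod.SPMConfig(
        variant=cfg.spm_variant, n_iter=cfg.spm_n_iter,
        n_burnin=cfg.spm_n_burnin, thin=cfg.spm_thin,
    )

    def _hindcast_compute():
        diag_rows, ens = [], {}
        n_members = min(cfg.n_ensemble_members, spm_cfg.n_saved)
        for i, rec in enumerate(records):
            try:
                post = spm_mod.fit_spm(
                    rec, _prior_set(rec.stock_id), spm_cfg,
                    seed=(cfg.seed * 1000003 + i) % 2**31,
                )
            except spm_mod.SPMFitError as e:
                warnings.warn(f"{rec.stock_id}: fit failed ({e}); excluded")
                diag_rows.append({"stock_id": rec.stock_id, "fitted": False})
                continue
            post.stock_id = rec.stock_id
            ens[rec.stock_id] = prod.build_ensemble(
                post, rec.catch, n_members, seed=(cfg.seed * 7919 + i) % 2**31
            )
            diag_rows.append({
                "stock_id": rec.stock_id, "fitted": True, "dic": post.dic,
                **{f"rhat_{k}": v for k, v in post.rhat.items()},
                **{f"dip_p_{k}": v for k, v in post.dip_p.items()},
                **{f"ppvr_{k}": v for k, v in post.ppvr.items()},
            })
        diag = pd.DataFrame(diag_rows)
        diag.to_csv(out / "spm_diag.csv", index=False)
        ds = xr.Dataset(
            {sid: (("year", "member"), e.members) for sid, e in ens.items()},
            coords={"member": np.arange(n_members)},
        )
        for sid, e in ens.items():
            ds[sid].attrs["years"] = e.years.tolist()
        ds.to_netcdf(out / "ensembles.nc")
        return diag, ens

    def _hindcast_load():
        diag = pd.read_csv(out / "spm_diag.csv")
        ds = xr.open_dataset(out / "ensembles.nc")
        ens = {}
        for sid in ds.data_vars:
            members = ds[sid].values
            mean = members.mean(axis=1)
            lo, hi = np.percentile(members, [2.5, 97.5], axis=1)
            ens[str(sid)] = prod.ProductivityEnsemble(
                stock_id=str(sid), years=np.array(ds[sid].attrs["years"]),
                members=members, mean=mean,
                ci_lower=np.minimum(lo, mean), ci_upper=np.maximum(hi, mean),
            )
        ds.close()
        return diag, ens

    spm_diag, ensembles = stages.run(
        "hindcast", ["spm_diag.csv", "ensembles.nc"],
        _hindcast_compute, _hindcast_load,
    )

    # ----- linear trend classification
    def _trends_compute():
        rows = []
        for sid, e in ensembles.items():
            tc = prod.classify_linear_trend(e.mean, e.years,
                                            window=cfg.hindcast_trend_window)
            rows.append({"stock_id": sid, "slope": tc.slope, "lo": tc.ci[0],
                         "hi": tc.ci[1], "label": tc.label})
        df = pd.DataFrame(rows)
        df.to_csv(out / "trends.csv", index=False)
        return df

    trends = stages.run(
        "trends", ["trends.csv"], _trends_compute,
        lambda: pd.read_csv(out / "trends.csv"),
    )

    # ----- DFA per area
    def _dfa_compute():
        rows = []
        for area in sorted(set(area_map.values())):
            sids = [s for s, a in area_map.items() if a in (area,) and s in ensembles]
            if len(sids) < 3:
                continue
            years = sorted(set().union(*(ensembles[s].years.tolist() for s in sids)))
            panel = pd.DataFrame(index=sids, columns=years, dtype=float)
            for s in sids:
                panel.loc[s, ensembles[s].years] = ensembles[s].mean
            try:
                w0, w1 = dfa_mod.coverage_window(panel)
            except ValueError:
                continue
            panel = panel.loc[:, (panel.columns >= w0) & (panel.columns <= w1)]
            grid = dfa_mod.fit_dfa_grid(panel, seed=cfg.seed, max_em_iter=150,
                                        compute_ci=False)
            for pos, (_, g) in enumerate(grid.iterrows()):
                rows.append({"area": area, "n_trends": g["n_trends"],
                             "R_structure": g["R_structure"],
                             "logLik": g["logLik"], "AICc": g["AICc"],
                             "best": pos == 0, "window": f"{w0}-{w1}"})
        df = pd.DataFrame(rows)
        df.to_csv(out / "dfa_models.csv", index=False)
        return df

    dfa_models = stages.run(
        "dfa", ["dfa_models.csv"], _dfa_compute,
        lambda: pd.read_csv(out / "dfa_models.csv"),
    )

    # ----- GLMM ensemble fit
    def _glmm_compute():
        res = glmm_mod.ensemble_fit(
            ensembles, drivers, species_map, structures=cfg.glmm_structures,
            n_members=cfg.n_glmm_members, fix_nu=cfg.glmm_fix_nu, seed=cfg.seed,
        )
        res.comparison.to_csv(out / "glmm_comparison.csv", index=False)
        res.effects.to_csv(out / "glmm_effects.csv", index=False)
        res.centers.to_csv(out / "glmm_centers.csv", index=False)
        coef_rows = []
        for mi, fit in enumerate(res.fits):
            eff = fit.species_effects.set_index("species_id")
            for sp in fit.species_effects["species_id"]:
                dev_a = (float(eff.loc[sp, "dev_alpha"])
                         if "alpha" in fit.random_terms else 0.0)
                row = {"member": mi, "species_id": sp,
                       "structure": fit.structure_id,
                       "alpha": fit.fixed["alpha"] + dev_a}
                for d in glmm_mod.DRIVERS:
                    row[d] = fit.species_slope(sp, d)
                coef_rows.append(row)
        coefs = pd.DataFrame(coef_rows)
        coefs.to_csv(out / "glmm_member_coefs.csv", index=False)
        return res.comparison, res.effects, res.centers, coefs

    glmm_comp, glmm_effects, glmm_centers, glmm_coefs = stages.run(
        "glmm",
        ["glmm_comparison.csv", "glmm_effects.csv", "glmm_centers.csv",
         "glmm_member_coefs.csv"],
        _glmm_compute,
        lambda: (pd.read_csv(out / "glmm_comparison.csv"),
                 pd.read_csv(out / "glmm_effects.csv"),
                 pd.read_csv(out / "glmm_centers.csv"),
                 pd.read_csv(out / "glmm_member_coefs.csv")),
    )

    # ----- forecast
    def _forecast_compute():
        member_fits = _coef_fits(glmm_coefs)
        wl_frames, dec_rows, reg_rows = [], [], []
        for name, warming in cfg.scenarios:
            forcing = fc.make_scenario_forcing(
                drivers, name, warming_by_2100=warming, seed=cfg.seed
            )
            projections, changes = {}, {}
            for sid in ensembles:
                try:
                    proj = fc.project_stock(member_fits, forcing, sid,
                                            species_map[sid], glmm_centers)
                except KeyError:
                    warnings.warn(f"{sid}: species missing from fits; excluded")
                    continue
                projections[sid] = proj
                ch = fc.decade_change(proj)
                changes[sid] = ch
                dec_rows.append({
                    "stock_id": sid, "scenario": name, "change": ch.change,
                    "lo": ch.change_ci[0], "hi": ch.change_ci[1],
                    "percent": ch.percent,
                    "direction": fc.directional_effect(proj.mean, proj.years),
                })
            wl = fc.classify_winners_losers(changes)
            wl["scenario"] = name
            wl_frames.append(wl)
            regional = fc.aggregate_regional(projections, area_map)
            for area, agg in regional.items():
                gl = fc.decade_change(fc.ProjectionEnsemble(
                    stock_id=area, scenario_id=name, years=agg["years"],
                    members=agg["members"], mean=agg["mean"],
                    ci_lower=agg["ci_lower"], ci_upper=agg["ci_upper"],
                ))
                reg_rows.append({
                    "area": area, "scenario": name, "n_stocks": agg["n_stocks"],
                    "change": gl.change, "lo": gl.change_ci[0],
                    "hi": gl.change_ci[1], "percent": gl.percent,
                    "percent_lo": gl.percent_ci[0], "percent_hi": gl.percent_ci[1],
                })
        wl_df = pd.concat(wl_frames, ignore_index=True)
        dec_df = pd.DataFrame(dec_rows)
        reg_df = pd.DataFrame(reg_rows)
        wl_df.to_csv(out / "winners_losers.csv", index=False)
        dec_df.to_csv(out / "decade_changes.csv", index=False)
        reg_df.to_csv(out / "regional.csv", index=False)
        return wl_df, dec_df, reg_df

    winners_losers, decade_changes, regional = stages.run(
        "forecast",
        ["winners_losers.csv", "decade_changes.csv", "regional.csv"],
        _forecast_compute,
        lambda: (pd.read_csv(out / "winners_losers.csv"),
                 pd.read_csv(out / "decade_changes.csv"),
                 pd.read_csv(out / "regional.csv")),
    )

    report = {
        "config_hash": config.config_hash(),
        "seed": cfg.seed,
        "stage_log": stages.log,
        "n_stocks": len(records),
        "exclusions": exclusions,
        "priors": priors_df,
        "spm_diagnostics": spm_diag,
        "trends": trends,
        "dfa_models": dfa_models,
        "glmm_comparison": glmm_comp,
        "glmm_effects": glmm_effects,
        "winners_losers": winners_losers,
        "decade_changes": decade_changes,
        "regional": regional,
    }
    (out / "report.meta.json").write_text(json.dumps(
        {"config_hash": config.config_hash(), "seed": cfg.seed,
         "stages": stages.log}, indent=2))
    return report


class _CoefFit:
    """Minimal fit-like shim for projection from persisted member coefficients."""

    random_terms = ("alpha", "T", "CHL", "MLD")

    def __init__(self, g: pd.DataFrame):
        self.fixed = {"alpha": 0.0, "T": 0.0, "CHL": 0.0, "MLD": 0.0}
        self.species_effects = pd.DataFrame({
            "species_id": g["species_id"],
            **{f"dev_{c}": g[c].to_numpy() for c in ("alpha", "T", "CHL", "MLD")},
        })


def _coef_fits(coefs: pd.DataFrame) -> list:
    return [_CoefFit(g) for _, g in coefs.groupby("member", sort=True)]


def run_community_experiment(
    seed: int = 0,
    n_species: int = 20,
    stocks_per_species: int = 2,
    fixed_betas: dict | None = None,
    random_slope_sds: dict | None = None,
    resid_scale: float = 0.02,
    resid_df: float = 8.0,
    n_members: int = 10,
    structures: tuple = (6,),
    fix_nu: float = 8.0,
    scenarios: tuple = (("ssp-mild", 1.5), ("ssp-strong", 4.5)),
    n_years: int = 28,
) -> dict:
    """Generator-level forecast experiment on a known-truth community.

    Builds a community panel whose species driver responses are drawn
    around near-symmetric means, forms a pseudo-ensemble by re-drawing
    the Student-t residuals per member (emulating hindcast spread), fits
    the mixed-model ensemble, projects each scenario and classifies
    winners and losers.  Returns per-scenario counts and the global
    decade change.
    """
    fixed_betas = fixed_betas or {"alpha": 0.15, "T": -0.002, "CHL": 0.03,
                                  "MLD": -0.0005}
    random_slope_sds = random_slope_sds or {"alpha": 0.03, "T": 0.02, "CHL": 0.02}
    rng = np.random.default_rng([seed, 77])
    n_stocks = n_species * stocks_per_species
    panels = [
        syn.simulate_driver_panel(n_years, seed=int(rng.integers(2**31)),
                                  stock_id=f"S{j + 1:03d}")
        for j in range(n_stocks)
    ]
    clean, truth = syn.simulate_community(
        n_species, stocks_per_species, fixed_betas, random_slope_sds,
        resid_scale=0.0, resid_df=resid_df, driver_panels=panels,
        seed=int(rng.integers(2**31)),
    )
    drivers = {p.stock_id: p for p in panels}
    species_map = dict(zip(clean["stock_id"], clean["species_id"]))
    ensembles = {}
    for sid, g in clean.groupby("stock_id"):
        base = g["P"].to_numpy()
        noise = resid_scale * rng.standard_t(resid_df, size=(base.size, n_members))
        members = base[:, None] + noise
        mean = members.mean(axis=1)
        lo, hi = np.percentile(members, [2.5, 97.5], axis=1)
        ensembles[sid] = prod.ProductivityEnsemble(
            stock_id=sid, years=g["year"].to_numpy(), members=members,
            mean=mean, ci_lower=np.minimum(lo, mean), ci_upper=np.maximum(hi, mean),
        )
    res = glmm_mod.ensemble_fit(
        ensembles, drivers, species_map, structures=structures,
        fix_nu=fix_nu, seed=seed,
    )
    out = {"truth": truth, "glmm": res, "scenarios": {}}
    for name, warming in scenarios:
        forcing = fc.make_scenario_forcing(drivers, name, warming_by_2100=warming,
                                           seed=seed)
        projections = {
            sid: fc.project_stock(res.fits, forcing, sid, species_map[sid],
                                  res.centers)
            for sid in ensembles
        }
        changes = {sid: fc.decade_change(p) for sid, p in projections.items()}
        wl = fc.classify_winners_losers(changes)
        counts = wl["class"].value_counts().to_dict()
        regional = fc.aggregate_regional(projections, {s: "A1" for s in ensembles})
        gl = fc.decade_change(fc.ProjectionEnsemble(
            stock_id="global", scenario_id=name, years=regional["global"]["years"],
            members=regional["global"]["members"], mean=regional["global"]["mean"],
            ci_lower=regional["global"]["ci_lower"],
            ci_upper=regional["global"]["ci_upper"],
        ))
        out["scenarios"][name] = {
            "winners": counts.get("winner", 0), "losers": counts.get("loser", 0),
            "neither": counts.get("neither", 0),
            "global_change": gl.change, "global_percent": gl.percent,
            "table": wl,
        }
    return out
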