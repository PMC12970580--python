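import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import gammaln

from stockprod import glmm, synthetic as syn
from stockprod.productivity import ProductivityEnsemble


class TestCriticalR:
    def test_published_thresholds(self):
        assert glmm.critical_r(26, 0.05) == pytest.approx(0.374, abs=1e-3)
        assert glmm.critical_r(26, 0.01) == pytest.approx(0.478, abs=1e-3)

    def test_false_positive_rate_by_construction(self, rng):
        """Independent 28-year white-noise pairs exceed the 0.05 threshold
        about 5% of the time."""
        n, reps = 28, 10_000
        crit = glmm.critical_r(n - 2, 0.05)
        x = rng.standard_normal((reps, n))
        y = rng.standard_normal((reps, n))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = np.sum(xc * yc, axis=1) / np.sqrt(
            np.sum(xc**2, axis=1) * np.sum(yc**2, axis=1)
        )
        rate = np.mean(np.abs(r) > crit)
        assert 0.035 < rate < 0.065

    def test_screen_structure(self):
        panels = [syn.simulate_driver_panel(28, seed=s) for s in range(6)]
        table, summary = glmm.collinearity_screen(panels)
        assert len(table) == 6 * 3
        assert set(summary["pair"]) == {"T-CHL", "T-MLD", "CHL-MLD"}
        assert (summary["n_pass_0.05"] <= 6).all()

    def test_short_window_errors(self):
        p = syn.simulate_driver_panel(28, seed=0)
        short = syn.DriverPanel("s", p.years[:2], p.T[:2], p.CHL[:2], p.MLD[:2])
        with pytest.raises(ValueError, match="window"):
            glmm.collinearity_screen([short])


def direct_t_regression(panel, nu=None):
    """Independent maximum-likelihood t regression (oracle for structure 1)."""
    y = panel["P"].to_numpy()
    X = np.column_stack([np.ones(len(panel)), panel["T"], panel["CHL"],
                         panel["MLD"]])

    def nll(p):
        beta, log_s = p[:4], p[4]
        nu_ = 2.01 + np.exp(p[5]) if nu is None else nu
        s = np.exp(log_s)
        u = y - X @ beta
        return -np.sum(
            gammaln((nu_ + 1) / 2) - gammaln(nu_ / 2)
            - 0.5 * np.log(nu_ * np.pi * s**2)
            - 0.5 * (nu_ + 1) * np.log1p(u**2 / (nu_ * s**2))
        )

    beta0 = np.linalg.lstsq(X, y, rcond=None)[0]
    x0 = np.r_[beta0, np.log(np.std(y - X @ beta0) + 1e-6)]
    if nu is None:
        x0 = np.r_[x0, np.log(3.0)]
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 8000, "fatol": 1e-10,
                                     "xatol": 1e-8})
    return -res.fun, res.x


class TestFitGLMM:
    def test_structure1_noiseless_exact(self):
        panel, _ = syn.simulate_community(
            4, 2, {"alpha": 0.1, "T": 0.02, "CHL": 0.05, "MLD": -0.001},
            None, 0.0, 5.0, seed=3,
        )
        fit = glmm.fit_glmm(panel, 1, fix_nu=5.0, center_drivers=False)
        assert fit.fixed["T"] == pytest.approx(0.02, rel=1e-6)
        assert fit.fixed["CHL"] == pytest.approx(0.05, rel=1e-6)
        assert fit.fixed["MLD"] == pytest.approx(-0.001, rel=1e-4)

    def test_structure1_matches_direct_t_optimizer(self):
        panel, _ = syn.simulate_community(
            5, 2, {"alpha": 0.1, "T": 0.01, "CHL": 0.03, "MLD": -0.002},
            None, 0.05, 6.0, seed=9,
        )
        fit = glmm.fit_glmm(panel, 1, center_drivers=False)
        ll_oracle, p_oracle = direct_t_regression(panel)
        assert fit.logLik == pytest.approx(ll_oracle, abs=1e-3)
        assert fit.fixed["T"] == pytest.approx(p_oracle[1], abs=1e-3)

    def test_random_sd_recovery_rate(self):
        """sigma_T recovered within a factor 1.5 in most replicates."""
        hits = 0
        reps = 8
        for rep in range(reps):
            panel, _ = syn.simulate_community(
                50, 2, {"alpha": 0.1, "T": 0.02, "CHL": 0.05, "MLD": -0.001},
                {"alpha": 0.05, "T": 0.01}, 0.02, 8.0, seed=400 + rep,
            )
            fit = glmm.fit_glmm(panel, 3, fix_nu=8.0)
            ratio = fit.random_sd["T"] / 0.01
            hits += 1 / 1.5 <= ratio <= 1.5
        assert hits >= 0.8 * reps

    def test_nesting_never_decreases_loglik(self, community_with_slopes):
        """Structures 2 c 3 c 6: warm-started richer fits dominate."""
        panel, _ = community_with_slopes
        f2 = glmm.fit_glmm(panel, 2, fix_nu=8.0)
        s3 = np.r_[f2.params_vector[:4], f2.params_vector[4],
                   np.log(1e-4), f2.params_vector[5]]
        f3 = glmm.fit_glmm(panel, 3, fix_nu=8.0, start=s3)
        s6 = np.r_[f3.params_vector[:4], f3.params_vector[4:6],
                   np.log(1e-4), f3.params_vector[6]]
        f6 = glmm.fit_glmm(panel, 6, fix_nu=8.0, start=s6)
        assert f3.logLik >= f2.logLik - 1e-6
        assert f6.logLik >= f3.logLik - 1e-6

    def test_gaussian_limit_matches_mixedlm(self):
        """With nu fixed huge, the t mixed model reduces to the Gaussian
        random-intercept model (statsmodels MixedLM, ML)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        panel, _ = syn.simulate_community(
            12, 2, {"alpha": 0.2, "T": 0.02, "CHL": 0.04, "MLD": -0.002},
            {"alpha": 0.08}, 0.0, 5.0, seed=15,
        )
        panel = panel.copy()
        panel["P"] += 0.05 * rng.standard_normal(len(panel))  # gaussian noise
        fit = glmm.fit_glmm(panel, 2, fix_nu=1e6, center_drivers=True,
                            xatol=1e-8, fatol=1e-10, maxiter=8000)
        centered = panel.copy()
        ctr = centered.groupby("stock_id")[["T", "CHL", "MLD"]].transform("mean")
        for c in ("T", "CHL", "MLD"):
            centered[c] = centered[c] - ctr[c]
        X = sm.add_constant(centered[["T", "CHL", "MLD"]])
        ml = sm.MixedLM(centered["P"], X, groups=centered["species_id"]).fit(
            reml=False
        )
        for mine, theirs in zip(
            (fit.fixed["alpha"], fit.fixed["T"], fit.fixed["CHL"],
             fit.fixed["MLD"]),
            ml.fe_params.to_numpy(),
        ):
            assert mine == pytest.approx(theirs, abs=1e-3)
        assert fit.random_sd["alpha"] == pytest.approx(
            np.sqrt(float(ml.cov_re.iloc[0, 0])), abs=1e-3
        )

    def test_validation(self, community_with_slopes):
        panel, _ = community_with_slopes
        with pytest.raises(ValueError):
            glmm.fit_glmm(panel, 9)
        single = panel[panel["species_id"] == "sp1"]
        with pytest.raises(ValueError, match="2 species"):
            glmm.fit_glmm(single, 2)


def make_pseudo_ensembles(panel, truth, n_members, resid_scale, resid_df, seed):
    rng = np.random.default_rng(seed)
    ens, drivers, species = {}, {}, {}
    for sid, g in panel.groupby("stock_id"):
        base = g["P"].to_numpy()
        members = base[:, None] + resid_scale * rng.standard_t(
            resid_df, size=(base.size, n_members)
        )
        mean = members.mean(axis=1)
        lo, hi = np.percentile(members, [2.5, 97.5], axis=1)
        ens[sid] = ProductivityEnsemble(sid, g["year"].to_numpy(), members,
                                        mean, np.minimum(lo, mean),
                                        np.maximum(hi, mean))
        drivers[sid] = syn.DriverPanel(sid, g["year"].to_numpy(),
                                       g["T"].to_numpy(), g["CHL"].to_numpy(),
                                       g["MLD"].to_numpy())
        species[sid] = g["species_id"].iloc[0]
    return ens, drivers, species


class TestEnsembleFit:
    def test_degenerate_ensemble_collapses_deltas(self, community_with_slopes):
        panel, truth = community_with_slopes
        ens, drivers, species = make_pseudo_ensembles(panel, truth, 4, 0.0, 8.0,
                                                      seed=0)
        res = glmm.ensemble_fit(ens, drivers, species, structures=(2, 3),
                                fix_nu=8.0)
        spread = res.comparison.groupby("structure")["AIC"].std()
        assert (spread < 1e-4).all()

    def test_structure6_recovered_as_best(self, community_with_slopes):
        """Random T and CHL slopes in truth: structure 6 wins median dAIC."""
        clean, truth = community_with_slopes
        base, _ = syn.simulate_community(
            24, 2, {"alpha": 0.12, "T": 0.015, "CHL": 0.04, "MLD": -0.001},
            {"alpha": 0.04, "T": 0.02, "CHL": 0.02},
            resid_scale=0.0, resid_df=8.0, seed=21,
        )
        ens, drivers, species = make_pseudo_ensembles(base, truth, 8, 0.02, 8.0,
                                                      seed=1)
        res = glmm.ensemble_fit(ens, drivers, species, fix_nu=8.0)
        assert res.best_structure == 6
        assert res.n_failed == 0

    def test_zero_effect_data_not_significant(self):
        panel, truth = syn.simulate_community(
            12, 2, {"alpha": 0.1, "T": 0.0, "CHL": 0.0, "MLD": 0.0},
            {"alpha": 0.02}, resid_scale=0.0, resid_df=8.0, seed=33,
        )
        ens, drivers, species = make_pseudo_ensembles(panel, truth, 10, 0.03,
                                                      8.0, seed=2)
        res = glmm.ensemble_fit(ens, drivers, species, structures=(2,),
                                fix_nu=8.0)
        assert not res.effects["significant"].any()

    def test_member_order_invariance(self, community_with_slopes):
        panel, truth = community_with_slopes
        ens, drivers, species = make_pseudo_ensembles(panel, truth, 6, 0.02,
                                                      8.0, seed=3)
        res_a = glmm.ensemble_fit(ens, drivers, species, structures=(3,),
                                  fix_nu=8.0)
        perm = np.array([3, 0, 5, 1, 4, 2])
        ens_b = {
            sid: ProductivityEnsemble(
                sid, e.years, e.members[:, perm], e.mean, e.ci_lower, e.ci_upper
            )
            for sid, e in ens.items()
        }
        res_b = glmm.ensemble_fit(ens_b, drivers, species, structures=(3,),
                                  fix_nu=8.0)
        pd.testing.assert_series_equal(
            res_a.effects["significant"], res_b.effects["significant"]
        )
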