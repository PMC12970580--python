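import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stockprod import forecast as fc
from stockprod import synthetic as syn
from stockprod.glmm import GLMMFit


def make_fit(fixed, devs=None, random_terms=()):
    species = sorted(devs) if devs else ["sp1"]
    eff = pd.DataFrame({"species_id": species})
    for term in random_terms:
        eff[f"dev_{term}"] = [devs[s].get(term, 0.0) for s in species]
    return GLMMFit(
        structure_id=6 if random_terms else 1, random_terms=tuple(random_terms),
        fixed=dict(fixed), random_sd={}, scale=0.02, df=8.0, logLik=0.0,
        AIC=0.0, BIC=0.0, n_obs=100, k_params=6, converged=True,
        species_effects=eff, params_vector=None,
    )


def constant_forcing(T=12.0, CHL=1.0, MLD=50.0, stock="S1", scen="scen"):
    years = np.arange(2021, 2101)
    panel = syn.DriverPanel(stock, years, np.full(80, T), np.full(80, CHL),
                            np.full(80, MLD))
    return fc.ScenarioForcing(scen, "esm", {stock: panel})


CENTERS = pd.DataFrame({"stock_id": ["S1"], "T": [12.0], "CHL": [1.0],
                        "MLD": [50.0]})


class TestProjectStock:
    def test_constant_drivers_at_centres_give_fitted_level(self):
        fits = [make_fit({"alpha": 0.15, "T": 0.02, "CHL": 0.0, "MLD": 0.0})]
        proj = fc.project_stock(fits, constant_forcing(), "S1", "sp1", CENTERS)
        assert np.allclose(proj.members, 0.15)

    def test_linearity_in_temperature(self):
        fits = [make_fit({"alpha": 0.1, "T": 0.02, "CHL": 0.0, "MLD": 0.0})]
        years = np.arange(2021, 2101)
        warm = syn.DriverPanel("S1", years, 12.0 + 2.0 * (years - 2021) / 79.0,
                               np.full(80, 1.0), np.full(80, 50.0))
        proj = fc.project_stock(
            [fits[0]], fc.ScenarioForcing("s", "e", {"S1": warm}), "S1", "sp1",
            CENTERS,
        )
        assert proj.members[-1, 0] - proj.members[0, 0] == pytest.approx(
            0.02 * 2.0, abs=1e-12
        )
        # finite-difference slope equals the fitted coefficient
        dT = warm.T[1] - warm.T[0]
        assert (proj.members[1, 0] - proj.members[0, 0]) / dT == pytest.approx(
            0.02, abs=1e-10
        )

    def test_mean_projection_equals_projection_of_mean_coefs(self):
        rng = np.random.default_rng(3)
        fits = [
            make_fit({"alpha": a, "T": b, "CHL": c, "MLD": d})
            for a, b, c, d in rng.normal(0, 0.02, size=(20, 4))
        ]
        years = np.arange(2021, 2101)
        panel = syn.DriverPanel("S1", years, 12 + rng.normal(0, 0.5, 80),
                                1.0 + 0.1 * rng.uniform(size=80),
                                50 + rng.normal(0, 3, 80))
        forcing = fc.ScenarioForcing("s", "e", {"S1": panel})
        proj = fc.project_stock(fits, forcing, "S1", "sp1", CENTERS)
        mean_fit = make_fit({
            k: float(np.mean([f.fixed[k] for f in fits]))
            for k in ("alpha", "T", "CHL", "MLD")
        })
        proj_mean = fc.project_stock([mean_fit], forcing, "S1", "sp1", CENTERS)
        assert np.allclose(proj.mean, proj_mean.members[:, 0], atol=1e-14)

    def test_species_effects_applied(self):
        devs = {"sp1": {"alpha": 0.05, "T": -0.02}, "sp2": {}}
        fits = [make_fit({"alpha": 0.1, "T": 0.02, "CHL": 0.0, "MLD": 0.0},
                         devs, ("alpha", "T"))]
        proj = fc.project_stock(fits, constant_forcing(), "S1", "sp1", CENTERS)
        assert np.allclose(proj.members, 0.15)  # slopes cancel at the centre
        with pytest.raises(KeyError):
            fc.project_stock(fits, constant_forcing(), "S1", "sp9", CENTERS)

    def test_forcing_coverage_validated(self):
        years = np.arange(2021, 2100)  # 79 years only
        panel = syn.DriverPanel("S1", years, np.full(79, 12.0),
                                np.full(79, 1.0), np.full(79, 50.0))
        with pytest.raises(ValueError, match="2021-2100"):
            fc.ScenarioForcing("s", "e", {"S1": panel})


class TestDirectionalEffect:
    def test_flat_and_monotone(self):
        assert fc.directional_effect(np.full(80, 0.1)) == "neutral"
        assert fc.directional_effect(np.linspace(0.3, 0.1, 80)) == "negative"

    def test_power_matches_analytic_oracle(self, rng):
        """Labeling rate at the 50%-power slope matches noncentral-t power."""
        n, reps = 80, 1000
        x = np.arange(n, dtype=float)
        xc = x - x.mean()
        sxx = float(np.sum(xc**2))
        sd = 0.05
        tcrit = stats.t.ppf(0.975, n - 2)
        # solve for the slope giving ~50% two-sided power
        from scipy.optimize import brentq

        def power(slope):
            ncp = slope / (sd / np.sqrt(sxx))
            return (1 - stats.nct.cdf(tcrit, n - 2, ncp)
                    + stats.nct.cdf(-tcrit, n - 2, ncp))

        slope50 = brentq(lambda s: power(s) - 0.5, 1e-6, 1e-3)
        hits = sum(
            fc.directional_effect(slope50 * x + sd * rng.standard_normal(n))
            == "positive"
            for _ in range(reps)
        )
        assert hits / reps == pytest.approx(0.5, abs=0.05)


def proj_from_members(members, stock="S1", scen="s"):
    years = np.arange(2021, 2101)
    mean = members.mean(axis=1)
    lo, hi = np.percentile(members, [2.5, 97.5], axis=1)
    return fc.ProjectionEnsemble(stock, scen, years, members, mean,
                                 np.minimum(lo, mean), np.maximum(hi, mean))


class TestDecadeChange:
    def test_stationary_projection(self):
        proj = proj_from_members(np.full((80, 10), 0.2))
        ch = fc.decade_change(proj)
        assert ch.change == pytest.approx(0.0)
        assert ch.percent == pytest.approx(0.0)

    def test_reference_baseline_consistency(self):
        """Delta -0.005 on a 0.1667 baseline is a 3.0% decline."""
        members = np.full((80, 5), 0.1667)
        members[70:] -= 0.005
        ch = fc.decade_change(proj_from_members(members))
        assert ch.change == pytest.approx(-0.005)
        assert ch.percent == pytest.approx(-3.0, abs=0.01)

    def test_member_wise_order_vs_brute_force(self, rng):
        members = 0.2 + 0.05 * rng.standard_normal((80, 40))
        ch = fc.decade_change(proj_from_members(members))
        ref = members[:10].mean(axis=0)
        foc = members[70:].mean(axis=0)
        assert np.allclose(ch.member_changes, foc - ref)
        assert ch.percent == pytest.approx(float(np.mean(100 * (foc - ref) / ref)))
        # member-wise percent differs from percent-of-means in general
        assert ch.percent != pytest.approx(
            100 * np.mean(foc - ref) / np.mean(ref), abs=1e-12
        )

    def test_nonpositive_reference(self):
        members = np.full((80, 5), -0.05)
        members[70:] = -0.02
        ch = fc.decade_change(proj_from_members(members))
        assert ch.change == pytest.approx(0.03)
        assert np.isnan(ch.percent)


class TestLandingsEquivalent:
    def test_worked_example(self):
        assert fc.landings_equivalent(-0.005) == pytest.approx(-16.5)
        assert fc.landings_equivalent(0.0) == 0.0

    def test_linearity(self):
        assert fc.landings_equivalent(0.01) == pytest.approx(
            2 * fc.landings_equivalent(0.005)
        )


class TestWinnersLosers:
    def test_classification_rule(self):
        changes = {
            "A": fc.DecadeChange(0.02, (0.01, 0.03), 10.0, (5.0, 15.0),
                                 np.zeros(3)),
            "B": fc.DecadeChange(-0.005, (-0.02, 0.01), -2.0, (-8.0, 4.0),
                                 np.zeros(3)),
            "C": fc.DecadeChange(-0.02, (-0.03, -0.01), -9.0, (-14.0, -4.0),
                                 np.zeros(3)),
        }
        wl = fc.classify_winners_losers(changes)
        assert dict(zip(wl["stock_id"], wl["class"])) == {
            "A": "winner", "B": "neither", "C": "loser"
        }

    def test_counts_sum_to_stock_count(self, rng):
        members = {f"S{i}": 0.1 + 0.02 * rng.standard_normal((80, 15))
                   for i in range(9)}
        changes = {s: fc.decade_change(proj_from_members(m, stock=s))
                   for s, m in members.items()}
        wl = fc.classify_winners_losers(changes)
        assert wl["class"].isin(["winner", "loser", "neither"]).all()
        assert len(wl) == 9


class TestAggregateRegional:
    def test_single_stock_area_identity(self, rng):
        proj = proj_from_members(0.2 + 0.01 * rng.standard_normal((80, 10)))
        agg = fc.aggregate_regional({"S1": proj}, {"S1": "A1"},
                                    include_global=False)
        assert np.allclose(agg["A1"]["mean"], proj.mean)

    def test_mirror_trends_cancel(self):
        up = proj_from_members(np.tile(np.linspace(0.1, 0.3, 80)[:, None],
                                       (1, 5)), stock="S1")
        down = proj_from_members(np.tile(np.linspace(0.3, 0.1, 80)[:, None],
                                        (1, 5)), stock="S2")
        agg = fc.aggregate_regional({"S1": up, "S2": down},
                                    {"S1": "A1", "S2": "A1"})
        assert np.allclose(agg["A1"]["mean"], 0.2)

    def test_global_recombines_area_means_by_stock_count(self, rng):
        projs = {f"S{i}": proj_from_members(
            0.1 * (i + 1) + 0.01 * rng.standard_normal((80, 8)), stock=f"S{i}")
            for i in range(5)}
        areas = {"S0": "A1", "S1": "A1", "S2": "A1", "S3": "A2", "S4": "A2"}
        agg = fc.aggregate_regional(projs, areas)
        recombined = (3 * agg["A1"]["mean"] + 2 * agg["A2"]["mean"]) / 5
        assert np.allclose(agg["global"]["mean"], recombined, atol=1e-12)

    def test_empty_area_warns(self, rng):
        proj = proj_from_members(np.full((80, 4), 0.1))
        with pytest.warns(UserWarning, match="no projected stocks"):
            fc.aggregate_regional({"S1": proj}, {"S1": "A1", "S2": "A2"})


class TestScenarioForcing:
    def test_deterministic_and_covering(self):
        hist = {f"S{i}": syn.simulate_driver_panel(28, seed=i) for i in range(3)}
        f1 = fc.make_scenario_forcing(hist, "ssp-strong", 4.5, seed=7)
        f2 = fc.make_scenario_forcing(hist, "ssp-strong", 4.5, seed=7)
        for sid in hist:
            assert np.array_equal(f1.panels[sid].T, f2.panels[sid].T)
            assert f1.panels[sid].years[0] == 2021
            assert f1.panels[sid].years[-1] == 2100

    def test_warming_reaches_target(self):
        hist = {"S1": syn.simulate_driver_panel(28, seed=0)}
        f = fc.make_scenario_forcing(hist, "x", 4.5, seed=0, noise_frac=0.0)
        panel = f.panels["S1"]
        assert panel.T[-1] - panel.T[0] == pytest.approx(4.5, rel=0.02)
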