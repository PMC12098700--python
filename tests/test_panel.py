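"""Fixed-effects estimator: oracle equivalence, clustered inference, variants."""

import numpy as np
import pandas as pd
import pytest

import hydroshift as hs
from hydroshift.errors import CollinearityError, ValidationError
from hydroshift.panel import (FitResult, benchmark_spec, cluster_vcov,
                              dose_response, fit_fe_ols, heterogeneous_effects,
                              implied_total, placebo_run)
from tests.conftest import small_config


def _dummy_design(df, spec, x_cols):
    """Explicit dummy-variable design matrix for oracle regressions."""
    blocks = [df[x_cols].to_numpy(float)]
    for f in spec.fixed_effects:
        blocks.append(pd.get_dummies(df[f]).to_numpy(float))
    return np.hstack(blocks)


class TestOracleEquivalence:
    def test_demean_equals_dummy_solution(self, tiny_panel):
        spec = benchmark_spec()
        a = fit_fe_ols(tiny_panel, spec, method="dummies")
        b = fit_fe_ols(tiny_panel, spec, method="demean")
        assert np.allclose(a.params.values, b.params.values, atol=1e-8)
        assert np.allclose(a.se.values, b.se.values, atol=1e-8)

    def test_demean_equals_dummy_on_small_world(self, small_panel):
        spec = benchmark_spec()
        a = fit_fe_ols(small_panel, spec, method="dummies")
        b = fit_fe_ols(small_panel, spec, method="demean")
        assert np.allclose(a.params.values, b.params.values, atol=1e-8)

    def test_beta_matches_full_lstsq_oracle(self, tiny_panel):
        spec = benchmark_spec()
        fit = fit_fe_ols(tiny_panel, spec)
        df = tiny_panel[tiny_panel["in_analysis"].astype(bool)].dropna(
            subset=["fhd", "local_drought"])
        x_cols = [c for c in spec.exposure + spec.controls if df[c].nunique() > 1]
        big = _dummy_design(df, spec, x_cols)
        coef, *_ = np.linalg.lstsq(big, df["pm25"].to_numpy(float), rcond=None)
        assert coef[0] == pytest.approx(fit.beta, abs=1e-8)

    def test_frisch_waugh_partialling(self, tiny_panel):
        """Partialling the FEs out of y and x and running simple OLS
        reproduces the exposure coefficient."""
        spec = benchmark_spec()
        fit = fit_fe_ols(tiny_panel, spec, method="dummies")
        df = tiny_panel[tiny_panel["in_analysis"].astype(bool)].dropna(
            subset=["fhd", "local_drought"])
        x_cols = [c for c in spec.exposure + spec.controls if df[c].nunique() > 1]
        d = pd.get_dummies(df[list(spec.fixed_effects)].astype(str)).to_numpy(float)
        def resid(v):
            coef, *_ = np.linalg.lstsq(d, v, rcond=None)
            return v - d @ coef
        xt = np.column_stack([resid(df[c].to_numpy(float)) for c in x_cols])
        yt = resid(df["pm25"].to_numpy(float))
        coef, *_ = np.linalg.lstsq(xt, yt, rcond=None)
        assert coef[0] == pytest.approx(fit.beta, abs=1e-8)


class TestClusterVcov:
    @staticmethod
    def _sim(n_clusters=19, n_per=40, seed=5):
        rng = np.random.default_rng(seed)
        g = np.repeat(np.arange(n_clusters), n_per)
        x = np.column_stack([rng.normal(size=g.size), rng.normal(size=g.size)])
        e = rng.normal(size=g.size)
        return x, e, g

    def test_matches_brute_force_formula(self):
        """CR1 sandwich equals its textbook formula to 1e-10, with 19 clusters."""
        x, e, g = self._sim()
        k = x.shape[1]
        got = cluster_vcov(x, e, g, k_params=k)
        bread = np.linalg.inv(x.T @ x)
        meat = np.zeros((k, k))
        for gg in np.unique(g):
            s = x[g == gg].T @ e[g == gg]
            meat += np.outer(s, s)
        n, G = x.shape[0], np.unique(g).size
        expected = (G / (G - 1)) * ((n - 1) / (n - k)) * bread @ meat @ bread
        assert np.allclose(got, expected, atol=1e-10)

    def test_matches_statsmodels_cluster_oracle(self, small_panel):
        """End-to-end: coefficient and clustered SE agree with an
        independent implementation (statsmodels OLS on the dummy design)."""
        import statsmodels.api as sm
        spec = benchmark_spec()
        fit = fit_fe_ols(small_panel, spec, method="dummies")
        df = small_panel[small_panel["in_analysis"].astype(bool)].dropna(
            subset=["fhd", "local_drought"])
        x_cols = [c for c in spec.exposure + spec.controls if df[c].nunique() > 1]
        big = _dummy_design(df, spec, x_cols)
        # compare the unscaled sandwich: statsmodels' small-sample factor
        # divides by the raw column count of the (redundant) dummy design,
        # whereas the CR1 convention here uses the design rank
        res = sm.OLS(df["pm25"].to_numpy(float), big).fit(
            cov_type="cluster", cov_kwds={"groups": df["market"].to_numpy(),
                                          "use_correction": False})
        assert res.params[0] == pytest.approx(fit.beta, abs=1e-8)
        n, k, g = fit.n_obs, fit.k_params, fit.n_clusters
        c = (g / (g - 1)) * ((n - 1) / (n - k))
        assert res.bse[0] == pytest.approx(float(fit.se["fhd"]) / np.sqrt(c),
                                           rel=1e-6)

    def test_duplicating_observations_keeps_beta(self, tiny_panel):
        spec = benchmark_spec()
        base = fit_fe_ols(tiny_panel, spec)
        doubled = pd.concat([tiny_panel, tiny_panel], ignore_index=True)
        dup = fit_fe_ols(doubled, spec)
        assert dup.beta == pytest.approx(base.beta, abs=1e-8)

    def test_cr1_close_to_classical_under_homoskedasticity(self):
        """With iid errors and many clusters the CR1 SE should track the
        classical OLS SE (within 20% on average over replications)."""
        rng = np.random.default_rng(11)
        ratios = []
        for _ in range(30):
            g = np.repeat(np.arange(50), 20)
            x = rng.normal(size=(g.size, 1))
            e = rng.normal(size=g.size)
            beta_hat, *_ = np.linalg.lstsq(x, e, rcond=None)
            resid = e - x[:, 0] * beta_hat
            cr1 = np.sqrt(cluster_vcov(x, resid, g, 1)[0, 0])
            classical = np.sqrt(resid @ resid / (g.size - 1)
                                / (x[:, 0] @ x[:, 0]))
            ratios.append(cr1 / classical)
        assert abs(np.mean(ratios) - 1.0) < 0.2

    def test_single_cluster_rejected(self):
        x, e, g = self._sim(n_clusters=1)
        with pytest.raises(ValidationError):
            cluster_vcov(x, e, g, 2)


class TestRecovery:
    def test_null_dgp_recovers_zero_exactly(self):
        cfg = small_config(true_beta=0.0, noise_sd=0.0, fire_event_rate=0.0,
                           seed=9)
        w = hs.generate_world(cfg)
        pnl = hs.assemble_panel(w.combustion_plants, w.pm25, w.met, w.truth.fhd,
                                w.fire, w.runoff, reference=cfg.reference_period)
        fit = fit_fe_ols(pnl)
        assert abs(fit.beta) < 1e-8

    def test_noise_free_fixture_recovers_truth_exactly(self, tiny_panel):
        fit = fit_fe_ols(tiny_panel)
        assert fit.beta == pytest.approx(1.55, abs=1e-6)

    def test_constant_shift_of_one_plant_absorbed_by_its_effect(self, tiny_panel):
        base = fit_fe_ols(tiny_panel)
        shifted = tiny_panel.copy()
        mask = shifted["plant_id"] == "M01_c0"
        shifted.loc[mask, "pm25"] += 5.0
        fit = fit_fe_ols(shifted)
        assert fit.beta == pytest.approx(base.beta, abs=1e-8)

    def test_absorbed_exposure_raises_collinearity(self, tiny_panel):
        df = tiny_panel.copy()
        # exposure constant within each plant => absorbed by plant effects
        df["fhd"] = df["plant_id"].map({p: i for i, p in
                                        enumerate(df["plant_id"].unique())})
        with pytest.raises(CollinearityError):
            fit_fe_ols(df)


@pytest.fixture(scope="module")
def low_noise_world():
    # three hydro plants per market spread FHD across all four dose bins
    cfg = small_config(noise_sd=0.2, seed=21, hydro_plants_per_market=3)
    w = hs.generate_world(cfg)
    pnl = hs.assemble_panel(w.combustion_plants, w.pm25, w.met, w.truth.fhd,
                            w.fire, w.runoff, reference=cfg.reference_period)
    return w, pnl


class TestDoseResponse:
    def test_bins_track_linear_dgp(self, low_noise_world):
        """Under a linear DGP with slope b, each bin coefficient is about
        b * (mean FHD in bin - mean FHD in reference)."""
        w, pnl = low_noise_world
        fit = dose_response(pnl)
        sample = pnl[pnl["in_analysis"].astype(bool)].dropna(subset=["fhd"])
        edges = [0.0, 0.25, 0.5, 0.75, 1.01]
        means = [sample.loc[(sample.fhd >= lo) & (sample.fhd < hi), "fhd"].mean()
                 for lo, hi in zip(edges[:-1], edges[1:])]
        for k, term in enumerate(fit.exposure):
            expected = w.truth.true_beta * (means[k + 1] - means[0])
            assert fit.params[term] == pytest.approx(expected, abs=0.25)

    def test_monotone_increase_across_bins(self, low_noise_world):
        _, pnl = low_noise_world
        fit = dose_response(pnl)
        coefs = fit.params[fit.exposure].values
        assert np.all(np.diff(np.concatenate([[0.0], coefs])) > -0.05)

    def test_empty_bin_rejected(self, tiny_panel):
        df = tiny_panel.copy()
        df["fhd"] = df["fhd"].clip(upper=0.2)  # everything in the reference bin
        with pytest.raises(ValidationError, match="bin"):
            dose_response(df)


class TestHeterogeneity:
    def test_fuel_ordering_recovered(self):
        cfg = small_config(noise_sd=0.3, seed=33,
                           true_beta_by_group={"fuel": {"coal": 0.8, "gas": 1.0,
                                                        "oil": 2.4, "biomass": 2.8}})
        w = hs.generate_world(cfg)
        pnl = hs.assemble_panel(w.combustion_plants, w.pm25, w.met, w.truth.fhd,
                                w.fire, w.runoff, reference=cfg.reference_period)
        fit = heterogeneous_effects(pnl, group="fuel")
        effects = {g.split("_x_")[1]: fit.params[g] for g in fit.exposure}
        present = set(effects)
        if {"oil", "coal"} <= present:
            assert effects["oil"] > effects["coal"]
        truth = {"coal": 0.8, "gas": 1.0, "oil": 2.4, "biomass": 2.8}
        for fuel, est in effects.items():
            assert est == pytest.approx(truth[fuel], abs=0.5)

    def test_size_groups_cover_sample(self, small_panel):
        fit = heterogeneous_effects(small_panel, group="size")
        sample = small_panel[small_panel["in_analysis"].astype(bool)].dropna(
            subset=["fhd", "local_drought"])
        assert fit.n_obs == len(sample)
        assert "group_differences" in fit.extra

    def test_homogeneous_dgp_shows_no_group_difference(self):
        flips = 0
        for seed in (41, 42, 43):
            cfg = small_config(seed=seed)
            w = hs.generate_world(cfg)
            pnl = hs.assemble_panel(w.combustion_plants, w.pm25, w.met,
                                    w.truth.fhd, w.fire, w.runoff,
                                    reference=cfg.reference_period)
            fit = heterogeneous_effects(pnl, group="size")
            diffs = fit.extra["group_differences"]
            flips += int((diffs["t"].abs() > 2).any())
        assert flips <= 1


class TestImpliedTotal:
    def _fit(self, baseline=15.76, beta=1.55):
        params = pd.Series({"fhd": beta})
        return FitResult(params=params,
                         vcov=pd.DataFrame([[0.31 ** 2]], index=["fhd"],
                                           columns=["fhd"]),
                         n_obs=79_022, n_clusters=19, k_params=1,
                         exposure=["fhd"], baseline_prediction=baseline,
                         residuals=np.zeros(1), method="dummies",
                         n_singletons_dropped=0,
                         exposure_means=pd.Series({"fhd": 0.5354838709677419}))

    def test_maximum_exposure_level(self):
        assert implied_total(self._fit(), 1.0) == pytest.approx(17.31)

    def test_zero_exposure_returns_baseline(self):
        assert implied_total(self._fit(), 0.0) == pytest.approx(15.76)

    def test_mean_exposure_increase(self):
        fit = self._fit()
        mean_fhd = float(fit.exposure_means["fhd"])
        total = implied_total(fit, mean_fhd)
        assert total == pytest.approx(16.59)
        assert total - fit.baseline_prediction == pytest.approx(0.83)

    def test_exposure_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            implied_total(self._fit(), 1.2)


@pytest.fixture(scope="module")
def preop_panel():
    """World with pre-operational plants in two hydropower markets."""
    cfg = small_config(noise_sd=0.0, fire_event_rate=0.0, seed=3,
                       commission_midpanel_share=0.5)
    w = hs.generate_world(cfg)
    return hs.assemble_panel(w.combustion_plants, w.pm25, w.met, w.truth.fhd,
                             w.fire, w.runoff, reference=cfg.reference_period)


class TestPlacebo:
    def test_pre_operational_sample_selection(self, preop_panel):
        fit = placebo_run(preop_panel, mode="pre_operational")
        assert fit.extra["placebo_mode"] == "pre_operational"
        # the placebo sample holds exactly the fire-free, fully-observed
        # months of years strictly before commissioning (none operational)
        pre = preop_panel[(preop_panel["year"] < preop_panel["commissioning_year"])
                          & preop_panel["fire_free"]
                          & preop_panel["market_has_hydro"]
                          & preop_panel[["fhd", "local_drought"]].notna().all(axis=1)]
        assert 0 < fit.n_obs <= len(pre)
        assert (pre["operational"] == 0).all()

    def test_pre_operational_null_effect_in_noise_free_world(self, preop_panel):
        fit = placebo_run(preop_panel, mode="pre_operational")
        assert abs(fit.beta) < 1e-6

    def test_non_combustion_null_effect(self, tiny):
        world, _ = tiny
        nc = world.noncombustion_plants
        pnl = hs.assemble_panel(nc, world.pm25, world.met, world.truth.fhd,
                                world.fire, world.runoff,
                                reference=world.config.reference_period)
        flag = hs.exposure.no_combustion_within(nc, world.combustion_plants, 50)
        pnl["no_combustion_within_radius"] = pnl["plant_id"].map(flag)
        assert pnl["no_combustion_within_radius"].all()
        fit = placebo_run(pnl, mode="non_combustion")
        assert abs(fit.beta) < 1e-6

    def test_nearby_combustion_shrinks_placebo_sample(self, tiny):
        world, _ = tiny
        nc = world.noncombustion_plants
        comb = world.combustion_plants.copy()
        # move one combustion plant on top of the first wind site
        comb.loc[comb.index[0], ["lat", "lon"]] = \
            nc.iloc[0][["lat", "lon"]].values
        flag = hs.exposure.no_combustion_within(nc, comb, 50)
        assert not flag.all() and flag.sum() == len(nc) - 1

    def test_empty_placebo_sample_rejected(self, tiny_panel):
        df = tiny_panel.copy()
        df["commissioning_year"] = 1900  # nothing is pre-operational
        with pytest.raises(ValidationError):
            placebo_run(df, mode="pre_operational")
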