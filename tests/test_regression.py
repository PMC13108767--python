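"""Fixed-effects estimator: oracle equivalence, recovery, and diagnostics."""

import numpy as np
import pandas as pd
import pytest

import pifc
from pifc.errors import RankError, SingularityError
from pifc.regression import FixedEffectsPanelModel, compute_vif

from conftest import dummy_ols_oracle, random_small_panel

PREDICTORS = ("mpower", "affordability", "literacy")


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_hand_built_dummy_ols(self, seed):
        """Estimator equals an independently built indicator-matrix least
        squares solution on random small panels (2-6 countries x 2-6 years)."""
        df = random_small_panel(seed)
        fit = FixedEffectsPanelModel(df, PREDICTORS).fit()
        oracle = dummy_ols_oracle(df, list(PREDICTORS))
        np.testing.assert_allclose(fit.betas.to_numpy(), oracle, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 3, 5])
    def test_univariable_matches_oracle(self, seed):
        df = random_small_panel(seed)
        fit = FixedEffectsPanelModel(df, ("mpower",)).fit()
        oracle = dummy_ols_oracle(df, ["mpower"])
        np.testing.assert_allclose(fit.betas.to_numpy(), oracle, atol=1e-8)


class TestParameterRecovery:
    def test_noiseless_recovery_exact(self, noiseless_panel):
        panel, truth = noiseless_panel
        for gender in ("men", "women"):
            fit = pifc.fit_fixed_effects(panel, gender, PREDICTORS)
            for p in PREDICTORS:
                assert fit.params[p] == pytest.approx(truth.beta[gender][p], abs=1e-8)

    def test_noiseless_fixed_effects_recovered(self, noiseless_panel):
        panel, truth = noiseless_panel
        fit = pifc.fit_fixed_effects(panel, "men", PREDICTORS)
        for country, eff in truth.country_effects["men"].items():
            assert fit.country_effects[country] == pytest.approx(eff, abs=1e-6)

    def test_noisy_recovery_unbiased_across_seeds(self):
        """Mean estimation error over 200 replicate panels within 3 MC SEs of 0."""
        errors = []
        for seed in range(200):
            panel, truth = pifc.generate_panel(
                n_countries=8, noise_sd=1.0, seed=1000 + seed)
            fit = pifc.fit_fixed_effects(panel, "men", ("mpower",))
            errors.append(fit.params["mpower"] - truth.beta["men"]["mpower"])
        errors = np.asarray(errors)
        mc_se = errors.std(ddof=1) / np.sqrt(len(errors))
        assert abs(errors.mean()) < 3 * mc_se

    def test_constant_response_within_country_gives_zero_slope(self):
        rng = np.random.default_rng(0)
        rows = []
        for ci in range(4):
            for year in (2010, 2012, 2014, 2016):
                rows.append({"country": f"C{ci}", "year": year, "gender": "men",
                             "prevalence": 10.0 + 5 * ci,
                             "mpower": int(rng.integers(20, 32)),
                             "affordability": 3.0, "literacy": 70.0})
        fit = FixedEffectsPanelModel(pd.DataFrame(rows), ("mpower",)).fit()
        assert abs(fit.params["mpower"]) < 1e-8


class TestInvariances:
    def test_response_shift_moves_only_intercept(self):
        df = random_small_panel(4)
        fit1 = FixedEffectsPanelModel(df, PREDICTORS).fit()
        df2 = df.assign(prevalence=df["prevalence"] + 7.5)
        fit2 = FixedEffectsPanelModel(df2, PREDICTORS).fit()
        np.testing.assert_allclose(fit1.betas.to_numpy(), fit2.betas.to_numpy(),
                                   atol=1e-8)
        assert fit2.beta0 - fit1.beta0 == pytest.approx(7.5, abs=1e-8)

    def test_residuals_mean_zero(self, study_bundle):
        fit = study_bundle["results"].fits["men"]["m4"]
        assert abs(fit.residuals.mean()) < 1e-8

    def test_gender_fits_independent(self, study_bundle):
        """Perturbing women's rows cannot change the men's fit."""
        panel = study_bundle["panel"]
        men_fit = pifc.fit_fixed_effects(panel, "men", PREDICTORS)
        mutated = panel.data.copy()
        women = mutated["gender"] == "women"
        mutated.loc[women, "prevalence"] = (mutated.loc[women, "prevalence"] / 2)
        men_fit2 = pifc.fit_fixed_effects(
            pifc.PolicyPanel(mutated, fit_years=panel.fit_years), "men", PREDICTORS)
        np.testing.assert_array_equal(men_fit.params.to_numpy(),
                                      men_fit2.params.to_numpy())


class TestErrors:
    def test_zero_within_variance_predictor_named(self):
        df = random_small_panel(1)
        df["affordability"] = df["country"].map(
            {c: i * 2.0 for i, c in enumerate(sorted(df["country"].unique()))})
        with pytest.raises(SingularityError, match="affordability"):
            FixedEffectsPanelModel(df, PREDICTORS).fit()

    def test_too_few_observations_rank_error(self):
        df = random_small_panel(2).iloc[:4]
        with pytest.raises(RankError):
            FixedEffectsPanelModel(df, PREDICTORS).fit()

    def test_single_country_rejected(self):
        df = random_small_panel(3)
        df = df[df["country"] == "C0"]
        with pytest.raises(RankError):
            FixedEffectsPanelModel(df, ("mpower",)).fit()


class TestVIF:
    def test_orthogonal_predictors_vif_one(self):
        x = np.array([1.0, 1.0, -1.0, -1.0] * 5)
        z = np.array([1.0, -1.0, 1.0, -1.0] * 5)
        df = pd.DataFrame({"a": x, "b": z})
        vif = compute_vif(df, ["a", "b"])
        np.testing.assert_allclose(vif.to_numpy(), [1.0, 1.0], atol=1e-12)

    def test_duplicated_predictor_infinite(self):
        x = np.arange(10.0)
        vif = compute_vif(pd.DataFrame({"a": x, "b": x}), ["a", "b"])
        assert np.isinf(vif).all()

    def test_known_correlation_closed_form(self):
        """rho = 0.6 between two predictors: VIF -> 1/(1-0.36) = 1.5625."""
        rng = np.random.default_rng(10)
        n = 200_000
        a = rng.standard_normal(n)
        b = 0.6 * a + np.sqrt(1 - 0.36) * rng.standard_normal(n)
        vif = compute_vif(pd.DataFrame({"a": a, "b": b}), ["a", "b"])
        np.testing.assert_allclose(vif.to_numpy(), [1.5625, 1.5625], rtol=0.02)

    def test_vif_reported_for_multivariable_fit(self, study_bundle):
        fit = study_bundle["results"].fits["men"]["m4"]
        assert fit.vif is not None
        assert (fit.vif >= 1.0).all()


class TestRSquaredComponents:
    def test_noiseless_all_one(self, noiseless_panel):
        panel, _ = noiseless_panel
        fit = pifc.fit_fixed_effects(panel, "men", PREDICTORS)
        for value in (fit.r2_within, fit.r2_between, fit.r2_overall):
            assert value == pytest.approx(1.0, abs=1e-10)

    def test_pure_noise_within_near_zero(self):
        """True slopes of zero: within-R2 reflects only overfitting noise."""
        r2w = []
        for seed in range(30):
            beta0 = {g: {p: 0.0 for p in PREDICTORS} for g in ("men", "women")}
            panel, _ = pifc.generate_panel(
                n_countries=10, beta=beta0, noise_sd=2.0, seed=seed)
            fit = pifc.fit_fixed_effects(panel, "men", ("mpower",))
            r2w.append(fit.r2_within)
        # year FE + 1 predictor on ~60 within-df: expect small but positive
        assert np.mean(r2w) < 0.25

    def test_components_bounded(self, study_bundle):
        for gender in ("men", "women"):
            for fit in study_bundle["results"].fits[gender].values():
                for v in (fit.r2_within, fit.r2_between, fit.r2_overall):
                    assert 0.0 <= v <= 1.0


class TestInteractionModel:
    def test_noiseless_interaction_recovery(self):
        panel, truth = pifc.generate_panel(
            interaction={"men": 0.002, "women": 0.001}, noise_sd=0.0, seed=21)
        fit = pifc.fit_fixed_effects(panel, "men", PREDICTORS, interaction=True)
        assert fit.params["mpower:literacy"] == pytest.approx(0.002, abs=1e-8)
        for p in PREDICTORS:
            assert fit.params[p] == pytest.approx(truth.beta["men"][p], abs=1e-6)

    def test_interaction_term_in_predictor_list(self, study_bundle):
        fit = pifc.fit_fixed_effects(study_bundle["panel"], "women",
                                     PREDICTORS, interaction=True)
        assert fit.predictors[-1] == "mpower:literacy"
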