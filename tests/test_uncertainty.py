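"""Bootstrap engine, resamplers, and the two sensitivity analyses."""

import numpy as np
import pandas as pd
import pytest

import pifc
from pifc.errors import BootstrapError, ConfigurationError, DomainError
from pifc.uncertainty import (
    interaction_marginal_effects,
    resample_countries,
    resample_rr_lognormal,
)


class TestBootstrapEngine:
    def test_same_seed_identical_cis(self):
        data = np.random.default_rng(1).normal(10, 2, 30)

        def stat(rng):
            if rng is None:
                return float(data.mean())
            return float(data[rng.integers(0, len(data), len(data))].mean())

        cfg = pifc.BootstrapConfig(n_reps=100, seed=7)
        r1 = pifc.bootstrap_ci(stat, cfg)
        r2 = pifc.bootstrap_ci(stat, cfg)
        assert r1.ci_low.equals(r2.ci_low)
        assert r1.ci_high.equals(r2.ci_high)

    def test_point_estimate_from_unresampled_data(self):
        data = np.arange(10.0)

        def stat(rng):
            if rng is None:
                return float(data.mean())
            return float(data[rng.integers(0, 10, 10)].mean())

        for reps in (10, 50):
            res = pifc.bootstrap_ci(stat, pifc.BootstrapConfig(n_reps=reps, seed=0))
            assert res.point.iloc[0] == 4.5

    def test_constant_statistic_zero_width(self):
        res = pifc.bootstrap_ci(lambda rng: 3.25,
                                pifc.BootstrapConfig(n_reps=50, seed=0))
        assert res.ci_low.iloc[0] == res.ci_high.iloc[0] == 3.25

    def test_failure_fraction_enforced(self):
        calls = {"n": 0}

        def flaky(rng):
            if rng is None:
                return 1.0
            calls["n"] += 1
            if calls["n"] % 2:
                raise RuntimeError("singular")
            return 1.0

        with pytest.raises(BootstrapError):
            pifc.bootstrap_ci(flaky, pifc.BootstrapConfig(n_reps=40, seed=0))


class TestResamplers:
    def test_country_resampling_relabels_duplicates(self, study_bundle):
        panel = study_bundle["panel"]
        anchors = study_bundle["anchors"]
        hdi = pifc.default_hdi_map()
        rng = np.random.default_rng(3)
        new_panel, new_anchors, new_hdi = resample_countries(panel, anchors, rng, hdi)
        assert len(new_panel.countries) == len(panel.countries)  # unique labels
        assert len(new_panel) == len(panel)
        for label in new_panel.countries:
            src = label.split("#")[0]
            assert new_hdi[label] == hdi[src]
            orig = panel.data[panel.data["country"] == src]
            copy = new_panel.data[new_panel.data["country"] == label]
            np.testing.assert_array_equal(orig["prevalence"].to_numpy(),
                                          copy["prevalence"].to_numpy())

    def test_rr_lognormal_centred_on_point(self, study_bundle):
        rr = study_bundle["rr"]
        draws = np.array([
            resample_rr_lognormal(rr, np.random.default_rng(s)).data["rr"].to_numpy()
            for s in range(400)])
        med = np.median(draws, axis=0)
        np.testing.assert_allclose(med, rr.data["rr"].to_numpy(), rtol=0.06)

    def test_pipeline_bootstrap_deterministic(self, study_bundle):
        results = study_bundle["results"]
        cfg = pifc.BootstrapConfig(n_reps=8, seed=5)
        t1 = results.bootstrap(cfg, by=[("region",)])[("region",)]
        t2 = results.bootstrap(cfg, by=[("region",)])[("region",)]
        pd.testing.assert_frame_equal(t1, t2)

    def test_country_keyed_cis_rejected_under_country_resampling(self, study_bundle):
        with pytest.raises(ConfigurationError):
            study_bundle["results"].bootstrap(
                pifc.BootstrapConfig(n_reps=4, seed=0, resample_unit="country"),
                by=[("country",)])

    def test_country_cis_via_rr_lognormal(self, study_bundle):
        out = study_bundle["results"].bootstrap(
            pifc.BootstrapConfig(n_reps=12, seed=2, resample_unit="rr_lognormal"),
            by=[("country",)])[("country",)]
        sub = out[out["scenario"] == "combined"]
        assert (sub["pif_ci_low"] <= sub["pif_ci_high"]).all()


class TestScaleIncidence:
    def test_factor_one_identity(self, study_bundle):
        strata = study_bundle["results"].strata
        pd.testing.assert_frame_equal(pifc.scale_incidence(strata, 1.0), strata)

    def test_counts_scale_fractions_do_not(self, study_bundle):
        strata = study_bundle["results"].strata
        scaled = pifc.scale_incidence(strata, 1.1)
        np.testing.assert_allclose(scaled["preventable_cases"],
                                   1.1 * strata["preventable_cases"])
        np.testing.assert_allclose(scaled["total_cases"], 1.1 * strata["total_cases"])
        np.testing.assert_array_equal(scaled["pif"], strata["pif"])
        np.testing.assert_array_equal(scaled["paf_current"], strata["paf_current"])

    def test_commutes_with_aggregation_exactly(self, study_bundle):
        results = study_bundle["results"]
        hdi = results.model.hdi
        scale_then_agg = pifc.aggregate(
            pifc.scale_incidence(results.strata, 0.9), ["region"], hdi)
        agg_then_scale = pifc.scale_incidence(results.regional(), 0.9)
        pd.testing.assert_frame_equal(scale_then_agg, agg_then_scale)

    def test_nonpositive_factor_rejected(self, study_bundle):
        with pytest.raises(DomainError):
            pifc.scale_incidence(study_bundle["results"].strata, 0.0)
        with pytest.raises(DomainError):
            pifc.scale_incidence(study_bundle["results"].strata, -1.1)


class TestInteractionScenario:
    def test_zero_interaction_reproduces_main_pipeline(self):
        """beta_inter = 0: interaction-model combined scenario is bit-identical
        to the plain multivariable combined scenario."""
        panel, _ = pifc.generate_panel(noise_sd=0.0, seed=31)
        anchors = pifc.generate_anchors(seed=31)
        rr = pifc.generate_rr_table(seed=31)
        plain = pifc.TobaccoPolicyModel(panel, anchors, rr).fit()
        inter = pifc.TobaccoPolicyModel(panel, anchors, rr, interaction=True).fit()
        a = plain.scenario_prevalence
        b = inter.scenario_prevalence
        for scenario in ("combined", "max_mpower"):
            np.testing.assert_allclose(
                a[a["scenario"] == scenario]["prevalence"].to_numpy(),
                b[b["scenario"] == scenario]["prevalence"].to_numpy(),
                atol=1e-8)

    def test_marginal_effects_attenuate_with_literacy(self):
        """Positive interaction with negative MPOWER slope: the MPOWER
        marginal effect shrinks in magnitude as literacy rises."""
        panel, _ = pifc.generate_panel(
            interaction={"men": 0.002, "women": 0.001}, noise_sd=0.0, seed=33)
        fit = pifc.fit_fixed_effects(
            panel, "men", ("mpower", "affordability", "literacy"), interaction=True)
        vals = panel.latest_policy_values()
        vals = vals[vals["gender"] == "men"]
        marg = interaction_marginal_effects(fit, vals)
        joined = marg.join(vals.set_index("country")["literacy"].rename("lit_now"),
                           how="left")
        order = joined.sort_values("lit_now")
        # effect = beta_mpower + 0.002 * literacy, increasing in literacy
        assert order["mpower"].is_monotonic_increasing

    def test_noiseless_marginal_effects_exact(self):
        panel, truth = pifc.generate_panel(
            interaction={"men": 0.002, "women": 0.001}, noise_sd=0.0, seed=34)
        fit = pifc.fit_fixed_effects(
            panel, "men", ("mpower", "affordability", "literacy"), interaction=True)
        vals = panel.latest_policy_values()
        vals = vals[vals["gender"] == "men"]
        marg = interaction_marginal_effects(fit, vals)
        b = truth.beta["men"]
        expected = b["mpower"] + 0.002 * vals.set_index("country")["literacy"]
        np.testing.assert_allclose(marg["mpower"], expected, atol=1e-6)

    def test_missing_interaction_term_rejected(self, study_bundle):
        fit = study_bundle["results"].fits["men"]["m4"]
        vals = study_bundle["panel"].latest_policy_values()
        with pytest.raises(ConfigurationError):
            interaction_marginal_effects(fit, vals[vals["gender"] == "men"])
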