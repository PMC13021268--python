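"""Model-fitting behaviour that does not need replicate studies.

The statistical calibration and oracle-equivalence checks live in
``test_acceptance.py``; here we exercise interfaces, degenerate inputs,
posterior-probability statements and the section/decomposition helpers.
"""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import fourps as fp
from fourps.inference import FitResult, ModelSpec
from fourps.mcmc import PosteriorDraws, SamplerSettings


def _fake_fit(samples, name="arm[intervention]"):
    """FitResult wrapping a hand-made posterior for one coefficient."""
    arr = np.asarray(samples, dtype=float).reshape(1, -1, 1)
    draws = PosteriorDraws(
        draws=arr,
        names=(name,),
        rhat=np.array([1.0]),
        ess_bulk=np.array([float(arr.size)]),
        accept_rate=1.0,
    )
    spec = ModelSpec(outcome="rank", item_id=1)
    summary = pd.DataFrame(
        [{"parameter": name, "kind": "coefficient", "mean": arr.mean(),
          "ci_2.5": np.quantile(arr, 0.025), "ci_97.5": np.quantile(arr, 0.975)}]
    )
    return FitResult(
        spec=spec, summary=summary, draws=draws, method="bayes", n_obs=arr.size,
        outcome_categories=(0, 1), data_digest="x", usable=True,
    )


class TestProbOfEffect:
    def test_symmetric_null_posterior_is_half(self):
        rng = np.random.default_rng(0)
        fit = _fake_fit(rng.normal(0.0, 1.0, 4000))
        assert fp.prob_of_effect(fit, "arm[intervention]") == pytest.approx(0.5, abs=0.03)

    def test_all_draws_above_one_gives_one(self):
        fit = _fake_fit(np.linspace(0.1, 2.0, 100))
        assert fp.prob_of_effect(fit, "arm[intervention]") == 1.0

    def test_direction_and_threshold(self):
        fit = _fake_fit(np.log([0.5, 0.8, 1.5, 2.0]))
        assert fp.prob_of_effect(fit, "arm[intervention]", threshold=1.0, direction="less") == 0.5
        assert fp.prob_of_effect(fit, "arm[intervention]", threshold=1.8) == 0.25

    def test_unknown_parameter_raises(self):
        fit = _fake_fit([0.0, 0.1])
        with pytest.raises(ValueError):
            fp.prob_of_effect(fit, "arm[intervention]", direction="sideways")
        with pytest.raises((KeyError, ValueError)):
            fp.prob_of_effect(fit, "nope")

    def test_ml_fit_uses_normal_approximation(self, effect_scored):
        spec = ModelSpec(outcome="rank", item_id=1, fixed_effects=("arm",), method="ml")
        fit = fp.fit_ordinal(effect_scored, spec)
        p = fp.prob_of_effect(fit, "arm[intervention]")
        assert 0.0 <= p <= 1.0 and p > 0.9  # known positive effect


class TestSpecValidation:
    def test_outcome_family_compatibility(self):
        with pytest.raises(ValueError):
            ModelSpec(outcome="gap", item_id=1)
        with pytest.raises(ValueError, match="multinomial"):
            ModelSpec(outcome="rank", item_id=1, reference_category="less_than_preferred")

    def test_wrong_family_dispatch_rejected(self, effect_scored):
        with pytest.raises(ValueError, match="ordinal"):
            fp.fit_ordinal(effect_scored, ModelSpec(outcome="match_category", item_id=1))
        with pytest.raises(ValueError, match="match_category"):
            fp.fit_multinomial(effect_scored, ModelSpec(outcome="rank", item_id=1))

    def test_single_observed_category_rejected(self, effect_scored):
        one_cat = effect_scored[effect_scored["rank"] == 5]
        with pytest.raises(ValueError, match="categor"):
            fp.fit_ordinal(one_cat, ModelSpec(outcome="rank", item_id=1))


class TestBayesFits:
    def test_ordinal_fit_reports_diagnostics_and_or_scale(self, effect_scored, light_sampler):
        spec = ModelSpec(
            outcome="rank", item_id=1, fixed_effects=("arm",), cluster="site_id",
            sampler=light_sampler,
        )
        fit = fp.fit_ordinal(effect_scored, spec)
        s = fit.summary
        assert set(s["parameter"]) == {
            "cutpoint[1]", "cutpoint[2]", "cutpoint[3]", "cutpoint[4]", "cutpoint[5]",
            "arm[intervention]", "site_sd",
        }
        assert s["rhat"].notna().all() and s["ess_bulk"].notna().all()
        row = fit.coefficient_row("arm[intervention]")
        assert row["ci_2.5"] < row["median"] < row["ci_97.5"]
        assert row["or_median"] == pytest.approx(np.exp(row["median"]))
        assert (s.loc[s["kind"] == "site_sd", "median"] > 0).all()

    def test_known_positive_effect_recovered_qualitatively(self, effect_scored, light_sampler):
        spec = ModelSpec(
            outcome="rank", item_id=1, fixed_effects=("arm",), cluster="site_id",
            sampler=light_sampler,
        )
        fit = fp.fit_ordinal(effect_scored, spec)
        assert fit.coefficient_row("arm[intervention]")["median"] > 0
        assert fp.prob_of_effect(fit, "arm[intervention]") > 0.95

    def test_multinomial_reports_both_contrasts(self, effect_scored, light_sampler):
        spec = ModelSpec(
            outcome="match_category", item_id=1, fixed_effects=("arm",),
            cluster="site_id", sampler=light_sampler,
        )
        fit = fp.fit_multinomial(effect_scored, spec)
        params = set(fit.summary["parameter"])
        assert "arm[intervention][less_than_preferred]" in params
        assert "arm[intervention][more_than_preferred]" in params
        assert fit.outcome_categories[0] == "match"

    def test_single_site_degenerates_gracefully(self, light_sampler):
        config = fp.SimulationConfig(n_respondents=80, n_sites=1, seed=21)
        cohort, _ = fp.simulate_trial(config)
        scored = fp.score_cohort(cohort)
        spec = ModelSpec(
            outcome="rank", item_id=1, fixed_effects=("arm",), cluster="site_id",
            sampler=light_sampler,
        )
        fit = fp.fit_ordinal(scored, spec)
        assert any("single cluster" in w for w in fit.warnings)
        # prior-driven site SD stays small under HalfNormal(1)
        assert fit.coefficient_row("site_sd")["median"] < 1.5


class TestSections:
    def test_identical_sections_give_near_identical_posteriors(self, light_sampler):
        config = fp.SimulationConfig(n_respondents=150, n_sites=3, seed=22)
        cohort, _ = fp.simulate_trial(config)
        scored = fp.score_cohort(cohort)
        scored["experience"] = scored["preference"]  # force identical columns
        spec = ModelSpec(outcome="rank", item_id=1, fixed_effects=("arm",), sampler=light_sampler)
        pref_fit, exp_fit = fp.fit_sections(scored, spec)
        a = pref_fit.coefficient_row("arm[intervention]")
        b = exp_fit.coefficient_row("arm[intervention]")
        assert a["median"] == pytest.approx(b["median"], abs=0.1)

    def test_sex_effect_flows_from_preferences_to_experiences(self, light_sampler):
        """A preference-only sex effect appears in both sections (coupling)."""
        config = fp.SimulationConfig(covariate_effects={"female": 0.8}, seed=23)
        cohort, _ = fp.simulate_trial(config)
        scored = fp.score_cohort(cohort)
        spec = ModelSpec(outcome="rank", item_id=1, fixed_effects=("sex",), sampler=light_sampler)
        pref_fit, exp_fit = fp.fit_sections(scored, spec)
        assert pref_fit.coefficient_row("sex[female]")["median"] > 0
        assert exp_fit.coefficient_row("sex[female]")["median"] > 0


class TestPerItem:
    def test_primary_first_and_counts(self, effect_scored):
        spec = ModelSpec(outcome="rank", item_id=1, fixed_effects=("arm",), method="ml")
        fits = fp.fit_per_item(effect_scored, spec, items=list(range(1, 13)), primary=[7])
        assert len(fits) == 12
        assert fits[0].item_id == 7 and fits[0].designation == "primary"
        assert all(f.designation == "secondary" for f in fits[1:])

    def test_single_item(self, effect_scored):
        spec = ModelSpec(outcome="rank", item_id=1, fixed_effects=("arm",), method="ml")
        fits = fp.fit_per_item(effect_scored, spec, items=[3])
        assert len(fits) == 1 and fits[0].fit is not None

    def test_item_without_data_flagged_others_unaffected(self, effect_scored):
        broken = effect_scored.copy()
        broken.loc[broken["item_id"] == 2, "rank"] = np.nan
        spec = ModelSpec(outcome="rank", item_id=1, fixed_effects=("arm",), method="ml")
        fits = fp.fit_per_item(broken, spec, items=[1, 2, 3])
        by_item = {f.item_id: f for f in fits}
        assert by_item[2].fit is None and by_item[2].error
        assert by_item[1].fit is not None and by_item[3].fit is not None

    def test_empty_items_rejected(self, effect_scored):
        spec = ModelSpec(outcome="rank", item_id=1, method="ml")
        with pytest.raises(ValueError):
            fp.fit_per_item(effect_scored, spec, items=[])


class TestDecomposeChange:
    def test_identical_cohorts_flag_neither(self, light_sampler):
        config = fp.SimulationConfig(n_respondents=150, n_sites=3, seed=24)
        cohort, _ = fp.simulate_trial(config)
        scored = fp.score_cohort(cohort)
        rep = fp.decompose_change(
            scored, scored.copy(), ModelSpec(outcome="rank", item_id=1, sampler=light_sampler)
        )
        assert rep.source == "neither"
        assert not rep.preference_shift and not rep.experience_shift

    def test_disjoint_respondents_rejected(self, effect_scored, light_sampler):
        other = effect_scored.copy()
        other["respondent_id"] = "x" + other["respondent_id"]
        with pytest.raises(ValueError, match="respondent"):
            fp.decompose_change(
                effect_scored, other, ModelSpec(outcome="rank", item_id=1, sampler=light_sampler)
            )

    def test_accepts_cohorts_directly(self, light_sampler):
        config = fp.SimulationConfig(n_respondents=100, n_sites=2, seed=25)
        cohort, _ = fp.simulate_trial(config)
        rep = fp.decompose_change(
            cohort, cohort, ModelSpec(outcome="rank", item_id=1, sampler=light_sampler)
        )
        assert rep.match_fit.n_obs == 200


class TestProportionalOddsCheck:
    def test_advisory_fields_present_and_supportive_on_own_data(self, effect_scored):
        spec = ModelSpec(outcome="rank", item_id=1, fixed_effects=("arm",))
        check = fp.check_proportional_odds(effect_scored, spec)
        assert set(check) >= {"aic_proportional", "aic_relaxed", "delta_aic", "advisory"}
        # the relaxed model spends ~9 extra parameters; on near-proportional
        # data the shared-coefficient model should not be heavily penalised
        assert check["delta_aic"] < 10.0

    def test_rejects_multinomial_outcome(self, effect_scored):
        with pytest.raises(ValueError):
            fp.check_proportional_odds(
                effect_scored, ModelSpec(outcome="match_category", item_id=1)
            )


class TestMlOracleAgreement:
    def test_bayes_ordinal_tracks_ml_on_large_n(self, light_sampler):
        """With n large and weak priors the posterior centres on the MLE."""
        config = fp.SimulationConfig(
            n_respondents=2000, n_sites=4, site_sd=0.0, concordance_effect=0.4, seed=26
        )
        cohort, _ = fp.simulate_trial(config)
        scored = fp.score_cohort(cohort)
        spec = ModelSpec(outcome="rank", item_id=1, fixed_effects=("arm",), sampler=light_sampler)
        bayes = fp.fit_ordinal(scored, spec)
        ml = fp.fit_ordinal(scored, dataclasses.replace(spec, method="ml"))
        assert bayes.coefficient_row("arm[intervention]")["median"] == pytest.approx(
            ml.coefficient_row("arm[intervention]")["mean"], abs=0.08
        )
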