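"""Estimate an intervention effect on the six-graded scale.

A two-arm clustered trial is simulated with a known concordance effect
(the intervention moves experiences toward preferences).  A Bayesian
multilevel proportional-odds model on the rank outcome then answers the
question a trialist actually asks: what is the probability the
intervention helped?
"""

import fourps as fp

config = fp.SimulationConfig(
    n_respondents=245, n_sites=9, concordance_effect=0.6, seed=11
)
cohort, _ = fp.simulate_trial(config)
scored = fp.score_cohort(cohort)

spec = fp.ModelSpec(
    outcome="rank", item_id=1, fixed_effects=("arm",), cluster="site_id",
    sampler=fp.SamplerSettings(seed=1),
)
fit = fp.fit_ordinal(scored, spec)

row = fit.coefficient_row("arm[intervention]")
print(f"item 1, arm odds ratio: {row['or_median']:.2f} "
      f"(95% CrI {row['or_ci_2.5']:.2f}-{row['or_ci_97.5']:.2f})")
print(f"P(OR > 1) = {fp.prob_of_effect(fit, 'arm[intervention]'):.3f}")
print(f"site SD (log-odds): {fit.coefficient_row('site_sd')['median']:.2f}")
print(f"diagnostics ok: {fit.usable} (worst R-hat {fit.summary['rhat'].max():.3f})")
print()
print("OR > 1 means intervention patients sit higher on the 0-5 scale, i.e.")
print("their experiences match their stated preferences more closely.")
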