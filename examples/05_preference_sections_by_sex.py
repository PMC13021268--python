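"""Analyse the preference and experience sections separately.

Preferences themselves carry information about a population: here women
are simulated to prefer higher levels of participation than men.  The
section models fit the raw ordinal reports of each part of the tool with
identical covariates.
"""

import fourps as fp

config = fp.SimulationConfig(
    n_respondents=300, n_sites=6, covariate_effects={"female": 0.5}, seed=42
)
cohort, _ = fp.simulate_trial(config)
scored = fp.score_cohort(cohort)

spec = fp.ModelSpec(
    outcome="rank", item_id=1, fixed_effects=("sex",),
    sampler=fp.SamplerSettings(seed=3),
)
pref_fit, exp_fit = fp.fit_sections(scored, spec)

for label, fit in (("preferences", pref_fit), ("experiences", exp_fit)):
    row = fit.coefficient_row("sex[female]")
    print(f"{label:<12} female-vs-male OR {row['or_median']:.2f} "
          f"(95% CrI {row['or_ci_2.5']:.2f}-{row['or_ci_97.5']:.2f})")

print()
print("The preference OR reflects the injected effect (exp(0.5) = 1.65).")
print("The experience OR is pulled along because experiences are generated")
print("relative to preferences - only their correspondence is person-centred.")
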