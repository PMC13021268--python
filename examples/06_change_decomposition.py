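"""Attribute an observed improvement to experiences or preferences.

If concordance improves between two timepoints, it matters whether
experiences came to match stable preferences (the intervention worked)
or the preferences themselves drifted (patients may have adapted to what
staff provide - worth a qualitative follow-up).  Here the follow-up gap
model suppresses 'less than preferred' experiences while preferences are
carried over unchanged.
"""

import dataclasses

import fourps as fp

config = fp.SimulationConfig(n_respondents=245, n_sites=9, arm_ratio=None, seed=55)
cohort_t0, truth = fp.simulate_trial(config)

followup = dataclasses.replace(
    config, gap_base_logits=(-4.5, -3.5, -2.5, 0.5, -0.5, -1.5, -2.5)
)
cohort_t1 = fp.regenerate_experiences(
    cohort_t0, followup, seed=77, site_effects=truth.site_effects
)

report = fp.decompose_change(
    cohort_t0, cohort_t1,
    fp.ModelSpec(outcome="rank", item_id=1, sampler=fp.SamplerSettings(seed=4)),
)

for label, fit in (
    ("participation (rank)", report.match_fit),
    ("preferences", report.preference_fit),
    ("experiences", report.experience_fit),
):
    row = fit.coefficient_row("timepoint")
    print(f"{label:<22} timepoint OR {row['or_median']:.2f} "
          f"(95% CrI {row['or_ci_2.5']:.2f}-{row['or_ci_97.5']:.2f})")

print()
print(f"classified change source: {report.source}")
print("Preference OR ~ 1 with experience OR > 1: the improvement reflects")
print("experiences aligning with stable preferences, not shifting preferences.")
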