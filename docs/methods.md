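# Methods notes

This note records the modelling choices, defaults and numerical decisions
behind `fourps`, and what the test suite does and does not establish.

## Scoring model

A pair of ordinal reports (preference `p`, experience `e`, both 1–4 with
the two response scales positioned in correspondence) is condensed into:

* match category by the sign of the gap `d = e − p`;
* rank 0–5 from a 16-cell scoring map;
* level by the fixed collapse 0–1 → insufficient, 2–3 → fair,
  4–5 → sufficient.

**Default map.** The published account of the six-graded scale fixes its
ordering principles (closer match is better; at equal distance, more
participation than preferred is better than less) but not a unique
cell-by-cell assignment. The shipped default makes rank a function of
the gap class, ordered best→worst `0, +1, −1, +2, −2, +3, −3` with ranks
`5, 4, 3, 2, 1, 0, 0`; the two extreme classes share rank 0 because
seven classes must fit six grades. Whether the canonical figure assigns
ranks purely by gap class or penalises particular cells (e.g. mismatch
at "crucial") cannot be settled from the text alone, so the map is a
first-class JSON artifact: any replacement 16-cell table can be dropped
in, and `validate_scoring_map` enforces the ordering principles
(diagonal = 5, rank non-increasing in |gap|, positive gap never below
the mirrored negative gap, all six grades emitted) on whatever map is
used.

**Missingness** is item-wise: an item with either side missing yields no
score, with no imputation — the instrument is a single-item tool and
each attribute is analysed separately. For the same reason no operation
in the package aggregates ranks across items.

## Synthetic cohorts

The simulator emulates the settings the instrument is used in: patients
nested in sites, optional intervention arms, repeated timepoints.

* **Preferences**: per item, cumulative-logit with shared cutpoints
  (default `−1.5, 0, 1.5`, i.e. marginal category probabilities
  ≈ 0.18/0.32/0.32/0.18), covariate effects on the latent scale
  (recognised: `female`, `age_decade`), and a per-site normal random
  intercept (`site_sd`, default 0.3 on the log-odds scale — moderate
  between-centre heterogeneity).
* **Experiences** are generated *through the gap*, not independently:
  a gap class in −3..+3 is drawn from a softmax over
  `gap_base_logits` (default symmetric, giving roughly 55% perfect
  matches per item — in the range seen in practice), restricted to
  classes keeping the experience in 1..4. Concordance is the estimand,
  so the intervention acts here: `concordance_effect` enters via a
  closeness weight `−|d|` (a positive scalar moves mass symmetrically
  toward gap 0 and hence moves the rank outcome monotonically), and
  `less_direction_effect` offsets only the negative-gap classes,
  mirroring interventions that specifically reduce "less than
  preferred". Site intercepts are shared with the gap model through the
  same closeness weight by default (`share_site_effects`).
* **Scale default** is 245 respondents across 9 sites, the size of a
  published multicentre evaluation in kidney care; sex is balanced and
  age is drawn near a chronic-disease population (mean 66, SD 12).
* **Repeated measures** reuse respondent identity; preferences are
  redrawn only under a non-zero `preference_drift` (default 0 — drift is
  a phenomenon to detect, not to assume).

No public 4Ps data exist to calibrate these defaults against; the
symmetric choices are deliberate and documented rather than estimated.
A green simulation-backed test therefore establishes *internal*
correctness (the estimators recover the generative truth of this world)
— not that the defaults match any particular clinical population, nor
robustness to real-data features such as informative missingness,
response styles, or site-by-arm confounding.

## Estimation

Per item (never pooled), the toolkit fits:

* **ordinal outcomes** (rank 0–5, level, raw preference or experience):
  cumulative-logit with proportional odds — one coefficient per
  covariate shifts all thresholds equally;
* **match category**: categorical-logit with the perfect match as
  reference category (configurable), one intercept and coefficient
  vector per non-reference category.

**Multilevel structure.** Site random intercepts are *integrated out* of
the likelihood with Gauss–Hermite quadrature (15 nodes; a 9-per-dimension
tensor grid over the two category-specific intercepts in the multinomial
case), leaving the site SD(s) as sampled parameters. This was a measured
decision, not a stylistic one: sampling 9+ site effects with a
Metropolis kernel produced a funnel geometry and unusable chains,
whereas the marginalised posterior is low-dimensional (6–10 parameters)
and well conditioned. Per-site effect estimates are consequently not
reported; the fixed effects, their odds ratios and the site SD are.

**Priors** (the source literature is silent; all configurable per
`ModelSpec`): Normal(0, 2.5) on log-odds coefficients, Normal(0, 10) on
each cutpoint/intercept with ordering enforced as a hard constraint, and
HalfNormal(1) on site SDs, sampled on the log scale with the Jacobian
included. Logit is the only implemented link — the recommended analyses
are stated in odds-ratio language, and probit/cloglog variants would
change the interpretation the reports are built around.

**Sampler.** Posteriors are sampled by the package's own engine
(`fourps.mcmc`): BFGS mode finding plus a Laplace covariance, then many
chains (default 12) advanced *in lockstep* — one batched log-posterior
call per iteration across all chains — under a mixture
Metropolis–Hastings kernel: a defensive independence proposal (a snug
plus a 3×-wide multivariate-t component, so proposal density cannot
collapse in skewed tails) and a `2.38/√d`-scaled random walk whose step
size adapts toward 23% acceptance during warmup. The proposal is refit
to pooled warmup draws twice. The likelihood collapses observations to
unique (covariate row, outcome) profiles, which makes evaluations cheap
for categorical designs and is exact in general. At default settings
(12 × 3000 draws after 800 warmup) a Case-I-scale ordinal fit takes a
few seconds with bulk ESS > 2000 and split-R̂ < 1.01.

**Diagnostics.** Split-R̂ and bulk ESS (via ArviZ) are recorded for
every parameter; a fit with R̂ > 1.01 or ESS < 400 is flagged
`usable = False` and marked in research reports, never hidden.
Divergence counts are reported as 0: the notion is
Hamiltonian-specific; for this kernel convergence trouble surfaces in
R̂/ESS. A fast maximum-likelihood mode (`method="ml"`, statsmodels,
fixed effects only, Wald intervals) exists for smoke tests and labels
itself in its output.

**Posterior statements.** `prob_of_effect` reports the share of draws
with the odds ratio beyond a threshold in a stated direction. The
null-hypothesis machinery is deliberately absent.

**Change decomposition.** For two timepoints with shared respondents,
three ordinal fits with a timepoint covariate (rank, preference,
experience) classify the change source by which section models' 95%
credible intervals exclude OR = 1: experience-shift, preference-shift,
both, or neither. The rank model provides the context (did concordance
change at all) but does not enter the classification.

**Multiplicity** is handled structurally, not by correction: research
mode requires designating primary items, reports list primary before
secondary and state the total number of models fitted. This matches the
design-based stance of the instrument's analysis guidance.

## Numerical notes

* Cutpoints are sampled directly in ordered space; unordered proposals
  get log-posterior −∞. The posterior mass sits far from the boundary,
  so rejections are rare and the geometry stays near-quadratic. (A
  log-increment transform was tried and abandoned: it made the posterior
  violently non-Gaussian for weakly identified boundary cutpoints.)
* Outcome categories are encoded over *observed* categories only; a
  two-category ordinal fit is therefore algebraically a logistic
  regression, which the tests exploit as an oracle.
* Ties in the clinical report's modal level resolve toward the lower
  (more actionable) level.
* `prob_of_effect` on ML fits uses a normal approximation on the
  log-odds scale.
* Seeds: every stochastic component (simulation, sampler) takes an
  explicit seed; simulation output is byte-reproducible, posterior
  summaries reproducible given the seed up to documented Monte-Carlo
  error.

## Known limitations

* Only the logit link; no probit/cloglog.
* No imputation for missing items (by design) and no model for
  informative missingness.
* The proportional-odds assumption is adopted; `check_proportional_odds`
  offers only an advisory ML-based AIC comparison against a fully
  category-specific multinomial relaxation (computed on adequately
  supported categories), and the data generated by the gap mechanism
  satisfy the assumption only approximately — the recovery study targets
  the population-level proportional-odds projection of the generative
  law.
* Site effects enter the gap model through the closeness weight; other
  site-by-outcome interactions are not simulated.
* Per-site random-effect estimates are unavailable (marginalised
  likelihood).
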