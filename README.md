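# fourps

Scoring and Bayesian analysis for the **Patient Preferences for Patient
Participation** instrument (the 4Ps).

## The problem

Person-centred care is not "the more patient participation, the better":
it is participation *on the patient's terms*. The 4Ps instrument measures
this by asking a patient, for each of 12 attributes of participation
(being listened to, taking part in planning, performing self-care, ...),
two things:

* a **preference** — how important the attribute is to them, on an
  ordered 4-level scale (*unimportant, somewhat important, very
  important, crucial*), stated prospectively;
* an **experience** — to what extent they experienced it (*not at all,
  to some extent, to a large extent, entirely*), reported in hindsight.

The outcome of interest is the *correspondence* between the two. Per
item, a pair of reports yields:

* a **match category**: match, less participation than preferred, or
  more than preferred;
* a **gap** `d = experience − preference` in −3..+3;
* a **rank** on the six-graded preference-based participation scale
  (0–5), via a 16-cell scoring map over the 4×4 response cross, built on
  two ordering principles: the closer the match the better, and at equal
  distance, more than preferred beats less than preferred;
* a clinical **level**: 0–1 *insufficient*, 2–3 *fair*, 4–5 *sufficient*
  conditions for preference-based participation.

The tool is single-item by design: no sum or mean score across the 12
attributes exists anywhere in this package.

The package is for researchers using the 4Ps as a trial or
quality-improvement outcome and for clinical teams tracking
person-centredness. Its analysis layer implements the recommended
estimation strategy: Bayesian multilevel **proportional-odds
(cumulative-logit) regression** for the ordinal scales,

```
P(Y_ij <= k) = logistic(theta_k − x_ij' beta − u_j),   u_j ~ N(0, sigma^2),
```

with patients `i` nested in sites `j`, and Bayesian multilevel
**multinomial regression** for the match category with the perfect match
as reference, so odds ratios read "less than preferred vs. a perfect
match" and "more than preferred vs. a perfect match". Results are posed
as posterior statements — `P(OR > 1)`, credible intervals — rather than
significance tests. A clustered cohort simulator with known generative
truth (preferences from a cumulative-logit model, experiences through a
gap-class model) backs calibration and recovery testing, since no public
4Ps datasets exist.

## Worked example

`examples/03_ordinal_intervention_effect.py` simulates a two-arm trial at
a realistic multicentre scale (245 patients, 9 sites) in which the
intervention moves experiences toward preferences, then fits the
multilevel ordinal model to item 1:

```
item 1, arm odds ratio: 2.52 (95% CrI 1.46-4.41)
P(OR > 1) = 0.999
site SD (log-odds): 0.25
diagnostics ok: True (worst R-hat 1.005)
```

The arm odds ratio above 1 says intervention patients sit higher on the
0–5 scale — their experiences align more closely with what they said
they preferred. `P(OR > 1)` is the posterior probability that the
intervention had *any* positive effect; the site SD quantifies
between-centre heterogeneity on the log-odds scale.

The other examples cover scoring single reports, the clinician-facing
three-level report, the multinomial match-reference analysis, separate
section models (e.g. sex differences in preferences), and the
repeated-measures decomposition that distinguishes "experiences came to
match preferences" from "preferences drifted".

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from a freshly built scoring map and the level-collapse
function (after an end-to-end simulate-and-score self-check), the
boundary ranks of the three-level clinical scale and writes them as
JSON.

## Layout

```
src/fourps/
  instrument.py   instrument definition, respondent records, CSV I/O
  scoring.py      gap, match category, 16-cell map, six-grade/three-level scales
  simulate.py     clustered cohort simulator with known truth
  mcmc.py         batched adaptive Metropolis-Hastings engine
  inference.py    Bayesian ordinal & multinomial fits, P(effect), decomposition
  reports.py      clinical and research report builders
  pipeline.py     one-config reproducible simulate→score→fit→report runs
examples/         one narrative script per capability
docs/methods.md   modelling and design notes
```

The verbatim item wording of the 4Ps is copyright-protected and available
from the instrument's first author; this package stores only attribute
labels and is not a substitute for the licensed questionnaire.
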