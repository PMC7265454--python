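# Methods

`avatarlab` simulates a training paradigm for investigative child interviews
and the psychometric analysis used to evaluate it.  This note records the
models, the parameter choices and their rationale, the numerical conventions,
and what the synthetic data can and cannot show.

## 1. The avatar response model

A scenario is a simulated child with a fixed "memory": nine *relevant*
details about an alleged incident and nine *neutral* details unrelated to it,
plus a keyword-indexed bank of verbatim *side details* and a ground-truth
outcome (who / where / what).  The last four relevant details (indices 6–9)
are conclusion-critical: only an interviewer who elicits all four can state
the correct outcome.  The default bank holds 16 scenarios, two per cell of
the 2 (age: 4, 6) x 2 (gender) x 2 (abuse present/absent) factorial.

The answer-selection algorithm dispatches on the operator-assigned question
type (13 codes; 3 recommended, 10 not recommended):

- **Recommended question with a matching keyword** — the next unconsumed
  side-bank answer is returned verbatim, bypassing the detail draw.
- **Recommended question otherwise** — a Bernoulli draw at the age-specific
  provision probability (0.125 at age 4, 0.25 at age 6) releases the next
  unprovided memory detail in fixed order; the category (relevant vs.
  neutral) is chosen by a fair coin, falling back to the other category when
  one is exhausted and to a no-new-info response when both are.
- **Not-recommended question presupposing content that contradicts memory**
  — the avatar assents with probability 0.30 at age 4 (0.15 at age 6, a
  package default: no empirical rate is stated for that age), creating an
  *incorrect detail*; otherwise it denies.  Consistent presuppositions are
  confirmed deterministically.
- **Other not-recommended questions** — a type-tagged generic or explicit
  no-new-info response (70/30 by default); never a memory or side detail.

Random-stream order is documented in `engine.py` so that any transcript is an
exact function of (scenario, parameters, question sequence, seed).

Design choices left open by the problem: a single provision probability per
age with a fair-coin category split (rather than per-category rates);
option-posing assent sharing the suggestive assent rate; the 10-minute limit
modelled as a question budget (default 60).  Each is configurable.

## 2. The synthetic trainee cohort

Each trainee holds a question-emitting policy:

| parameter | default | units | rationale |
|---|---|---|---|
| baseline p_rec | logit-normal, mean 0.441 | probability | observed baseline share of recommended questions |
| baseline spread | 0.75 on the logit scale | — | reproduces a total baseline SD of ~23.6 pp in the observed proportion once binomial noise is added (see below) |
| question count | trunc-normal(16.6, 8.5), min 1, rounded | questions/interview | printed mean and SD; family unstated, truncation keeps counts positive |
| learn_gain | 0.042 per feedback event | probability | five feedback events carry the feedback-group mean from ~0.44 to ~0.65, the anchor trajectory, clamping included |
| keyword_rate | 0.15 | probability | share of recommended questions aimed at side-detail keywords; unstated, chosen as a modest realism rate |
| assertion_true_rate | 0.2 | probability | fraction of presupposing questions whose content happens to match memory |
| presence_noise | 0.05 | probability | random flip of the dichotomous presence judgment |

The experiment runs 17 feedback + 15 control trainees through 6 interviews
each, with six distinct avatars drawn per trainee from the 16-scenario bank.
After interviews 1–5 a feedback-group trainee receives a feedback set of up
to two recommended and two not-recommended questions from the transcript just
produced, preferring question types not yet covered for that trainee; each
event adds `learn_gain` to p_rec (never decreasing, clamped at 1) and halves
the subtype weight of the criticised not-recommended types.  Control policies
never change, so with `learn_gain = 0` the generator satisfies the
group x time null exactly — the basis of the type-I calibration checks.

**The interviewer conclusion rule is a stand-in.**  No decision model links
elicited evidence to the trainee's verdict in the source paradigm, so the
package uses: presence judged "present" iff abuse-indicative evidence
surfaced (a conclusion-critical detail of a truly abused child, or a falsely
assented abuse assertion), flipped with probability 0.05; outcome slots are
filled correctly iff all four critical details were elicited; confidence is a
monotone step function of the critical-detail count onto the
{50, 60, 70, 80, 90, 100} scale.  Conclusions from synthetic data therefore
test the pipeline's plumbing, not human judgment.

**What the generator does not emulate.**  Question-type streams are
conditionally independent given the policy (real interviewers ask in runs);
detail-seeking skill does not improve with feedback (the effect enters only
through question-type propensities); avatar reluctance, operator coding
error, and cultural or gender effects are out of scope.  The observed detail
means in the real data (≈2 relevant details from ≈7.6 recommended questions
in a first interview) exceed what the stated 12.5%/25% provision rates can
produce; the engine keeps the stated rates, so the generator under-produces
details relative to the field data.  Passing tests show the algorithmic and
statistical machinery is correct under the stated probabilities — not that
the generator is a faithful model of human trainees.

## 3. Dependent variables and the integrated factor

Each interview is coded into six DVs: numbers of recommended and
not-recommended questions, percent recommended, and counts of relevant,
neutral and incorrect details.  The integrated factor is the mean of the six
per-DV z-scores with reversed signs for not-recommended questions and
incorrect details.  Standardization pools all participant x interview rows
(192 in the default design) with sample SDs (ddof = 1); a per-occasion
alternative can be had by passing a `reference` population.  A zero-question
interview has an undefined proportion; such rows are flagged NaN and excluded
from analysis with a warning (the generator's count truncation at 1 makes
them impossible by default).

## 4. Statistical battery

- **Epsilons.**  Greenhouse–Geisser from the trace form on the
  orthonormal-contrast projection of the pooled within-group covariance;
  Huynh–Feldt via the multi-group formula of Huynh (1978),
  ((N−g+1)(k−1)ε̂ − 2) / ((k−1)(N−g−(k−1)ε̂)), clipped to [ε̂, 1]
  (the Lecoutre (1991) variant differs by one unit in the numerator and can
  be substituted by editing one line; the Huynh form matches common
  statistical packages).
- **Multisample sphericity.**  The likelihood ratio for "all groups' contrast
  covariances equal and spherical" factors exactly into a Box-M test on the
  contrast scores and a Mauchly test on the pooled contrast covariance; each
  factor uses its standard Bartlett correction and the corrected chi-squares
  add (df = g·p(p+1)/2 − 1, p = k−1).  Small-sample behaviour is checked by
  simulation (type-I 0.05 ± 0.02 at n = 16 per group, k = 6), not claimed
  exact.  With k = 2 the test is vacuous and returns p = 1.
- **Mixed ANOVA.**  Classical split-plot sums of squares (weighted means for
  unequal group sizes; cross-checked against pingouin).  Within effects are
  corrected by GG when ε̂ < 0.75 and HF otherwise — the boundary itself goes
  to HF.  Effect size is partial eta squared; observed power uses the
  noncentral F with ncp = F · df1 at the corrected dfs (the convention of
  mainstream GLM software).
- **Planned comparisons.**  Per-occasion two-group one-way F (equivalently
  t²) with its own per-occasion error term, pooled-SD Cohen's d, Holm
  step-down adjustment over the family of six occasions.
- **RCI.**  (follow-up mean − baseline) / (SD₁·√(2(1−ICC))) with the control
  group's ICC as the reliability plug-in and |RCI| > 1.645 as the two-sided
  90% criterion.  The null calibration (~10% flagged under no true change)
  holds for the pre/post design the difference-SE assumes; averaging five
  follow-ups, as the training analysis does, shrinks the numerator's noise
  and makes the procedure conservative under the null (~3–4% flagged).
- **ICC.**  One-way random ICC(1) by default, floored at 0; a two-way
  consistency variant (removing the occasion effect) is selectable.
- **Kappa.**  Cohen's kappa with the Fleiss–Cohen–Everitt asymptotic
  variance; a single-category perfect-agreement table is returned as a
  flagged degenerate result rather than an error.
- **Adjusted CI levels.**  Goldstein–Healy: the two-sided level gamma solving
  z_gamma = z_{alpha/2}·√(se1²+se2²)/(se1+se2), so that just-touching
  intervals correspond to a two-sample z-test at alpha; 83.4 / 85.6 / 87.9%
  at SE ratios 1 / 2 / 3 for alpha = 0.05.

## 5. Numerical conventions and degenerate inputs

Ties in feedback selection break by earliest transcript position.  All
probabilities are clamped to [0, 1] after updates.  Zero-variance DVs raise
a named computation error rather than returning NaN statistics.  Report JSON
rounds to 10 significant digits so replays diff cleanly.  Every simulation
entry point takes an explicit integer seed; nothing draws from global state.

## 6. Problem sizes used in the checks

The calibration suites use 2,000 null replicates for the sphericity test and
the GG-corrected ANOVA (n = 16 per group, k = 6), 4,000 simulated stable
participants for the RCI null rate, and 500 replicate experiments at the
default design for the feedback-effect recovery check; Monte-Carlo rate
checks use 100,000 draws (3 MC standard errors ≈ 0.3–0.4 pp).

**Known limitation — interaction power.**  Under the calibrated study
conditions the group x time interaction on percent recommended is detected in
roughly 63% of replicate experiments at alpha = 0.05 (and at the nominal rate
under the null).  The dominant cause is the heavy lower tail of the
truncated-normal question-count distribution: ~4% of interviews contain a
single question, inflating the within-occasion error SD of an observed
proportion to ≈17 pp.  With the anchor-constrained learning trajectory
(≈21 pp total rise) the interaction noncentrality is ≈10, which caps power
near 0.63 for this design.  A lighter-tailed count family (e.g. gamma) would
raise power to ≈0.8, but the truncated normal is retained as the stated
study condition.
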