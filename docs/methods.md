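# Methods

## The study design being emulated

A retrospective case–control comparison in a pediatric emergency
population with a very low rate of moderate-to-severe TBI. Cases are
children under 16 with a confirmed intracranial bleed or fracture;
controls are head-injured children from the same registry who remained
well, age-matched **year for year at 4 controls per case** (39 cases,
156 controls). Candidate predictors are binary history and examination
items; the headline comparison is between a 4-variable logistic model
(road traffic accident, loss of consciousness, vomiting, base-of-skull
fracture signs) and a 7-variable ELM vote-score ensemble (those four
plus seizure, confusion and clinical skull-fracture signs).

## Synthetic cohort generator

Patient-level data are not available, so all simulation-based results
rest on a generative model calibrated to the published marginals:

- **Ages**: cases draw from Normal(8.1, 4.2) truncated to [0, 16)
  (matching the published means/SDs of 8.11/4.25 and 8.10/4.21 and the
  under-16 entry criterion). Each case is matched by `control_ratio`
  controls whose age is the case's integer year plus U[0, 1) — matching
  "year for year" holds by construction. The rounding rule (floor) is a
  design choice; the source describes year-for-year matching but not the
  rounding. A separate `age_match` operation performs the same stratified
  sampling without replacement from an external control pool and fails
  loudly, naming each deficient age stratum.
- **Predictors**: class-conditional Bernoulli draws whose default
  prevalences are the published case/control counts (e.g. loss of
  consciousness 25/39 vs 8/156). Only the marginals are published; the
  default joint structure is class-conditional independence. A single
  shared latent Gaussian severity factor with loading `rho` (Gaussian
  copula) is available to induce positive within-class dependence; the
  marginals remain exact for any `rho`.
- **Subgroup items**: headache and amnesia are asked only of verbal
  children (age ≥ 2 years), irritability only of preverbal children;
  outside the applicable band the value is not-applicable (NaN, empty in
  CSV). The 2-year threshold mirrors the preverbal definition used in
  the source setting.

What the generator does **not** emulate: the registry's true joint
predictor distribution, any age–predictor dependence, injury-severity
scales, or CT findings beyond the binary outcome. Consequently, passing
simulation tests demonstrates that the *methods* behave correctly under
the published marginal structure — not that the models would attain the
same performance on real registry data.

A second fixture, `fixture_cohort`, assigns (rather than samples)
predictor columns so that every univariable 2×2 margin equals the
printed counts exactly; its joint structure is arbitrary and it is used
only where the univariable tables are the target.

## Univariable statistics

2×2 tables are tested with Pearson's chi-square **without continuity
correction** or Fisher's exact test (two-sided by the probability-mass
convention, with the standard 1+1e-7 floating-point guard on the mass
comparison; degenerate tables return p = 1). r×c tables use the Pearson
chi-square with empty rows optionally dropped, df = (r−1)(c−1).
Continuous summaries use the pooled-variance Student t-test (a Welch
variant is available but not the default, as the pooled test reproduces
the published age p-value of 0.99).

**Test selection.** Every verifiable published history/examination
p-value corresponds to Fisher's exact test (vomiting 0.113, headache
0.401, scalp laceration 0.825, frontal hematoma 0.011, amnesia and
irritability 1), including rows where all expected counts exceed 5 — so
the default rule for the univariable report is Fisher for all 2×2
history/examination items. The textbook expected-count rule (Fisher when
any expected cell is below 5, Pearson otherwise) is provided as
`select_test(rule="cochran")`, and its operating characteristics are
what the type-I-error simulation measures. Two published rows are
knowingly irreproducible from their printed counts (loss of
consciousness > 1 minute, printed < 0.001 vs Fisher 0.008; tense
fontanelle, printed 0.03 vs Fisher 0.003) and are treated as printing
inconsistencies. The unequal-pupils row prints percentages only; its
back-computed counts (10/39, 2/156) are flagged uncertain. Percentages
in reports are rounded to integers, as printed. No multiple-testing
correction is applied (none was in the source analysis).

**Type-I-error simulation design.** The calibration of the
expected-count selection rule is assessed on null cohorts of n = 195
(39/156) whose predictors have equal prevalences in both classes at
{5%, 15%, 25%, 35%, 45%} — a span from rare to common symptoms chosen so
that *both* branches of the rule are exercised (at these margins the
expected-count threshold switches tests at a pooled prevalence of
~12.8%). Exact conditional tests are conservative on sparse tables: at
the study's own control-arm prevalences, where nearly every predictor
lands in the Fisher branch, the pooled rejection rate is ~2–3% rather
than 5%. This is a known property of exact tests at small expected
counts, not an implementation artifact.

## Logistic model

Unconditional maximum likelihood (Newton/IRLS via statsmodels, gradient
max-norm < 1e-6 at the solution), Wald p-values and covariance from the
observed information. The age matching is deliberately **not** modelled
in the likelihood, mirroring the source analysis; conditional logistic
regression is out of scope. Complete or quasi-complete separation is
detected (solver failure, non-convergence, or any |coefficient| > 15)
and *flagged* on the result rather than raised; a lightly
ridge-penalised IRLS supplies finite coefficients for inspection in that
case. Penalized (Firth-style) estimation is intentionally off by
default — the very wide published intervals (e.g. 3.61–106.66) are
consistent with unpenalized Wald inference.

Selection is the published two-step procedure: a univariable screen
keeping predictors with single-predictor Wald p < 0.2 (a separated
predictor passes the screen: it is maximally associated), then forward
stepwise with backward pruning (enter at p < 0.1, prune at p > 0.05),
ties broken by lowest p then lexicographic name. The screen's p-value
flavour (Wald) is a design choice; the source does not state whether
Wald, likelihood-ratio or chi-square screening was used. Because
enter/remove gates differ, the procedure can oscillate; a repeated-state
guard terminates the (deterministic) cycle. Subgroup items with
structurally missing values cannot enter the full-cohort multivariable
model. AIC (2k − 2logL), BIC (k ln n − 2logL) and logL are reported side
by side for the stepwise candidates. Adjusted ORs are exp(β) with Wald
intervals exp(β ± 1.96·SE).

In the headline model comparison the logistic model is refit with
exactly the four published predictors (a flag switches to data-driven
stepwise selection), so the comparison matches the published variable
lists rather than whatever a particular synthetic draw selects.

## ELM ensemble

Implemented from first principles. Per classifier: input weights uniform
on [−1, 1], hidden biases uniform on [0, 1] (the common ELM convention;
the source leaves the ranges open; both configurable), 30 sigmoid hidden
units, targets coded 0/1, output weights by minimum-norm least squares
(`lstsq`; a 1e-8 ridge solve is the fallback for a failed
factorization — 30 hidden units can exceed the rank spanned by the few
distinct binary rows of a 78-sample balanced set, and the minimum-norm
solution handles this without error). The per-classifier decision
threshold on the continuous output is 0.5. Features are the seven binary
items, unscaled; age is not a feature.

Ensemble: T = 100 under-samples (each all 39 positives plus 39 negatives
drawn uniformly without replacement), one master seed spawning one
independent substream per classifier, so T can grow without reshuffling
earlier members. The risk score is exactly 100 × votes/T, hence always a
multiple of 100/T in [0, 100].

Reported ML performance is apparent (resubstitution) by default — the
source does not state whether its figures are resubstitution or held
out, and the logistic figures are apparent, so the default keeps the two
models on the same footing; stratified k-fold scoring is available via
`cv=k`.

## Evaluation

ROC curves have one point per distinct score threshold plus endpoints;
AUC is trapezoidal, identical to the Mann–Whitney probability with ties
counted half (verified against an all-pairs oracle). The operating
cutoff minimizes √((1−TPR)² + FPR²) — the point nearest the (0, 1)
corner — with ties broken toward higher specificity, then lower
threshold; a positive call is score ≥ cutoff (the source does not state
the call convention). Proportion CIs are Wald on the probability scale,
clipped to [0, 1], matching the symmetric clipped style of the published
intervals; AUC CIs are nonparametric bootstrap (2000 percentile
resamples by default, seeded from the pipeline master seed; single-class
resamples are redrawn). Wilson/DeLong-style alternatives were considered
and left out: the published interval style is already matched, and the
bootstrap covers the AUC. Zero-denominator metrics are reported as
not-evaluable rather than raised.

## Problem sizes used in the checks

The simulation-based checks run at the sizes their questions require:
calibration of the generator at 5000 cases; odds-ratio recovery at 2000
cases × 100 replicates (mean log-OR within 10% of truth); stepwise
recovery at 500 cases × 200 replicates (all four true predictors, no
noise terms, in ≥ 80%); the ROC-ordering comparison at the study's own
39/156 over 50 seeds (the ensemble matches or beats the logistic AUC in
a majority, with both mean AUCs above 0.9); the selection-rule
calibration over 1000 null cohorts. The acceptance script reports
averages over 25 seeded replicates for the model comparison and uses the
same calibrated designs elsewhere.

## Known limitations

- Class-conditional independence is an idealization; real symptom
  clusters are dependent. The `rho` factor gives only exchangeable
  positive dependence.
- Apparent (resubstitution) performance overstates generalization for
  both models; the package reproduces that reporting choice rather than
  endorsing it.
- The Wald intervals and the separation flag are asymptotic devices
  applied to 39 cases; they describe the published analysis style, not
  best current practice (which would consider Firth penalization and
  conditional likelihoods under matching).
- No statistical test of the AUC difference is provided, only a paired
  bootstrap CI of the difference.
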