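# Methods

## The score and its automated derivation

The Pulmonary Embolism Severity Index is additive: age in years plus
fixed weights for ten binary components (male sex +10; history of
cancer +30, heart failure +10, chronic lung disease +10; heart rate
≥ 110 /min +20; systolic blood pressure < 100 mmHg +30; respiratory
rate ≥ 30 /min +20; temperature < 36 °C +20; altered mental status
+60; oxygen saturation < 90 % +20). Classes: I < 66, II 66–85,
III 86–105, IV 106–125, V > 125; "low risk" is score < 86 (classes
I–II). One published boundary statement gives class II as "66–86"
while the low-risk band is elsewhere defined strictly as < 86; we
resolve the off-by-one in favor of the strict < 86 cut, which matches
the standard index and keeps `low_risk ⇔ class ∈ {I, II}` exact.
Weights and boundaries are data (`PesiWeights`, `ClassBoundaries`), so
variants are configurable without touching the engine.

The automated calculator sees only what the EHR held at the trigger
instant (the CT-pulmonary-angiogram order in the validation setting):
every datum timestamped after `trigger_time` is invisible. This
causality rule is what makes documentation latency an error source,
and it is property-tested (polluting a snapshot with arbitrary
post-trigger data never changes the result). A `trigger` argument
(CLI `--at`) rescored at any other instant supports the
score-after-diagnosis deployment variant.

Component rules:

- **Comorbidities.** An entry on the active problem list or in past
  medical history (statuses `active` and `history` by default;
  `resolved` only when explicitly requested) matches a category if its
  code equals, or is an is-a descendant of, a category root and is not
  excluded. Exclusion sets default to empty; they exist because
  real-world value sets need carve-outs such as non-metastatic skin
  cancer. The shipped concept fragment is illustrative (a hand-built
  is-a graph over well-known SNOMED CT identifiers, 10–20 codes per
  category); institutional value sets load from a `child,parent` edge
  CSV plus a JSON category file. Problem-list and history entries are
  merged without precedence.
- **Vitals.** The extremum in the adverse direction per kind — max HR
  and RR, min SBP, temperature, and SpO₂ — over samples charted at or
  before the trigger. Missing kinds contribute no points and
  provenance "absent": the tool scores whatever is charted. Duplicate
  or contradictory rows at one timestamp are all kept; the extremum
  logic makes the adverse one decisive.
- **Oxygen criterion.** A disjunction evaluated over trigger-visible
  data: SpO₂ nadir < 90 %, supplemental flow > 2 L/min, flow
  > 2 L/min above the home oxygen requirement, or a respiratory-assist
  device (BiPAP, CPAP, venturi mask, high-flow, ventilator). The
  clauses are independent, so a patient on a chronic 4 L/min home
  regimen triggers the absolute clause even at baseline; we implement
  that literal reading and provide
  `suppress_absolute_flow_when_home_o2` (default off) for sites that
  want the absolute clause gated for home-oxygen patients. Provenance
  names the first qualifying datum in time order.
- **Altered mental status.** GCS < 14 charted at or before trigger, or
  an "altered mental status" chief concern — matched by coded concept
  or by case-insensitive text, since production chief-complaint fields
  are coded inconsistently across sites.
- **Sex.** Sex assigned at birth when recorded, otherwise
  administrative sex with a logged warning. The fallback is exactly
  where the sex-conflation error enters.

## Synthetic cohorts and the error model

`generate_cohort` draws paired `(truth, documented)` snapshots. The
truth marginals default to a consecutive adult CT-PE cohort at a
tertiary ED: age truncated-normal mean 58.2 (SD 17.7, min 18), 43.8 %
male, comorbidity prevalences 37 % cancer / 17.6 % heart failure /
41 % chronic lung disease, 10 % first-visit patients. Values not fixed
by that setting were chosen once as typical ED flowsheet behavior:
two samples per vital kind in the 90 minutes before the trigger, with
truncated-normal parameters HR (88, 18), RR (18, 5), SBP (128, 22),
temperature (36.8, 0.6) °C, SpO₂ (96.5, 3) %; 3 % altered mental
status; 8 % on supplemental oxygen; 3 % with a 2 L/min home oxygen
requirement. Vitals are sampled independently per kind — no
physiologic coupling — because the engine consumes only extremes.

`ErrorModel` rates are per-patient marginal probabilities of a
score-affecting documentation error, one per error component, realized
through the mechanisms an EHR actually exhibits:

- *Comorbidity errors*: when the truth carries the comorbidity, every
  qualifying code is omitted from the documented snapshot (history not
  entered or updated by trigger time); when it does not, a stale
  spurious entry appears. Either direction flips the component flag,
  so the injected rate is identically the marginal error rate — which
  is what lets an evaluation on a large simulated cohort recover the
  injected rates to binomial precision.
- *Vitals errors*: the threshold-crossing samples of one crossing kind
  (HR, SBP, RR, or temperature) are re-timestamped 30 minutes after
  the trigger — measured before the order, entered after — or, when no
  true crossing exists, a spurious adverse HR sample is charted. SpO₂
  is deliberately not delayed: its flag is entangled with the oxygen-
  device clauses, so delaying it would not guarantee a score effect.
- *Sex conflation*: sex assigned at birth becomes unknown and the
  administrative field carries the opposite value.

First-visit patients multiply the comorbidity omission rates by 3
(capped at probability 1): a problem list cannot predate the first
encounter, and validation data show agreement roughly halves its odds
on first visits. The multiplier's magnitude is a design choice — the
direction is evidenced, the size is not identifiable from published
marginals. Default rates (cancer 0.07, heart failure 0.027, chronic
lung disease 0.045, vitals 0.046, sex 0.002) are calibrated so that
with the multiplier acting on 10 % first visits the marginal component
error rates come out at 8.4 / 3.2 / 5.4 / 4.6 / 0.2 % — the error
profile of a real single-center validation.

`score_pair` computes the gold-standard score from `truth`, the
automated score from `documented`, and attributes any total-score gap
by substitution: components are grouped as cancer, heart failure,
chronic lung disease, vitals (the four vital criteria plus the oxygen
flag), and other (sex, mental status); the tagged set is the smallest
group subset whose joint truth-substitution brings the documented
total closest to (normally exactly onto) the truth total. For a single
discrepant component this is the plain "substituting it moves the
total toward truth" rule; the subset search exists because
opposite-sign collisions (an omission next to a spurious entry) defeat
any single substitution. If totals differ and no substitution helps,
the record is tagged `other`, preserving the invariant that tags are
empty exactly when the totals agree.

## The study replica

`build_study_replica` reconstructs, with no randomness, a 500-record
paired-score table hitting every published marginal of the validation
study simultaneously: 394 exact matches; 477 binary-band and 442 class
agreements; the 23 band discordances split 15 automated-low vs 8
automated-high; 203 automated-low-risk patients with class counts
112/91/84/80/133; 50 first visits; 40 acute-PE cases; component-error
tags 42 cancer / 16 heart failure / 27 chronic lung disease / 23
vitals / 1 other. Where the joint distribution is not published the
construction takes a minimal completion: the 109 tags cover the 106
mismatched records via exactly three doubly-tagged {cancer, vitals}
rows; mismatch score pairs are chosen so each tag's weight delta is
arithmetically consistent (e.g. a cancer tag moves the total by 30, a
vitals tag by 20); 33 of the 40 acute-PE rows are exact matches so the
published acute-PE subset accuracy (82.5 %) also reproduces; and 18 of
the 50 first visits sit among the mismatches, which reproduces the
published direction (and approximate size) of the first-visit odds
ratio. Exact-match totals cycle through five representative scores per
class so the Bland–Altman series is non-degenerate. A consistency
check recounts every marginal at construction time and fails loudly on
drift.

The replica is a marginal reconstruction, not patient-level data: any
statistic not pinned by the published marginals (κ on classes, the
odds ratios, Bland–Altman spread) reflects the completion choices, and
the package does not claim those values match the unpublished
patient-level ones.

## Statistical methods

- **Exact binomial CI**: Clopper–Pearson, the interval that inverts
  the exact binomial test (beta quantiles; lower bound 0 at k = 0,
  upper bound 1 at k = n). Tests pin it to an independent bisection
  oracle on the regularized incomplete beta function at 1e-8 and check
  conservative coverage by simulation. The published source did not
  name its exact CI flavor; Clopper–Pearson reproduces the printed
  74.9–82.3 % interval within 0.2 percentage points (our bounds print
  as 75.0–82.3), and the residual is rounding/method ambiguity.
- **Cohen κ** on the five-class labels: κ = (p_o − p_e)/(1 − p_e) with
  p_e from marginal products; large-sample SE
  √(p_o(1−p_o)/n)/(1−p_e) for the Wald CI; undefined (NaN) when both
  raters use a single label. Cross-checked against scikit-learn's
  implementation in the test suite.
- **Odds ratios**: separate univariable logistic fits of exact
  agreement on each predictor (gold-standard low-risk; first visit),
  Newton/IRLS via statsmodels (tolerance 1e-10, max 50 iterations);
  Wald CI and p. Univariable models are the default because published
  validation tables report predictors jointly-unadjusted as often as
  adjusted; a 2×2 pre-check reports separation (an empty cell) as
  non-estimable instead of fitting. For a single binary predictor the
  ML odds ratio equals the cross-product ratio ad/bc, which the tests
  assert at 1e-6.
- **Bland–Altman**: mean difference of paired totals, sample-SD
  limits mean ± 1.96 SD, with the per-point (mean, difference) series
  exported for plotting.
- **Component-error homogeneity**: the error proportions are compared
  with a chi-square test of homogeneity on the 2×5 table of
  per-patient binary indicators; a one-way ANOVA on the same
  indicators is reported alongside, for continuity with validation
  reports that phrase this comparison as ANOVA. On binary indicators
  the two are asymptotically equivalent; chi-square is the standard
  choice.
- **Nesting invariant**: an exact score match implies a class match
  implies a band match; `evaluate` asserts it on every run.

## Numerical and degenerate-input choices

Vital-extreme ties resolve to the earliest-charted sample; provenance
for the oxygen criterion names the first qualifying datum in time
order. Unknown enum values in source data degrade to `other`/`unknown`
with a warning rather than failing the record, but out-of-range values
(GCS outside 3–15, SpO₂ outside 0–100 %, temperature outside
25–45 °C) are rejected with the record index and field named — never
clamped. Fahrenheit temperatures convert at ingest, before validation,
so the engine and its thresholds stay Celsius-pure. Empty record lists
are errors for `evaluate` (no denominators) but valid for readers and
matchers.

## Problem sizes

The test suite exercises the pipeline identity at n = 1,000, error-
rate recovery at n = 20,000 (3-SE binomial bands), prevalence
convergence at n = 2,000, CI coverage with 2,000 replicate draws per
true proportion, and ancestry-oracle agreement on random DAGs up to
200 nodes. These sizes make the binomial bands tight enough to detect
a misimplemented rate while keeping the whole suite under a minute of
compute for the statistical parts.

## Limitations

The simulator emulates marginal prevalences and error rates, not joint
clinical structure: vitals are uncoupled, comorbidities independent,
and error processes independent across components, so passing tests
demonstrate correctness of extraction, scoring, attribution and
statistics — not performance on real EHR data, where errors cluster
within patients and documentation practices vary by site. The shipped
concept sets are illustrative, not institutional. The replica
reproduces published marginals only (see above). Outcome prediction
(30-day mortality), simplified-PESI variants, and any live EHR
integration are out of scope.
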