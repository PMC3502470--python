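# Methods

## Instrument model

The MSQ item bank is a declarative JSON document (30 items with section,
subscale, and point range) validated on load: exactly 30 items with ids
1–30, subscale cardinalities ROM 5 / strength 1 / pain 6 / work-daily 9 /
sport-recreation 6 / quality-of-life 3, the objective section equal to
ROM ∪ strength, and a raw maximum equal to the sum of item maxima (314 for
the default bank).  Item ids follow the printed order of the form: 1–5 ROM
(flexion, abduction, internal rotation, external rotation, range of the
hand), 6 strength, 7–12 pain, 13–21 work/daily, 22–27 sport/recreation,
28–30 quality of life.  The original form's photograph-anchored answer
levels are represented as the 0–10 integer scale; item labels are
descriptive placeholders, since only the structure (not the verbatim item
text) is published in machine-readable form.

Respondent records carry cover-sheet demographics plus an `item_id → points`
mapping.  The strength item may instead be given as the raw lifted weight
(0–12 kg on a 0.5 kg grid).  Validation flags incompleteness and
out-of-range answers as issues — answers are never clamped and incomplete
questionnaires are never silently imputed at this layer, mirroring the
practice of excluding incomplete forms from analysis.

## Scoring rules and policies

* **Percent score.** `MSQ% = 100 · raw / 314`, kept at full precision
  internally and displayed as a round-half-up integer (the convention that
  reproduces all printed structural percentages: 50/314 → 16, 24/314 → 8,
  74/314 → 24, 240/314 → 76, 60/314 → 19, 90/314 → 29, 30/314 → 10).
  A known quirk of the source material: a raw score of 310 is 98.7 % under
  this rule, although the matching printed percent maximum is 89; the
  stated arithmetic is implemented and the discrepancy is left as
  documented.
* **Strength weight rule.** The narrative description ("each 500 g counts
  2 points") multiplied over the 24 half-kilogram steps would yield 48
  points, contradicting the stated 24-point maximum at 12 kg.  The default
  policy (`per_kg`) reconciles both endpoints with 2 points per kilogram;
  the literal reading (`literal_500g`: 2 points per 500 g, saturating at
  6 kg) is selectable by configuration.
* **Missing answers.** `strict` (default) refuses to produce a total and
  lists the missing items.  `prorate` must be enabled explicitly: each
  partially answered subscale is rescaled to its own maximum (round half
  up) and the report is flagged `prorated`.  A completely unanswered
  subscale contributes zero — prorating cannot invent information about a
  domain with no answers — which keeps `raw = objective + subjective`
  exactly.

## Reference engines and crosswalk

SPADI, DASH and CMS are scored by their canonical published rules (SPADI
subscale = item mean × 10, total = subscale mean, conventionally higher =
worse with an explicit `inverted` orientation returning 100 − total for comparison on the higher = better scale; DASH =
((mean of answered − 1)/4)·100 with at most 3 of 30 items missing; CMS =
sum of pain 0–15, ADL 0–20, ROM 0–40, strength 0–25).  SPADI items are
modelled on a 0–10 numeric scale rather than a 100 mm analogue line; totals
are invariant to that choice.  The CMS strength component converts the
self-assessed bag lift at one point per pound (2.2046 lb/kg, round half
up, cap 25); the bag lift is the only strength source modelled, as no
dynamometer protocol applies to a self-assessment form.

The crosswalk is data, not code: versioned JSON entries
`(target instrument, component, source items, transform, range)`.  Because
the exact item-to-item correspondence of the original form is not published
in the main text, the shipped default is a *documented reconstruction* from
the instrument structure — ROM → CMS ROM, bag lift → CMS strength, pain →
{CMS pain, SPADI pain, DASH symptom block}, work/daily + sport → {CMS ADL,
SPADI disability, DASH function block}, quality of life → DASH
social/emotional block — with linear (or inverting) rescaling of subtotals
onto component ranges.  DASH entries carry `target_items` weights (6/21/3)
so the 30-item mean formula applies; the engines accept real-valued items so
crosswalk pseudo-responses score exactly.  Users can replace the document
wholesale; `validate_crosswalk` reports dangling references, uncovered
components and range mismatches.  Boundary exactness (all-max ↔ best score,
all-min ↔ worst) and item-wise monotone consistency hold for any complete
monotone crosswalk of this form and are enforced by tests.

## Cohort simulator

Each synthetic patient carries a latent function level θ ∈ [0, 1].  For each
instrument the patient answers, a perturbed copy
θᵢ = clip(θ + εᵢ, 0, 1), εᵢ ~ N(0, σ²_cross) drives all items of that
instrument; each item adds N(0, (σ_item · range)²) noise, a fixed
difficulty offset, and is clamped and rounded onto its response grid
(SPADI/DASH items oriented higher = worse; the MSQ bag lift on the 0.5 kg
grid).  The difficulty offsets spread uniformly over one response step
within each averaging group — the deterministic analogue of item
difficulties in a graded-response model.  Without them every item of an
instrument would collapse to a single quantized value, and the 5-level DASH
grid alone would cap the noiseless original-vs-calculated correlation near
0.93; with them, noiseless correlations reach unity to well within
two-decimal reporting precision (|r| ≥ 0.9996), which is what "r → 1 as
noise → 0" can mean for discrete instruments.

Defaults (the simulated study conditions, chosen once):

| parameter | default | rationale |
|---|---|---|
| `n_patients` | 51 | size of the validation cohort emulated |
| latent | Beta(4, 3) | reproduces the observed MSQ percent distribution (mean ≈ 58, SD ≈ 17.5) |
| `item_noise_sd` | 0.08 of item range | with σ_cross below, replicate-mean concurrent validity lands at r ≈ 0.91–0.94, the published agreement level |
| `cross_instrument_noise_sd` | 0.04 latent units | as above; dominates pair-level disagreement |
| `missing_rate` | 0 | incompleteness is opt-in for testing exclusion logic |

All draws flow from one `numpy` generator seeded by `SimConfig.seed`, so
cohorts replay exactly.  The fixture cohort pins demographic margins by
exact-count assignment (independent shuffles of per-attribute count lists,
34 dominant-affected patients chosen by permutation) rather than sampling,
so the published counts — 51 patients, 36/15 sex split, 41/10 handedness,
34 dominant-side affected, age bands 12/26/13 across 20–80 years,
employment 33/3/14/1, and the 14-diagnosis case mix summing to 51 — are
reproduced exactly at any seed.

What the simulator does *not* emulate: diagnosis-specific response
profiles, differential item functioning, floor/ceiling pathology, response
styles (acquiescence, central tendency), or item-level missingness
structure.  Passing validation tests on simulated cohorts therefore shows
that the pipeline is internally consistent and that agreement behaves
correctly as a function of noise — not that the crosswalk reproduces any
particular clinical population's scores.

## Validity statistics

Pearson's r with a two-sided p-value from t = r·√((n−2)/(1−r²)) on n−2 df
(equivalent to the simple-regression slope test, which resolves the
ambiguity between correlation-t and regression-F for this design);
least-squares slope/intercept; Mean/SD/Max/Min/Range descriptives with the
sample (n−1) standard deviation; Tukey box summaries using
linear-interpolation quartiles (fixed explicitly, since quartile
conventions differ across software) with whiskers at the most extreme
observations within 1.5 × IQR and points beyond flagged as outliers.
Calculated scores inherit the MSQ's higher = better orientation, so the
native DASH pair correlates negatively; the inverted pair (original DASH
flipped to higher = better) has the same |r| with positive sign, and both
are reported.

## Problem sizes and numerics

The test suite and acceptance script use: 1,000 random responses for
scoring/crosswalk monotonicity and the brute-force raw-score oracle; 3,000
patients for the law-of-large-numbers check on the latent mean; 200 seeded
51-patient replicates for the replicate-mean correlations; 100 random
series for the statistics-vs-naive-oracle agreement at 1e-12.  Rounding is
round-half-up wherever an integer is displayed (percent display, subscale
weights, CMS pounds), with full precision retained internally.  Degenerate
inputs fail loudly: zero-variance series, constant predictors, empty
series, out-of-range scores and off-grid weights all raise typed errors
rather than returning NaN.
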