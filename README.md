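# msq — Munich Shoulder Questionnaire scoring and validation toolkit

The Munich Shoulder Questionnaire (MSQ) is a 30-item patient self-assessment
of shoulder function designed so that a single form yields, at the same time,
the three most widely used shoulder outcome scores: the Shoulder Pain and
Disability Index (SPADI), the Disabilities of the Arm, Shoulder and Hand
score (DASH) and the Constant–Murley Score (CMS).  This package is for
shoulder surgeons, outcome researchers and methodologists who want to score
MSQ response tables reproducibly, derive the three established scores from
them, and quantify how well the derived ("calculated") scores agree with
directly administered originals.

## The instrument and its scores

The MSQ has an objective section — five range-of-motion items (flexion,
abduction, internal/external rotation, range of the hand; 0–10 points each)
and one strength item, a standardised bag lift in 90° abduction scored 2
points per kilogram up to 12 kg (24 points) — and a subjective section of 24
items (six pain, nine work/daily activity, six sport/recreation, three
quality of life; 0–10 points each).  The raw score

```
raw = Σ item points ∈ [0, 314],    MSQ% = 100 · raw / 314
```

is reported as a percentage, higher = better function.  Section maxima are 74
(objective, 24%) and 240 (subjective, 76%); subscale weights are ROM 16%,
strength 8%, pain 19%, work/daily 29%, sport 19%, quality of life 10%.

Derived scores come from a declarative, versioned crosswalk: each entry maps
a set of MSQ items onto one component of a target instrument (e.g. the ROM
subtotal, 0–50, rescales linearly onto the CMS ROM component, 0–40; the bag
lift feeds the CMS strength component at one point per pound, capped at 25;
orientation flips for the inversely scaled DASH are explicit transforms).
Component values are then scored by the same engines used for directly
administered responses: SPADI subscales are item means × 10 averaged,
DASH = ((mean item − 1)/4) · 100 with ≤ 3 missing items tolerated, CMS is
the component sum on 0–100.

Concurrent validity between original and calculated scores is assessed with
Pearson's r (two-sided p from the t-transform on n−2 df), a least-squares
regression line, Mean/SD/Max/Min/Range descriptives and Tukey box summaries.
Because the DASH scale runs inversely (higher = worse) while calculated
scores inherit the MSQ's orientation, the native DASH pair correlates
negatively; the toolkit reports both orientations.

Because no patient-level cohort is publicly available, the package includes
a latent-trait simulator: each synthetic patient has one function level
θ ∈ [0, 1] that drives all four instruments' items (with per-item difficulty
offsets, item-level noise, and instrument-level noise), so the agreement
between paired instruments is a controllable input.  A fixture generator
pins the demographic margins of a 51-patient surgical shoulder clinic
(36 male / 15 female, 41 right-handed, 34 dominant-side affected, a
14-diagnosis case mix).

## Worked example

```python
import msq

inst = msq.load_instrument()
demo = msq.Demographics(respondent_id="pat-017", age=48, sex="female",
                        affected_side="right", hand_dominance="right",
                        assessed_side="right", employment="paid work")
answers = {1: 7, 2: 6, 3: 5, 4: 6, 5: 7,            # range of motion
           7: 5, 8: 4, 9: 6, 10: 5, 11: 4, 12: 5,   # pain
           13: 6, 14: 5, 15: 4, 16: 7, 17: 7, 18: 6, 19: 6, 20: 6, 21: 8,
           22: 4, 23: 3, 24: 5, 25: 4, 26: 6, 27: 4,
           28: 7, 29: 6, 30: 6}
resp = msq.MSQResponse(demographics=demo, answers=answers, lifted_weight_kg=5.0)

report = msq.section_subtotals(resp, inst)
print(f"raw={report.raw}  percent={report.percent:.1f}  display={report.percent_display}")
print(f"objective={report.objective_subtotal}  subjective={report.subjective_subtotal}")

derived = msq.derive_scores(resp)
print(f"cCMS={derived.ccms:.1f}  cSPADI={derived.cspadi_inverted:.1f}  "
      f"cDASH={derived.cdash:.1f} (inverted {derived.cdash_inverted:.1f})")
```

prints

```
raw=170  percent=54.1  display=54
objective=41  subjective=129
cCMS=53.9  cSPADI=51.2  cDASH=46.2 (inverted 53.8)
```

The patient scores 170 of 314 raw points (54% function).  The 5 kg bag lift
contributes 10 MSQ points and 11 CMS strength points (11 lb).  The calculated
CMS (53.9, higher = better), SPADI (51.2, reported here in the higher =
better orientation) and DASH (46.2 on its native higher = worse scale, 53.8
inverted) all place the patient near mid-scale, consistently with the MSQ
percentage.

The same operations are available from a shell:

```
msq simulate --n 51 --seed 7 --fixture --out cohort/
msq score    --input cohort/msq_responses.csv --out report/
msq crosswalk --input cohort/msq_responses.csv --out derived.csv
msq validate --original orig.csv --calculated calc.csv --out validation.json
msq report   --cohort cohort/ --out report/
```

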