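# cannascreen

Rule-based NLP pipeline for detecting cannabis-use documentation in
pediatric clinical notes, with a synthetic-corpus generator for exact,
privacy-free evaluation.

## What it does

Free-text clinical notes often record substance use that never reaches
structured diagnosis codes. `cannascreen` implements a keyword-screening
pipeline for cannabis mentions and rolls sentence-level polarity up to
patient-level status:

1. **Lexicon with misspelling expansion** — a curated seed dictionary
   (marijuana, cannabis, CBD, THC, weed, MJ, plus prescription
   cannabinoids) is expanded against a corpus vocabulary using cosine
   similarity of character 1–3-gram count vectors, so spelling variants
   like *marijuahana* are retrieved without hand-listing them.
2. **Note screening** — whole-token keyword retrieval, context exclusion
   for the two ambiguous terms (*CBD* as common bile duct, *weed* as
   allergen), and an age filter (patients under 7 at note time are
   excluded from use analysis; their mentions are household exposure).
3. **Sentence classification** — keyword-bearing sentences are labeled
   positive/negative for patient use by a deterministic cue labeler
   (toxicology > negation > third-party attribution > affirmation >
   counseling), with a trainable TF-IDF + logistic-regression baseline
   as an alternative backend.
4. **Cohort aggregation** — patient status (positive / documented
   negative / undocumented), per-year trend tables, and a cross-check
   against ICD-9/ICD-10/SNOMED CT cannabis diagnosis codes.
5. **Disparity models** — adjusted odds ratios for documentation and
   positive use across sex, race, and the Social Vulnerability Index,
   via logistic GLM (or a random-intercept GLMM variant).
6. **Synthetic generator** — a corpus simulator that plants known
   demographics, documentation/positivity odds ratios, legalization
   step-ups, confounder sentences, and misspellings, so every pipeline
   stage can be scored against exact ground truth.

## Worked example: misspelling expansion

The method's core primitive is cosine similarity over combined character
1–3-gram **count** vectors (lowercased). For the seed *marijuana* and the
candidate *marijuahana*:

```
$ python examples/01_misspelling_expansion.py
dictionary terms: cannabidiol, cannabis, cbd, cesamet, dronabinol, epidiolex, marijuana, marinol, mj, syndros, tetrahydrocannabinol, thc, weed

profile('marijuana'):   A x3, JU x1 (no AH)
profile('marijuahana'): A x4, H x1, AH x1, AHA x1
cosine similarity = 0.9015 -> rounds to 0.9
threshold for 'marijuana' is 0.70: ACCEPT

candidate vocabulary: marijuahana, marijuanna, cannabiss, canabis, epidiollex, fracture, needed, ragweed, seaweed, patient
  canabis      -> cannabis   cos=0.894 (threshold 0.70)
  cannabiss    -> cannabis   cos=0.949 (threshold 0.70)
  epidiollex   -> epidiolex  cos=0.921 (threshold 0.70)
  marijuahana  -> marijuana  cos=0.901 (threshold 0.70)
  marijuanna   -> marijuana  cos=0.926 (threshold 0.70)
rejected (below every threshold): fracture, needed, patient, ragweed, seaweed
```

0.90 ≥ 0.70, so the variant joins the lexicon. *weed* carries a stricter
curated threshold (0.85) because common English words (*needed*,
*ragweed*) otherwise clear the default.

Screening and classification on hand-written notes:

```
$ python examples/02_screen_and_classify.py
n01  screened_in          Presents with knee pain after soccer. Pt admits to smoking...
      sentence 1 [marijuana] -> POSITIVE  "Pt admits to smoking marijuana daily."
n02  screened_in          Denies drugs or alcohol. Urine tox screen: positive for am...
      sentence 1 [cannabis] -> POSITIVE  "Urine tox screen: positive for amphetamines and cannabis."
n03  screened_in          He has not tried any other drugs and denies any use of mar...
      sentence 0 [marijuana] -> NEGATIVE  "He has not tried any other drugs and denies any use of marijuana, cocaine, or other drug abuse."
n04  excluded_bile_duct   Ultrasound shows the CBD dilated to 9 mm, gallbladder wall...
n05  excluded_allergy     Allergy panel positive for ragweed and weed pollen....
n06  excluded_underage    Birth Hx: Exposed to maternal THC in utero....
n07  no_mention           Ankle sprain, RICE protocol advised. Return in two weeks....
```

Note n02 shows the precedence design: a toxicology *positive for …
cannabis* overrides the denial earlier in the note.

## Usage

As a library (see `examples/` for narrative walk-throughs):

```python
from cannascreen import build_lexicon, screen_notes, rule_based_label

lexicon = build_lexicon()
decisions = screen_notes(notes, lexicon, birth_dates)
```

As a CLI:

```
cannascreen simulate --out-dir data/ --n-patients 500 --seed 7
cannascreen run --notes data/notes.jsonl --patients data/patients.csv \
    --diagnoses data/diagnoses.csv --out-dir out/
```

`run` executes lexicon → screen → classify → cohort → disparity and
writes every intermediate plus a manifest whose counts reconcile with
the outputs. Exit codes: 0 success, 2 schema error, 3 stage failure.

## Evaluation on synthetic ground truth

Real clinical corpora are private, so evaluation uses the planted-truth
generator (`examples/03_synthetic_pipeline.py`,
`examples/04_disparity_recovery.py`): screening recall and filter
soundness are checked note-by-note against gold statuses, classifier
accuracy against planted label noise, and disparity estimates against
planted odds ratios — e.g. a planted black-vs-white OR of 3.22 is
recovered as 3.12 (95% CI 2.72–3.58) at n = 20,000.

## Reproduction

```
python -m pytest -q tests/                     # full suite incl. acceptance
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the worked-example cosine (target `t1`:
0.90 to two decimals over the 28 distinct n-grams of the two tokens).
All randomness flows from explicit seeds; `simulate` and the generator
are byte-deterministic for a fixed config.

See `docs/methods.md` for the statistical details and design decisions.
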