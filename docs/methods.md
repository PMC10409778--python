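# Methods

This note documents the statistical and algorithmic choices behind
`cannascreen`, module by module.

## Lexicon and misspelling expansion (`cannascreen.lexicon`)

Tokens are lowercased; non-alphabetic characters are stripped. A token's
profile is the multiset of all contiguous character substrings of
lengths 1–3, kept as **raw counts** in a single combined vector (not
binary presence, not per-length averaging). Similarity between two
profiles is the textbook cosine `A·B / (|A||B|)` over the union of
n-gram keys. For tokens shorter than the maximum n, only realizable
lengths contribute.

A corpus vocabulary word becomes an accepted misspelling of a dictionary
term when (a) it is not itself a dictionary term, (b) its cosine to the
term meets that term's threshold, and (c) the term is the
highest-similarity match among qualifying terms (lexicographic
tie-break). The default threshold is 0.70. Short terms (`cbd`, `thc`,
`mj`, anything under 4 characters) are never expanded: their n-gram
profiles are too small to discriminate. *weed* carries a curated
per-term threshold of 0.85 because ordinary English words land in the
0.72–0.80 band (`needed` 0.72, `ragweed` 0.74) while genuine
single-edit variants of *weed* score ≥ 0.88; this mirrors the
human-in-the-loop curation step of the original method.

## Screening (`cannascreen.screening`)

Keyword retrieval matches whole tokens case-insensitively (longest
alternative first); `mj` is only accepted as uppercase `MJ` or with a
trailing colon (template field), never as lowercase prose. A note whose
only hits are *CBD* together with biliary context (gallbladder, bile
duct, dilated, …) is excluded as a common-bile-duct mention; a note
whose only hits are *weed* with allergy context (pollen, allergy,
rhinitis, …) is excluded as an allergen mention. Any unambiguous seed in
the same note overrides the exclusion. Patients younger than 7 years at
note time — age computed as `(note_date − birth_date) / 365.25`,
boundary inclusive — are excluded from use analysis (their mentions are
household exposure). Order: keyword → context exclusion → age →
sentence extraction. The sentence splitter protects decimal numbers and
clinical abbreviations (prn., Dr., Rx., …).

## Sentence classification (`cannascreen.classify`)

The deterministic rule labeler applies cue precedence within a
keyword-bearing sentence:

1. toxicology `positive for … <term>` → positive (overrides a denial in
   the same sentence);
2. toxicology negative, or explicit negation (denies, no history of,
   never used, quit, …) → negative;
3. third-party attribution (mother, brother, in utero, pregnancy, …)
   without a patient-attributed report marker → negative;
4. affirmation (admits/reports/endorses + term, smokes/uses + term,
   `term use`, `MJ: +`) or prescription-cannabinoid context
   (marinol/dronabinol/… with RX/mg/tab cues) → positive;
5. counseling-only discussion and everything else → negative.

A note is positive when any of its sentences is positive.

The trainable baseline is a `FeatureUnion` of word 1–2-gram and
character (within-word-boundary) 2–4-gram TF-IDF vectors feeding
`LogisticRegression` (liblinear). Splits are assigned 80/10/10 greedily
by note, never splitting a note across partitions. `evaluate` reports
the confusion cells, sensitivity, specificity, and AUROC computed as
the tie-corrected Mann–Whitney rank statistic (identical to
`sklearn.metrics.roc_auc_score`, implemented directly for per-call
speed); AUROC is `None` when the gold labels contain one class.

## Cohort aggregation (`cannascreen.cohort`)

Patient status is a partition: *positive* (any positive sentence),
*negative_documented* (screened-in note, no positive sentence),
*undocumented* (everything else, including excluded-only patients).
Trend tables report per-year documentation and positivity as
percentages of all notes and of orthopedic/sports-medicine (OSM) notes
with OSM denominators; a patient is newly positive only in the year of
their first positive note. Diagnosis matching normalizes ICD codes by
removing dots and matches by prefix (F12.20 matches F12); SNOMED CT
concepts match exactly. The cross-check reports the intersection of
NLP-positive patients with code-diagnosed patients as a percentage of
NLP positives, rounded to one decimal.

## Disparity models (`cannascreen.disparity`)

Two settings: documentation (any mention vs. none, all patients) and
positive use (positive vs. all others, or vs. documented negatives).
Covariates: female (reference male), race indicators (reference white),
SVI per 0.01 units. Unknown sex and unavailable race get their own
indicator columns so those patients remain in the model without
contaminating the reported contrasts; rows with missing SVI are dropped
and logged. The default estimator is a binomial GLM with logit link —
with one row per patient there is nothing to cluster on — and a
variational-Bayes random-intercept GLMM is available when a cluster
column (e.g. clinic site) exists. Wald 95% CIs; coefficients with
|log aOR| > 15 are flagged as probable separation.

## Synthetic generator (`cannascreen.synth`)

Each patient draws sex, race (study-cohort proportions), and SVI
(Beta(0.628, 1.690); mean 0.271), then a care window and
Poisson-distributed notes per year. Documentation of a note is
Bernoulli with logit = base (−4.2) + covariate effects + ln 2 step-ups
in 2012 and 2016 (legalization cutovers); conditional on documentation,
positivity is Bernoulli with logit base 0.9946 (73% balance) + its own
covariate effects. Documented notes render one cue sentence from nine
template families; `label_noise` is the probability that the rendered
cue polarity disagrees with the gold label. Non-documented notes may
carry a confounder sentence (bile-duct CBD or allergen weed).
Misspellings are injected by duplication, transposition, or vowel/'h'
digraph insertion; terms shorter than 6 characters receive only
duplication/transposition, since any insertion moves a 4–5-character
n-gram profile below every defensible expansion threshold. Patients
under 7 at note time only ever receive household-exposure sentences.
Cannabis diagnosis codes are planted on 14.5% of positive patients.
One `numpy` Generator seeded from the config drives all draws, so a
config is byte-reproducible.

## Verification strategy

Unit tests pin hand-computed examples (the 0.9015 cosine and its
n-gram count fragments; forced confusion-matrix arithmetic) and check
implementations against independent oracles: brute-force substring
enumeration for profiles/cosine, all-pairs brute force for expansion,
pair-counting for AUROC, exhaustive enumeration of all ≤ 8-item inputs
for `evaluate`, and a character-walk normalization oracle for ICD
matching. Corpus-level properties are verified against the generator's
planted truth: screening recall and filter soundness of 1.0, classifier
accuracy under planted noise, recovery of planted odds ratios with
calibrated null rejection rates, and per-year trend rates within
binomial bounds of the planted documentation probabilities.
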