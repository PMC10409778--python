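"""Sentence-level positive/negative cannabis-use classification.

Two backends share the same contract: a deterministic rule-based labeler
(negation- and attribution-aware cue matching) and a trainable TF-IDF +
logistic-regression baseline. A note is positive when any of its
keyword-bearing sentences is positive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import FeatureUnion, Pipeline

from .lexicon import Lexicon

__all__ = [
    "LabeledSentence",
    "UseLabel",
    "EvalMetrics",
    "assign_splits",
    "rule_based_label",
    "train_classifier",
    "predict_scores",
    "evaluate",
    "ClassifierModel",
    "TrainConfig",
]

POSITIVE, NEGATIVE = "positive", "negative"


class ClassifyError(ValueError):
    pass


@dataclass
class LabeledSentence:
    sentence_text: str
    label: str
    note_id: str
    split: str = "unassigned"

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise ClassifyError(f"label must be positive/negative, got {self.label!r}")


@dataclass(frozen=True)
class UseLabel:
    note_id: str
    sentence_index: int
    label: str
    score: float  # probability of positive use


@dataclass(frozen=True)
class EvalMetrics:
    accuracy: float
    auroc: float | None
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int


def assign_splits(
    sentences: list[LabeledSentence],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> list[LabeledSentence]:
    """Assign train/valid/test splits, grouped by note.

    Sentences sharing a note_id always land in the same split, so a note
    never leaks across the train/test boundary. Deterministic given seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ClassifyError(f"fractions must sum to 1, got {fractions}")
    note_ids = sorted({s.note_id for s in sentences})
    if len(note_ids) < 3:
        raise ClassifyError(f"need >= 3 distinct notes to split, got {len(note_ids)}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(note_ids))
    n_sent = {nid: 0 for nid in note_ids}
    for s in sentences:
        n_sent[s.note_id] += 1
    total = len(sentences)
    targets = [fractions[0] * total, fractions[1] * total, fractions[2] * total]
    names = ["train", "valid", "test"]
    assignment: dict[str, str] = {}
    filled = [0.0, 0.0, 0.0]
    # round-robin greedy: put each note into the most underfilled split
    for nid in order:
        deficits = [targets[i] - filled[i] for i in range(3)]
        k = int(np.argmax(deficits))
        assignment[nid] = names[k]
        filled[k] += n_sent[nid]
    # guarantee every split is non-empty when >= 3 notes exist
    for k, name in enumerate(names):
        if filled[k] == 0:
            donor = max(range(3), key=lambda j: filled[j])
            for nid in order:
                if assignment[nid] == names[donor]:
                    assignment[nid] = name
                    filled[k] += n_sent[nid]
                    filled[donor] -= n_sent[nid]
                    break
    return [replace(s, split=assignment[s.note_id]) for s in sentences]


# -- rule-based baseline -------------------------------------------------

_NEGATION = re.compile(
    r"\b(denies|denied|deny|negative for|no (?:use|history|current use|report)|"
    r"not (?:tried|used|using)|never (?:used|tried|smoked)|quit|abstains)\b"
)
_THIRD_PARTY = re.compile(
    r"\b(mother|father|mom|dad|brother|sister|grandmother|grandfather|uncle|aunt|"
    r"sibling|roommate|household|maternal|paternal|in utero|pregnancy|prenatal|"
    r"family member|friend)\b"
)
_PATIENT_MARKER = re.compile(r"\b(pt|patient|he|she|they)\s+(admits|reports|endorses|states)\b")
_COUNSELING = re.compile(
    r"\b(discussed|discussion|counsel(?:ed|ing)?|education provided|"
    r"risks and benefits|interactions? of)\b"
)
_RX_CONTEXT = re.compile(r"\b(rx|prescri\w*|refill|dose|mg|tab|medication)\b|\d+\s*mg")


def _term_alt(lexicon: Lexicon) -> str:
    terms = sorted(
        set(lexicon.all_terms()) | set(lexicon.variant_to_term()),
        key=lambda t: (-len(t), t),
    )
    return "(?:" + "|".join(re.escape(t) for t in terms) + ")"


def _sentence_cues(text: str, lexicon: Lexicon) -> dict[str, bool]:
    low = text.lower()
    term = _term_alt(lexicon)
    med_terms = set(lexicon.medical_terms)
    med_terms.update(
        v for v, t in lexicon.variant_to_term().items() if t in med_terms
    )
    medical = "(?:" + "|".join(re.escape(t) for t in sorted(med_terms, key=lambda t: (-len(t), t))) + ")"
    tox_pos = re.search(r"positive\s+for\b[^.;:]*?(?<![a-z])" + term + r"(?![a-z])", low)
    tox_neg = re.search(r"negative\s+for\b[^.;:]*?(?<![a-z])" + term + r"(?![a-z])", low)
    negation = _NEGATION.search(low)
    strong_affirm = re.search(
        r"\b(?:admits?|endorses?|reports?|states?)\b[^.;]*?(?<![a-z])" + term + r"(?![a-z])"
        r"|\b(?:smok(?:es|ing|ed)|us(?:es|ing|ed)|vap(?:es|ing|ed)|tried)\s+(?:of\s+)?"
        + term + r"(?![a-z])"
        r"|(?<![a-z])" + term + r"\s+(?:use|user|dependence|abuse)\b"
        r"|\buse\s+of\s+" + term + r"(?![a-z])"
        r"|(?<![a-z])" + term + r"\s*:?\s*\+",
        low,
    )
    rx_medical = (
        re.search(r"(?<![a-z])" + medical + r"(?![a-z])", low) is not None
        and _RX_CONTEXT.search(low) is not None
    )
    return {
        "tox_positive": tox_pos is not None,
        "tox_negative": tox_neg is not None,
        "negation": negation is not None,
        "third_party": _THIRD_PARTY.search(low) is not None,
        "patient_marker": _PATIENT_MARKER.search(low) is not None,
        "counseling": _COUNSELING.search(low) is not None,
        "strong_affirm": strong_affirm is not None,
        "rx_medical": rx_medical,
    }


def rule_based_label(
    sentence_text: str,
    lexicon: Lexicon,
    note_id: str = "",
    sentence_index: int = 0,
) -> UseLabel:
    """Deterministic cue-based polarity for one keyword-bearing sentence.

    Cue precedence: a toxicology 'positive for ... <term>' always wins
    (it overrides an earlier denial in the same sentence); then tox
    negatives and explicit negation; then third-party attribution without
    a patient-attributed report; then affirmation cues (including
    prescription-cannabinoid context); counseling-only mentions and
    everything else default to negative.
    """
    hits_any = re.search(
        r"(?<![a-z])" + _term_alt(lexicon) + r"(?![a-z])", sentence_text.lower()
    )
    if hits_any is None:
        raise ClassifyError("rule_based_label requires a sentence with a lexicon hit")
    c = _sentence_cues(sentence_text, lexicon)
    if c["tox_positive"]:
        positive = True
    elif c["tox_negative"] or c["negation"]:
        positive = False
    elif c["third_party"] and not c["patient_marker"]:
        positive = False
    elif c["strong_affirm"] or c["rx_medical"]:
        positive = True
    else:
        positive = False
    score = 0.95 if positive else 0.05
    return UseLabel(
        note_id=note_id,
        sentence_index=sentence_index,
        label=POSITIVE if positive else NEGATIVE,
        score=score,
    )


# -- trainable baseline ---------------------------------------------------

@dataclass
class TrainConfig:
    seed: int = 0
    threshold: float = 0.5
    max_iter: int = 1000
    C: float = 1.0


@dataclass
class ClassifierModel:
    """A fitted sentence classifier satisfying the predict contract."""

    pipeline: Pipeline
    threshold: float = 0.5
    validation_metrics: "EvalMetrics | None" = field(default=None)

    def predict_proba_positive(self, texts: list[str]) -> np.ndarray:
        proba = self.pipeline.predict_proba(texts)
        classes = list(self.pipeline.named_steps["clf"].classes_)
        return proba[:, classes.index(POSITIVE)]


def train_classifier(
    train: list[LabeledSentence],
    valid: list[LabeledSentence],
    config: TrainConfig | None = None,
) -> ClassifierModel:
    """Fit the word+character TF-IDF logistic-regression baseline.

    Deterministic given config.seed. Raises on an empty or single-class
    training set.
    """
    config = config or TrainConfig()
    if not train or not valid:
        raise ClassifyError("train and valid splits must be non-empty")
    labels = {s.label for s in train}
    if len(labels) < 2:
        raise ClassifyError(f"training set has a single class: {labels}")
    features = FeatureUnion(
        [
            ("word", TfidfVectorizer(ngram_range=(1, 2), lowercase=True)),
            ("char", TfidfVectorizer(analyzer="char_wb", ngram_range=(2, 4), lowercase=True)),
        ]
    )
    pipe = Pipeline(
        [
            ("features", features),
            (
                "clf",
                LogisticRegression(
                    C=config.C,
                    max_iter=config.max_iter,
                    random_state=config.seed,
                    solver="liblinear",
                ),
            ),
        ]
    )
    pipe.fit([s.sentence_text for s in train], [s.label for s in train])
    model = ClassifierModel(pipeline=pipe, threshold=config.threshold)
    val_preds = predict_scores(
        model,
        [(s.note_id, i, s.sentence_text) for i, s in enumerate(valid)],
    )
    model.validation_metrics = evaluate(val_preds, [s.label for s in valid])
    return model


def predict_scores(
    model: ClassifierModel,
    sentences: list[tuple[str, int, str]],
) -> list[UseLabel]:
    """Score (note_id, sentence_index, text) triples with a fitted model."""
    if not sentences:
        return []
    texts = [t for _, _, t in sentences]
    scores = model.predict_proba_positive(texts)
    return [
        UseLabel(
            note_id=nid,
            sentence_index=idx,
            label=POSITIVE if sc >= model.threshold else NEGATIVE,
            score=float(sc),
        )
        for (nid, idx, _), sc in zip(sentences, scores)
    ]


def evaluate(predictions: list[UseLabel], gold: list[str]) -> EvalMetrics:
    """Confusion-matrix metrics plus rank-based AUROC.

    AUROC uses the Mann-Whitney rank statistic (tie-corrected); when the
    gold labels contain a single class it is undefined and reported as
    None while the threshold metrics are still returned.
    """
    if len(predictions) != len(gold):
        raise ClassifyError(
            f"{len(predictions)} predictions for {len(gold)} gold labels"
        )
    if not predictions:
        raise ClassifyError("cannot evaluate an empty prediction list")
    for g in gold:
        if g not in (POSITIVE, NEGATIVE):
            raise ClassifyError(f"bad gold label {g!r}")
    tp = fp = tn = fn = 0
    for p, g in zip(predictions, gold):
        if g == POSITIVE:
            tp += p.label == POSITIVE
            fn += p.label == NEGATIVE
        else:
            fp += p.label == POSITIVE
            tn += p.label == NEGATIVE
    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    n_pos, n_neg = tp + fn, tn + fp
    if n_pos and n_neg:
        # Mann-Whitney form with midranks for ties; equivalent to
        # sklearn.metrics.roc_auc_score but without its per-call overhead,
        # which dominates on the many small inputs this sees.
        scores = np.asarray([p.score for p in predictions], dtype=float)
        y = np.asarray([g == POSITIVE for g in gold])
        order = np.argsort(scores, kind="mergesort")
        s = scores[order]
        ranks = np.empty(len(s))
        i = 0
        while i < len(s):
            j = i
            while j + 1 < len(s) and s[j + 1] == s[i]:
                j += 1
            ranks[i : j + 1] = 0.5 * (i + j) + 1.0  # midrank, 1-based
            i = j + 1
        rank_sum_pos = float(ranks[y[order]].sum())
        auroc = (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    else:
        auroc = None
    return EvalMetrics(
        accuracy=accuracy,
        auroc=auroc,
        sensitivity=sensitivity,
        specificity=specificity,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )
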