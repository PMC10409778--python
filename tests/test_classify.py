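"""Split assignment, rule-based labeling, training harness, and metrics."""

import itertools

import numpy as np
import pytest

from cannascreen.classify import (
    ClassifyError,
    LabeledSentence,
    TrainConfig,
    UseLabel,
    assign_splits,
    evaluate,
    predict_scores,
    rule_based_label,
    train_classifier,
)
from conftest import EXAMPLE_SENTENCES


def brute_force_metrics(pred_labels, gold):
    """Oracle: literal counting over the four confusion cells."""
    tp = sum(p == "positive" and g == "positive" for p, g in zip(pred_labels, gold))
    fp = sum(p == "positive" and g == "negative" for p, g in zip(pred_labels, gold))
    tn = sum(p == "negative" and g == "negative" for p, g in zip(pred_labels, gold))
    fn = sum(p == "negative" and g == "positive" for p, g in zip(pred_labels, gold))
    return tp, fp, tn, fn


def pair_counting_auroc(scores, gold):
    """Oracle: P(score_pos > score_neg) + 0.5 P(tie) over all pairs."""
    pos = [s for s, g in zip(scores, gold) if g == "positive"]
    neg = [s for s, g in zip(scores, gold) if g == "negative"]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _mk_preds(labels, scores=None):
    scores = scores or [0.9 if l == "positive" else 0.1 for l in labels]
    return [UseLabel("n", i, l, s) for i, (l, s) in enumerate(zip(labels, scores))]


class TestSplits:
    def _sentences(self, n_notes, per_note=1):
        return [
            LabeledSentence(f"text {i} {j}", "positive" if i % 2 else "negative", f"note{i}")
            for i in range(n_notes)
            for j in range(per_note)
        ]

    def test_ten_notes_split_8_1_1(self):
        out = assign_splits(self._sentences(10), seed=1)
        counts = {k: sum(s.split == k for s in out) for k in ("train", "valid", "test")}
        assert counts == {"train": 8, "valid": 1, "test": 1}

    def test_deterministic_given_seed(self):
        a = assign_splits(self._sentences(20), seed=7)
        b = assign_splits(self._sentences(20), seed=7)
        assert [s.split for s in a] == [s.split for s in b]

    def test_notes_never_straddle_splits(self):
        out = assign_splits(self._sentences(12, per_note=3), seed=3)
        by_note = {}
        for s in out:
            by_note.setdefault(s.note_id, set()).add(s.split)
        assert all(len(v) == 1 for v in by_note.values())

    def test_too_few_notes_rejected(self):
        with pytest.raises(ClassifyError):
            assign_splits(self._sentences(2), seed=0)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ClassifyError):
            assign_splits(self._sentences(10), fractions=(0.8, 0.1, 0.2), seed=0)


class TestRuleBasedLabel:
    @pytest.mark.parametrize("text,expected", EXAMPLE_SENTENCES,
                             ids=[f"example{i}" for i in range(len(EXAMPLE_SENTENCES))])
    def test_curated_examples_polarity(self, text, expected, lexicon):
        # note-level polarity: positive iff any keyword sentence is positive
        from cannascreen.screening import extract_cannabis_sentences
        from conftest import make_note

        note = make_note(text)
        sentences = extract_cannabis_sentences(note, lexicon)
        assert sentences, "every example must yield at least one keyword sentence"
        labels = [rule_based_label(s.sentence_text, lexicon).label for s in sentences]
        note_label = "positive" if "positive" in labels else "negative"
        assert note_label == expected

    def test_tox_positive_overrides_denial_in_same_sentence(self, lexicon):
        text = "Denies use but urine tox screen positive for cannabis"
        assert rule_based_label(text, lexicon).label == "positive"

    def test_no_lexicon_hit_is_contract_violation(self, lexicon):
        with pytest.raises(ClassifyError):
            rule_based_label("No relevant substance here", lexicon)

    def test_label_consistent_with_score_threshold(self, lexicon):
        lab = rule_based_label("Pt admits to smoking marijuana daily", lexicon)
        assert (lab.label == "positive") == (lab.score >= 0.5)


def _separable_sentences(n, seed, noise=0.0):
    """Planted cue-label corpus: affirmation vs denial phrasings."""
    rng = np.random.default_rng(seed)
    pos = ["Pt admits to smoking {t} daily.", "Patient reports using {t} on weekends.",
           "Tox screen positive for {t}."]
    neg = ["Patient denies {t} use.", "No history of {t} or alcohol use.",
           "Toxicology negative for {t} and opiates."]
    terms = ["marijuana", "cannabis", "thc", "weed"]
    out = []
    for i in range(n):
        positive = bool(rng.random() < 0.73)
        bank = pos if positive != (rng.random() < noise) else neg
        text = str(rng.choice(bank)).format(t=str(rng.choice(terms)))
        out.append(LabeledSentence(text, "positive" if positive else "negative", f"note{i}"))
    return out


class TestTraining:
    def test_separable_corpus_high_validation_accuracy(self):
        sentences = assign_splits(_separable_sentences(200, seed=4), seed=4)
        model = train_classifier(
            [s for s in sentences if s.split == "train"],
            [s for s in sentences if s.split == "valid"],
        )
        assert model.validation_metrics.accuracy >= 0.95

    def test_empty_train_rejected(self):
        valid = _separable_sentences(5, seed=1)
        with pytest.raises(ClassifyError):
            train_classifier([], valid)

    def test_single_class_train_rejected(self):
        sents = [LabeledSentence("uses cannabis", "positive", f"n{i}") for i in range(5)]
        with pytest.raises(ClassifyError):
            train_classifier(sents, sents)

    def test_retrain_same_data_identical_metrics(self):
        sentences = assign_splits(_separable_sentences(150, seed=9), seed=9)
        train = [s for s in sentences if s.split == "train"]
        valid = [s for s in sentences if s.split == "valid"]
        m1 = train_classifier(train, valid, TrainConfig(seed=2)).validation_metrics
        m2 = train_classifier(train, valid, TrainConfig(seed=2)).validation_metrics
        assert m1 == m2

    def test_scores_in_unit_interval_and_threshold_monotone(self):
        sentences = assign_splits(_separable_sentences(150, seed=5), seed=5)
        model = train_classifier(
            [s for s in sentences if s.split == "train"],
            [s for s in sentences if s.split == "valid"],
        )
        test = [s for s in sentences if s.split == "test"]
        preds = predict_scores(model, [(s.note_id, i, s.sentence_text) for i, s in enumerate(test)])
        assert all(0.0 <= p.score <= 1.0 for p in preds)
        n_pos_default = sum(p.label == "positive" for p in preds)
        model.threshold = 0.9
        stricter = predict_scores(model, [(s.note_id, i, s.sentence_text) for i, s in enumerate(test)])
        assert sum(p.label == "positive" for p in stricter) <= n_pos_default

    def test_model_agrees_with_rule_labeler_on_cue_pure_sentences(self, lexicon):
        sentences = assign_splits(_separable_sentences(300, seed=6), seed=6)
        model = train_classifier(
            [s for s in sentences if s.split == "train"],
            [s for s in sentences if s.split == "valid"],
        )
        test = [s for s in sentences if s.split == "test"]
        preds = predict_scores(model, [(s.note_id, i, s.sentence_text) for i, s in enumerate(test)])
        rules = [rule_based_label(s.sentence_text, lexicon).label for s in test]
        agree = np.mean([p.label == r for p, r in zip(preds, rules)])
        assert agree >= 0.90


class TestEvaluate:
    def test_perfect_predictions(self):
        gold = ["positive", "negative", "positive", "negative"]
        m = evaluate(_mk_preds(gold), gold)
        assert (m.accuracy, m.auroc, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0, 1.0)

    def test_forced_arithmetic_example(self):
        # TP=2 FP=1 TN=1 FN=0
        preds = _mk_preds(["positive", "positive", "positive", "negative"])
        gold = ["positive", "positive", "negative", "negative"]
        m = evaluate(preds, gold)
        assert m.accuracy == 0.75
        assert m.sensitivity == 1.0
        assert m.specificity == 0.5

    def test_matches_bruteforce_oracle_small_inputs(self):
        for n in range(1, 5):
            for gold in itertools.product(["positive", "negative"], repeat=n):
                for plabels in itertools.product(["positive", "negative"], repeat=n):
                    m = evaluate(_mk_preds(list(plabels)), list(gold))
                    assert (m.tp, m.fp, m.tn, m.fn) == brute_force_metrics(plabels, gold)

    def test_auroc_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        gold = ["positive" if rng.random() < 0.5 else "negative" for _ in range(60)]
        scores = [float(rng.choice([0.1, 0.4, 0.4, 0.8, 0.9])) for _ in gold]
        if len(set(gold)) < 2:
            gold[0] = "positive"; gold[1] = "negative"
        preds = [UseLabel("n", i, "positive" if s >= 0.5 else "negative", s)
                 for i, s in enumerate(scores)]
        m = evaluate(preds, gold)
        assert m.auroc == pytest.approx(pair_counting_auroc(scores, gold))

    def test_auroc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        gold = ["positive"] * 30 + ["negative"] * 30
        scores = list(rng.uniform(0.01, 0.99, size=60))
        preds = [UseLabel("n", i, "positive" if s >= 0.5 else "negative", s)
                 for i, s in enumerate(scores)]
        transformed = [UseLabel("n", i, p.label, p.score ** 3) for i, p in enumerate(preds)]
        assert evaluate(preds, gold).auroc == pytest.approx(evaluate(transformed, gold).auroc)

    def test_random_scores_auroc_near_half(self):
        rng = np.random.default_rng(12)
        gold = ["positive"] * 500 + ["negative"] * 500
        preds = [UseLabel("n", i, "negative", float(rng.random())) for i in range(1000)]
        m = evaluate(preds, gold)
        assert abs(m.auroc - 0.5) < 0.06

    def test_one_class_gold_auroc_undefined_others_returned(self):
        gold = ["positive", "positive"]
        m = evaluate(_mk_preds(["positive", "negative"]), gold)
        assert m.auroc is None
        assert m.accuracy == 0.5
        assert m.sensitivity == 0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ClassifyError):
            evaluate(_mk_preds(["positive"]), ["positive", "negative"])
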