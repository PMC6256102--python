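"""Classification, metrics, and cross-validation."""

import logging

import pytest

from deptc.corpus import ClassSpec, LabeledCorpus, LabeledSentence, NEUTRAL
from deptc.evaluation import (
    Prediction,
    classify,
    cross_validate,
    evaluate,
    relative_improvement,
)
from deptc.semgrex import parse_pattern
from deptc.training import DTCModel, RankedPattern, TrainConfig, train
from deptc.trees import parse_bracketed_tree


def model_with(patterns, majority=NEUTRAL, fallback="majority", backup=None):
    """patterns: list of (pattern text, label, score)"""
    ranked = [
        RankedPattern(pattern=parse_pattern(t), label=lab, score=s)
        for t, lab, s in patterns
    ]
    return DTCModel(
        class_spec=ClassSpec("wait_time"),
        ranked=ranked,
        majority_label=majority,
        config=TrainConfig(),
        fallback=fallback,
        backup_classifier=backup,
    )


def corpus_of(records, class_id="wait_time"):
    sentences = []
    for tree_s, label in records:
        tree = parse_bracketed_tree(tree_s)
        labels = {} if label == NEUTRAL else {class_id: label}
        sentences.append(LabeledSentence(text=tree.text, tree=tree, labels=labels))
    return LabeledCorpus(class_specs=[ClassSpec(class_id)], sentences=sentences)


class TestClassify:
    def test_rank_order_decides(self):
        model = model_with([("{word:wait}", "x", 0.9), ("{word:wait}", "y", 0.8)])
        pred = classify(model, parse_bracketed_tree("[wait/NN]"))
        assert pred.predicted_label == "x"
        assert not pred.via_fallback
        assert pred.matched_pattern.score == 0.9

    def test_fallback_majority(self):
        model = model_with([("{word:wait}", "x", 0.9)])
        pred = classify(model, parse_bracketed_tree("[door/NN]"))
        assert pred.predicted_label == NEUTRAL and pred.via_fallback
        assert pred.matched_pattern is None

    def test_backup_classifier_receives_text(self):
        seen = []

        def backup(text):
            seen.append(text)
            return "y"

        model = model_with([], fallback="backup", backup=backup)
        pred = classify(model, parse_bracketed_tree("[door/NN]"), text="the door")
        assert pred.predicted_label == "y" and pred.via_fallback
        assert seen == ["the door"]

    def test_prediction_invariant_enforced(self):
        with pytest.raises(ValueError):
            Prediction(predicted_label="x", matched_pattern=None, via_fallback=False)

    def test_no_lower_ranked_label_when_higher_matches(self):
        model = model_with(
            [("{word:wait} > {word:long}", "y", 0.95), ("{word:wait}", "x", 0.9)]
        )
        t = parse_bracketed_tree("[wait/NN amod>long/JJ]")
        assert classify(model, t).predicted_label == "y"


class TestEvaluate:
    def test_all_correct_scores_one(self):
        model = model_with([("{word:wait}", "x", 0.9), ("{word:hour}", "y", 0.8)])
        corpus = corpus_of(
            [("[wait/NN]", "x"), ("[hour/NN]", "y"), ("[door/NN]", NEUTRAL)]
        )
        report = evaluate(model, corpus, "wait_time")
        assert report.weighted_accuracy == 1.0

    def test_constant_neutral_scores_one_third(self):
        model = model_with([])  # empty ranked list, majority neutral
        corpus = corpus_of(
            [("[wait/NN]", "x"), ("[hour/NN]", "y"), ("[door/NN]", NEUTRAL)]
        )
        report = evaluate(model, corpus, "wait_time")
        assert report.weighted_accuracy == pytest.approx(1 / 3)

    def test_hand_computed_confusion(self):
        # gold x: 2 predicted x; gold y: 1 x + 1 y; gold neutral: 4 neutral
        model = model_with([("{word:px}", "x", 0.9), ("{word:py}", "y", 0.8)])
        corpus = corpus_of(
            [
                ("[px/NN]", "x"),
                ("[px/NN]", "x"),
                ("[px/NN]", "y"),
                ("[py/NN]", "y"),
            ]
            + [("[f%d/NN]" % i, NEUTRAL) for i in range(4)]
        )
        report = evaluate(model, corpus, "wait_time")
        assert report.confusion["x"]["x"] == 2
        assert report.confusion["y"] == {"x": 1, "y": 1, "neutral": 0}
        assert report.per_label_accuracy == {"x": 1.0, "y": 0.5, "neutral": 1.0}
        assert report.weighted_accuracy == pytest.approx(5 / 6)
        # predicted-correct: 3 predicted x of which 2 gold x; 1 predicted y correct
        assert report.predicted_correct_ratio["x"] == pytest.approx(2 / 3)
        assert report.predicted_correct_ratio["y"] == 1.0

    def test_weighted_equals_mean_of_per_label(self):
        model = model_with([("{word:px}", "x", 0.9)])
        corpus = corpus_of(
            [("[px/NN]", "x"), ("[py/NN]", "y"), ("[pz/NN]", NEUTRAL), ("[px/NN]", NEUTRAL)]
        )
        report = evaluate(model, corpus, "wait_time")
        vals = [v for v in report.per_label_accuracy.values() if v is not None]
        assert report.weighted_accuracy == pytest.approx(sum(vals) / len(vals))
        # confusion row sums equal gold label frequencies
        assert {g: sum(row.values()) for g, row in report.confusion.items()} == {
            "x": 1,
            "y": 1,
            "neutral": 2,
        }

    def test_absent_label_excluded_with_warning(self, caplog):
        model = model_with([])
        corpus = corpus_of([("[a/DT]", NEUTRAL), ("[b/DT]", "x")])
        with caplog.at_level(logging.WARNING, logger="deptc"):
            report = evaluate(model, corpus, "wait_time")
        assert report.per_label_accuracy["y"] is None
        assert report.weighted_accuracy == pytest.approx(0.5)  # mean of (0, 1)
        assert "absent" in caplog.text

    def test_report_serializations(self):
        model = model_with([])
        corpus = corpus_of([("[a/DT]", NEUTRAL), ("[b/DT]", "x")])
        report = evaluate(model, corpus, "wait_time")
        assert "weighted_accuracy" in report.to_json()
        assert "wait_time" in report.to_text()


def separable_corpus(n=6):
    recs = []
    for i in range(n):
        recs.append(("[short/JJ x>wait/NN y>f%d/NN]" % i, "x"))
        recs.append(("[hour/NN x>g%d/NN]" % i, "y"))
        recs.append(("[h%d/NN x>k%d/NN]" % (i, i), NEUTRAL))
    return corpus_of(recs)


class TestCrossValidate:
    CFG = TrainConfig(n_x=4, n_y=4, m=2)

    def test_perfectly_separable_corpus_scores_one(self):
        report = cross_validate(separable_corpus(), "wait_time", self.CFG, k=2, seed=3)
        assert report.mean_weighted_accuracy == 1.0

    def test_same_seed_same_report(self):
        a = cross_validate(separable_corpus(), "wait_time", self.CFG, k=3, seed=9)
        b = cross_validate(separable_corpus(), "wait_time", self.CFG, k=3, seed=9)
        assert a.to_json() == b.to_json()

    def test_leave_one_out_fold_sizes(self):
        corpus = separable_corpus(2)  # 6 sentences
        report = cross_validate(corpus, "wait_time", self.CFG, k=6, seed=0)
        assert [r.n_sentences for r in report.fold_reports] == [1] * 6

    def test_k_bounds_enforced(self):
        with pytest.raises(ValueError):
            cross_validate(separable_corpus(2), "wait_time", self.CFG, k=1)
        with pytest.raises(ValueError):
            cross_validate(separable_corpus(1), "wait_time", self.CFG, k=99)


def test_relative_improvement_percent():
    assert relative_improvement(60.0, 50.0) == pytest.approx(20.0)
    with pytest.raises(ValueError):
        relative_improvement(1.0, 0.0)
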