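"""Word selection, pattern scoring, and model training."""

import io
import logging
import math

import pytest

from deptc.corpus import ClassSpec, LabeledCorpus, LabeledSentence, NEUTRAL
from deptc.semgrex import parse_pattern
from deptc.training import (
    DTCModel,
    RankedPattern,
    TrainConfig,
    information_gain,
    load_model,
    pattern_weighted_accuracy,
    save_model,
    train,
)
from deptc.trees import parse_bracketed_tree


def corpus_of(records, class_id="wait_time"):
    """records: list of (bracketed tree, label)"""
    sentences = []
    for tree_s, label in records:
        tree = parse_bracketed_tree(tree_s)
        labels = {} if label == NEUTRAL else {class_id: label}
        sentences.append(LabeledSentence(text=tree.text, tree=tree, labels=labels))
    return LabeledCorpus(class_specs=[ClassSpec(class_id)], sentences=sentences)


def brute_ig(n11, n10, n01, n00):
    """Information gain from a 2x2 (present/absent x positive/negative) table."""

    def h(*counts):
        tot = sum(counts)
        return -sum(c / tot * math.log2(c / tot) for c in counts if c) if tot else 0.0

    n = n11 + n10 + n01 + n00
    pres, absent = n11 + n10, n01 + n00
    return h(n11 + n01, n10 + n00) - (pres / n) * h(n11, n10) - (absent / n) * h(n01, n00)


class TestInformationGain:
    def test_perfectly_discriminative_word_ranks_first(self):
        recs = [("[wait/NN x>%s/NN]" % w, "x") for w in ("pa", "pb", "pc")]
        # no single word is perfectly anti-correlated with x
        recs += [("[door/NN x>qa/NN]", NEUTRAL), ("[gate/NN x>qb/NN]", NEUTRAL),
                 ("[door/NN x>qc/NN]", NEUTRAL)]
        corpus = corpus_of(recs)
        ws = information_gain(corpus, "wait_time", "x", n=2)
        assert ws.words[0] == "wait"
        # oracle: "wait" present in all 3 positives, no negatives -> 1 bit
        assert brute_ig(3, 0, 0, 3) == pytest.approx(1.0)

    def test_ubiquitous_word_has_zero_gain(self):
        recs = [("[wait/NN x>u%d/NN]" % i, "x" if i < 2 else NEUTRAL) for i in range(4)]
        corpus = corpus_of(recs)
        ws = information_gain(corpus, "wait_time", "x", n=10)
        assert ws.words[-1] == "wait"  # IG 0 sorts last
        assert brute_ig(2, 2, 0, 0) == pytest.approx(0.0)

    def test_ties_broken_lexicographically(self):
        # "alpha" and "beta" have identical contingency tables
        recs = [
            ("[alpha/NN x>beta/NN]", "x"),
            ("[alpha/NN x>beta/NN]", "x"),
            ("[other/NN x>stuff/NN]", NEUTRAL),
        ]
        ws = information_gain(corpus_of(recs), "wait_time", "x", n=2)
        assert ws.words == ("alpha", "beta")

    def test_fewer_than_n_words_returns_all(self):
        ws = information_gain(corpus_of([("[a/DT]", "x")]), "wait_time", "x", n=30)
        assert ws.words == ("a",)

    def test_matches_bruteforce_on_every_word(self):
        recs = [
            ("[wait/NN x>slow/JJ]", "x"),
            ("[wait/NN x>fast/JJ]", "x"),
            ("[door/NN x>slow/JJ]", NEUTRAL),
            ("[door/NN x>door/NN]", NEUTRAL),  # repeated word counts once
        ]
        corpus = corpus_of(recs)
        ws = information_gain(corpus, "wait_time", "x", n=10)
        tables = {
            "wait": (2, 0, 0, 2),
            "slow": (1, 1, 1, 1),
            "fast": (1, 0, 1, 2),
            "door": (0, 2, 2, 0),
        }
        expected = sorted(tables, key=lambda w: (-brute_ig(*tables[w]), w))
        assert list(ws.words) == expected


class TestWeightedAccuracy:
    def test_hand_enumerated_two_thirds(self):
        # 2 x-instances matched, 1 y unmatched, 1 neutral matched -> 2/3
        corpus = corpus_of(
            [
                ("[wait/NN]", "x"),
                ("[wait/NN]", "x"),
                ("[door/NN]", "y"),
                ("[wait/NN]", NEUTRAL),
            ]
        )
        p = parse_pattern("{word:wait}")
        score = pattern_weighted_accuracy(p, "x", corpus, "wait_time")
        assert score == pytest.approx(2 / 3)

    def test_match_everything_scores_one_third(self):
        corpus = corpus_of([("[a/DT]", "x"), ("[b/DT]", "y"), ("[c/DT]", NEUTRAL)])
        assert pattern_weighted_accuracy(
            parse_pattern("{}"), "x", corpus, "wait_time"
        ) == pytest.approx(1 / 3)

    def test_perfect_pattern_scores_one(self):
        corpus = corpus_of([("[wait/NN]", "x"), ("[door/NN]", "y"), ("[kind/NN]", NEUTRAL)])
        assert pattern_weighted_accuracy(
            parse_pattern("{word:wait}"), "x", corpus, "wait_time"
        ) == 1.0

    def test_absent_label_contributes_vacuous_accuracy(self):
        corpus = corpus_of([("[wait/NN]", "x"), ("[door/NN]", NEUTRAL)])
        # y absent: accuracies are (1, 1, 1)
        assert pattern_weighted_accuracy(
            parse_pattern("{word:wait}"), "x", corpus, "wait_time"
        ) == 1.0

    def test_empty_corpus_rejected(self):
        empty = LabeledCorpus(class_specs=[ClassSpec("wait_time")], sentences=[])
        with pytest.raises(ValueError):
            pattern_weighted_accuracy(parse_pattern("{}"), "x", empty, "wait_time")

    def test_duplicating_corpus_leaves_scores_unchanged(self):
        corpus = corpus_of(
            [("[wait/NN]", "x"), ("[door/NN]", "y"), ("[wait/NN x>door/NN]", NEUTRAL)]
        )
        doubled = LabeledCorpus(
            class_specs=corpus.class_specs, sentences=corpus.sentences * 2
        )
        p = parse_pattern("{word:wait}")
        assert pattern_weighted_accuracy(p, "x", corpus, "wait_time") == pytest.approx(
            pattern_weighted_accuracy(p, "x", doubled, "wait_time")
        )


SMALL = TrainConfig(n_x=5, n_y=5, m=2)


class TestTrain:
    def test_perfect_separator_ranks_first(self):
        corpus = corpus_of(
            [
                ("[short/JJ x>wait/NN]", "x"),
                ("[short/JJ x>wait/NN y>fa/NN]", "x"),
                ("[hour/NN x>fb/NN]", "y"),
                ("[hour/NN x>fc/NN]", "y"),
                ("[fd/NN x>fe/NN]", NEUTRAL),
                ("[ff/NN x>fg/NN]", NEUTRAL),
            ]
        )
        model = train(corpus, "wait_time", SMALL)
        assert model.ranked[0].score == 1.0
        scores = [rp.score for rp in model.ranked]
        assert scores == sorted(scores, reverse=True)
        assert all(0.0 <= s <= 1.0 for s in scores)

    def test_training_is_deterministic(self, tmp_path):
        recs = [
            ("[short/JJ x>wait/NN]", "x"),
            ("[hour/NN x>delay/NN]", "y"),
            ("[door/NN x>kind/NN]", NEUTRAL),
        ]
        out = []
        for _ in range(2):
            model = train(corpus_of(recs), "wait_time", SMALL)
            buf = io.StringIO()
            save_model(model, buf)
            out.append(buf.getvalue())
        assert out[0] == out[1]

    def test_neutral_only_corpus_yields_fallback_model(self, caplog):
        corpus = corpus_of([("[a/DT]", NEUTRAL), ("[b/DT]", NEUTRAL)])
        with caplog.at_level(logging.WARNING, logger="deptc"):
            model = train(corpus, "wait_time", SMALL)
        assert model.ranked == []
        assert model.majority_label == NEUTRAL
        assert "no" in caplog.text

    def test_tie_break_prefers_longer_pattern(self):
        ranked = [
            RankedPattern(parse_pattern("{word:a}"), "x", 0.5),
            RankedPattern(parse_pattern("{word:a} > {word:b}"), "x", 0.5),
        ]
        ordered = sorted(
            ranked,
            key=lambda rp: (-rp.score, -len(rp.pattern.source_text), rp.pattern.source_text),
        )
        assert ordered[0].pattern.source_text == "{word:a} > {word:b}"

    def test_model_roundtrip(self, tmp_path):
        corpus = corpus_of(
            [("[short/JJ x>wait/NN]", "x"), ("[hour/NN]", "y"), ("[door/NN]", NEUTRAL)]
        )
        model = train(corpus, "wait_time", SMALL)
        path = tmp_path / "model.txt"
        save_model(model, path)
        again = load_model(path)
        assert again.class_spec.class_id == "wait_time"
        assert again.config == model.config
        assert [
            (rp.score, rp.label, rp.pattern.source_text) for rp in again.ranked
        ] == [(rp.score, rp.label, rp.pattern.source_text) for rp in model.ranked]
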