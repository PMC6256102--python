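"""Training: word selection, pattern harvesting, scoring and ranking.

For one opinion class the trainer, per non-neutral label value:

1. binarizes the corpus labels (target label vs everything else) and picks
   the top-n word types by information gain of their presence indicator;
2. extracts semgrex patterns from every tree carrying the target label,
   using those words as seeds;
3. scores every distinct (pattern, label) pair on the full class corpus
   by *weighted accuracy* — the unweighted mean of the pattern's per-label
   accuracies over the three label values, so rare non-neutral labels
   count as much as the frequent neutral one;
4. sorts the pooled list in descending score order (ties: more specific,
   i.e. longer, pattern first, then lexicographic).

Everything is deterministic given the corpus and configuration; there is
no randomness in training.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

from .corpus import LABELS, NEUTRAL, X, Y, ClassSpec, LabeledCorpus, LabeledSentence
from .extraction import DEFAULT_NEGATION_LABEL, WordSet, extract
from .semgrex import SemgrexPattern, cached_matches, parse_pattern

__all__ = [
    "TrainConfig",
    "RankedPattern",
    "DTCModel",
    "information_gain",
    "pattern_weighted_accuracy",
    "train",
    "save_model",
    "load_model",
]

logger = logging.getLogger("deptc")


@dataclass(frozen=True)
class TrainConfig:
    """Training knobs.

    ``n_x``/``n_y`` cap the information-gain word lists for the two
    non-neutral labels and ``m`` bounds the seed words per pattern; the
    defaults (30, 30, 4) are the standard operating point — larger ``m``
    grows the pattern space combinatorially for little benefit.
    ``top_k`` optionally truncates the ranked list after training
    (default: keep everything).
    """

    n_x: int = 30
    n_y: int = 30
    m: int = 4
    negation_label: str = DEFAULT_NEGATION_LABEL
    seed: int = 0
    top_k: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("n_x and n_y must be >= 1")
        if self.m < 1:
            raise ValueError("m must be >= 1")


@dataclass(frozen=True)
class RankedPattern:
    pattern: SemgrexPattern
    label: str  # x or y
    score: float  # weighted accuracy on the training set, in [0, 1]

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")


@dataclass
class DTCModel:
    """A trained classifier for one opinion class: a ranked pattern list
    plus a fallback policy for sentences no pattern matches."""

    class_spec: ClassSpec
    ranked: list[RankedPattern]
    majority_label: str
    config: TrainConfig
    fallback: str = "majority"  # "majority" | "backup"
    backup_classifier: Optional[object] = None  # callable text -> label; not serialized

    def __post_init__(self) -> None:
        scores = [rp.score for rp in self.ranked]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("ranked list must be non-increasing in score")


def _entropy(counts: Sequence[int]) -> float:
    total = sum(counts)
    if total == 0:
        return 0.0
    h = 0.0
    for c in counts:
        if c:
            p = c / total
            h -= p * math.log2(p)
    return h


def _sentence_word_types(sentence: LabeledSentence) -> frozenset[str]:
    return frozenset(w.lower() for w in sentence.tree.words())


def information_gain(
    corpus: LabeledCorpus,
    class_id: str,
    target_label: str,
    n: int,
) -> WordSet:
    """Top-``n`` word types by information gain for target-vs-rest labels.

    The gain of word ``w`` is H(binary label) - H(binary label | w present),
    computed on presence/absence of the lowercased surface word. Ties are
    broken lexicographically; with fewer than ``n`` distinct words, all
    are returned.
    """
    if not corpus.sentences:
        raise ValueError("corpus is empty")
    gold = [lab == target_label for lab in corpus.labels_for(class_id)]
    n_pos = sum(gold)
    n_all = len(gold)
    h_label = _entropy([n_pos, n_all - n_pos])
    # contingency counts per word: (present & positive, present total)
    present_pos: Counter[str] = Counter()
    present_all: Counter[str] = Counter()
    for sent, is_pos in zip(corpus.sentences, gold):
        for w in _sentence_word_types(sent):
            present_all[w] += 1
            if is_pos:
                present_pos[w] += 1
    gains: list[tuple[float, str]] = []
    for w, pa in present_all.items():
        pp = present_pos[w]
        absent_all = n_all - pa
        absent_pos = n_pos - pp
        h_cond = (pa / n_all) * _entropy([pp, pa - pp]) + (absent_all / n_all) * _entropy(
            [absent_pos, absent_all - absent_pos]
        )
        gains.append((h_label - h_cond, w))
    gains.sort(key=lambda gw: (-gw[0], gw[1]))
    top = tuple(w for _, w in gains[:n])
    return WordSet(words=top, cap=n)


def pattern_weighted_accuracy(
    pattern: SemgrexPattern,
    label: str,
    corpus: LabeledCorpus,
    class_id: str,
) -> float:
    """Mean of the pattern's per-label accuracies over the 3 label values.

    The pattern, paired with ``label``, is correct on an instance when it
    matches an instance of that label or fails to match an instance of a
    different label. A label with zero instances contributes accuracy 1
    (the pattern cannot err on absent instances).
    """
    if not corpus.sentences:
        raise ValueError("corpus is empty")
    correct = {lab: 0 for lab in LABELS}
    totals = {lab: 0 for lab in LABELS}
    for sent, gold in zip(corpus.sentences, corpus.labels_for(class_id)):
        totals[gold] += 1
        hit = cached_matches(pattern, sent.tree)
        if (hit and gold == label) or (not hit and gold != label):
            correct[gold] += 1
    accs = [correct[lab] / totals[lab] if totals[lab] else 1.0 for lab in LABELS]
    return sum(accs) / len(accs)


def train(corpus: LabeledCorpus, class_id: str, config: TrainConfig = TrainConfig()) -> DTCModel:
    """Train a ranked-pattern classifier for one class. Deterministic."""
    if not corpus.sentences:
        raise ValueError("corpus is empty")
    spec = corpus.spec(class_id)
    gold = corpus.labels_for(class_id)
    label_counts = Counter(gold)
    for lab in (X, Y):
        if label_counts[lab] == 0:
            logger.warning(
                "class %r has no %r-labeled sentence; training on what is available",
                class_id,
                lab,
            )

    pooled: dict[tuple[str, str], SemgrexPattern] = {}
    for lab, n_words in ((X, config.n_x), (Y, config.n_y)):
        if label_counts[lab] == 0:
            continue
        words = information_gain(corpus, class_id, lab, n_words)
        for sent, g in zip(corpus.sentences, gold):
            if g != lab:
                continue
            for pattern, plab in extract(
                words, sent.tree, lab, config.m, config.negation_label
            ):
                pooled.setdefault((pattern.source_text, plab), pattern)

    ranked = [
        RankedPattern(
            pattern=pattern,
            label=plab,
            score=pattern_weighted_accuracy(pattern, plab, corpus, class_id),
        )
        for (_, plab), pattern in pooled.items()
    ]
    # descending score; ties: longer (more specific) canonical text first,
    # then lexicographic, then label — fully deterministic
    ranked.sort(
        key=lambda rp: (
            -rp.score,
            -len(rp.pattern.source_text),
            rp.pattern.source_text,
            rp.label,
        )
    )
    if config.top_k is not None:
        ranked = ranked[: config.top_k]

    # majority label; ties broken neutral > x > y so degenerate corpora
    # fall back to "not relevant"
    order = {NEUTRAL: 0, X: 1, Y: 2}
    majority = max(LABELS, key=lambda lab: (label_counts[lab], -order[lab]))
    if not ranked:
        logger.warning("class %r produced no patterns; model is fallback-only", class_id)
    return DTCModel(
        class_spec=spec,
        ranked=ranked,
        majority_label=majority,
        config=config,
    )


# ---------------------------------------------------------------------------
# model file format: one JSON header line, then `score\tlabel\tpattern` lines
# ---------------------------------------------------------------------------


def save_model(model: DTCModel, sink: Union[str, Path, TextIO]) -> None:
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            save_model(model, fh)
        return
    cfg = asdict(model.config)
    header = {
        "class_id": model.class_spec.class_id,
        "config": cfg,
        "majority_label": model.majority_label,
        "fallback": model.fallback,
    }
    sink.write(json.dumps(header, sort_keys=True) + "\n")
    for rp in model.ranked:
        sink.write(f"{rp.score!r}\t{rp.label}\t{rp.pattern.source_text}\n")


def load_model(source: Union[str, Path, TextIO]) -> DTCModel:
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return load_model(fh)
    lines = [ln.rstrip("\n") for ln in source]
    if not lines:
        raise ValueError("empty model file")
    header = json.loads(lines[0])
    config = TrainConfig(**header["config"])
    ranked = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        score_s, label, text = ln.split("\t", 2)
        ranked.append(
            RankedPattern(pattern=parse_pattern(text), label=label, score=float(score_s))
        )
    return DTCModel(
        class_spec=ClassSpec(class_id=header["class_id"]),
        ranked=ranked,
        majority_label=header["majority_label"],
        config=config,
        fallback=header.get("fallback", "majority"),
    )
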