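"""Classification, evaluation metrics and cross-validation.

A sentence is classified by the highest-ranked pattern that matches its
dependency tree; when nothing matches, the model falls back to the
training-set majority label or to a user-supplied backup classifier
(any callable mapping sentence text to a label).

Metrics per class:

* per-label accuracy — of the sentences whose gold label is L, the
  fraction classified L;
* weighted accuracy — the unweighted mean of the three per-label
  accuracies, so the usually rare non-neutral labels carry the same
  weight as the frequent neutral one;
* predicted-correct ratio — of the sentences *predicted* x (or y), the
  fraction whose gold label agrees (a precision-style measure).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

from sklearn.model_selection import KFold, StratifiedKFold

from .corpus import LABELS, NEUTRAL, X, Y, LabeledCorpus
from .semgrex import cached_matches
from .trees import DependencyTree
from .training import DTCModel, RankedPattern, TrainConfig, train

__all__ = [
    "Prediction",
    "EvalReport",
    "CrossValidationReport",
    "classify",
    "evaluate",
    "cross_validate",
    "relative_improvement",
]

logger = logging.getLogger("deptc")


@dataclass(frozen=True)
class Prediction:
    predicted_label: str
    matched_pattern: Optional[RankedPattern]
    via_fallback: bool

    def __post_init__(self) -> None:
        if self.via_fallback != (self.matched_pattern is None):
            raise ValueError("via_fallback must coincide with absence of a matched pattern")


def classify(
    model: DTCModel,
    tree: DependencyTree,
    text: Optional[str] = None,
) -> Prediction:
    """Label one tree with the highest-ranked matching pattern.

    The ranked list is scanned in order; the first match decides. With no
    match, the majority label applies, unless the model carries a backup
    classifier (``fallback == "backup"``), which then receives the
    sentence text.
    """
    for rp in model.ranked:
        if cached_matches(rp.pattern, tree):
            return Prediction(predicted_label=rp.label, matched_pattern=rp, via_fallback=False)
    if model.fallback == "backup" and model.backup_classifier is not None:
        label = model.backup_classifier(text if text is not None else tree.text)
        return Prediction(predicted_label=label, matched_pattern=None, via_fallback=True)
    return Prediction(
        predicted_label=model.majority_label, matched_pattern=None, via_fallback=True
    )


@dataclass
class EvalReport:
    """Per-class evaluation results; see the module docstring for the measures."""

    class_id: str
    per_label_accuracy: dict[str, Optional[float]]
    predicted_correct_ratio: dict[str, Optional[float]]
    weighted_accuracy: float
    confusion: dict[str, dict[str, int]]  # gold label -> predicted label -> count
    n_sentences: int = 0

    def to_dict(self) -> dict:
        return {
            "class_id": self.class_id,
            "per_label_accuracy": self.per_label_accuracy,
            "predicted_correct_ratio": self.predicted_correct_ratio,
            "weighted_accuracy": self.weighted_accuracy,
            "confusion": self.confusion,
            "n_sentences": self.n_sentences,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_text(self) -> str:
        def fmt(v: Optional[float]) -> str:
            return "n/a" if v is None else f"{100 * v:6.2f}%"

        lines = [f"class: {self.class_id}  (n={self.n_sentences})"]
        lines.append("label      accuracy   predicted-correct")
        for lab in LABELS:
            pc = self.predicted_correct_ratio.get(lab)
            lines.append(
                f"{lab:<10} {fmt(self.per_label_accuracy.get(lab))}    "
                + (fmt(pc) if lab != NEUTRAL else "")
            )
        lines.append(f"weighted accuracy: {fmt(self.weighted_accuracy)}")
        return "\n".join(line.rstrip() for line in lines)


def evaluate(model: DTCModel, corpus: LabeledCorpus, class_id: str) -> EvalReport:
    """Score a trained model on a labeled corpus for one class."""
    if not corpus.sentences:
        raise ValueError("corpus is empty")
    gold = corpus.labels_for(class_id)
    confusion = {g: {p: 0 for p in LABELS} for g in LABELS}
    for sent, g in zip(corpus.sentences, gold):
        pred = classify(model, sent.tree, sent.text)
        confusion[g][pred.predicted_label] += 1

    per_label: dict[str, Optional[float]] = {}
    for lab in LABELS:
        total = sum(confusion[lab].values())
        if total == 0:
            logger.warning(
                "class %r: label %r absent from corpus; excluded from the mean",
                class_id,
                lab,
            )
            per_label[lab] = None
        else:
            per_label[lab] = confusion[lab][lab] / total
    present = [v for v in per_label.values() if v is not None]
    weighted = sum(present) / len(present)

    predicted_correct: dict[str, Optional[float]] = {}
    for lab in (X, Y):
        predicted = sum(confusion[g][lab] for g in LABELS)
        predicted_correct[lab] = confusion[lab][lab] / predicted if predicted else None

    return EvalReport(
        class_id=class_id,
        per_label_accuracy=per_label,
        predicted_correct_ratio=predicted_correct,
        weighted_accuracy=weighted,
        confusion=confusion,
        n_sentences=len(corpus.sentences),
    )


@dataclass
class CrossValidationReport:
    class_id: str
    k: int
    seed: int
    stratified: bool
    fold_reports: list[EvalReport]

    @property
    def mean_weighted_accuracy(self) -> float:
        return sum(r.weighted_accuracy for r in self.fold_reports) / len(self.fold_reports)

    def mean_per_label_accuracy(self) -> dict[str, Optional[float]]:
        out: dict[str, Optional[float]] = {}
        for lab in LABELS:
            vals = [
                r.per_label_accuracy[lab]
                for r in self.fold_reports
                if r.per_label_accuracy.get(lab) is not None
            ]
            out[lab] = sum(vals) / len(vals) if vals else None
        return out

    def to_dict(self) -> dict:
        return {
            "class_id": self.class_id,
            "k": self.k,
            "seed": self.seed,
            "stratified": self.stratified,
            "mean_weighted_accuracy": self.mean_weighted_accuracy,
            "mean_per_label_accuracy": self.mean_per_label_accuracy(),
            "folds": [r.to_dict() for r in self.fold_reports],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def cross_validate(
    corpus: LabeledCorpus,
    class_id: str,
    config: TrainConfig = TrainConfig(),
    k: int = 10,
    seed: int = 0,
) -> CrossValidationReport:
    """Stratified k-fold cross-validation for one class.

    Folds are stratified on the class's 3-valued label and shuffled with
    ``seed``; the seed is recorded in the report so runs are repeatable.
    A label with fewer instances than ``k`` degrades to unstratified
    assignment for that label (scikit-learn warns).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(corpus.sentences):
        raise ValueError(f"k={k} exceeds corpus size {len(corpus.sentences)}")
    gold = corpus.labels_for(class_id)
    from collections import Counter

    min_count = min(Counter(gold).values())
    stratified = min_count >= k
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        logger.warning(
            "class %r: a label has fewer than k=%d instances; "
            "falling back to unstratified folds",
            class_id,
            k,
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_reports: list[EvalReport] = []
    for train_idx, test_idx in splitter.split(gold, gold):
        model = train(corpus.subset(train_idx), class_id, config)
        fold_reports.append(evaluate(model, corpus.subset(test_idx), class_id))
    return CrossValidationReport(
        class_id=class_id, k=k, seed=seed, stratified=stratified, fold_reports=fold_reports
    )


def relative_improvement(value: float, baseline: float) -> float:
    """Relative improvement of ``value`` over ``baseline``, in percent."""
    if baseline == 0:
        raise ValueError("baseline must be non-zero")
    return 100.0 * (value - baseline) / baseline
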