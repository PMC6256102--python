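"""Labeled-corpus data model and JSON-lines reader/writer.

Every sentence carries, for each declared opinion class, exactly one of
three label values: ``x`` ("yes"), ``y`` ("no"), or ``neutral`` (the
sentence does not mention the class). A sentence may be non-neutral for
more than one class. Classes model review aspects such as wait time or
staff friendliness; what "yes"/"no" mean is class-specific (e.g. short vs
long wait) and is documented on the :class:`ClassSpec`.

Corpus file format: JSON lines. An optional first record
``{"classes": [...]}`` declares the class inventory; every other record is
``{"text": ..., "tree": <bracketed> | "conllu": <block>, "labels": {...}}``.
A label value may be a string or a list of strings (the union of several
annotators); a list containing both ``x`` and ``y`` for one class is a
conflict and the record is dropped with a logged warning.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, TextIO, Union

from .trees import DependencyTree, TreeFormatError, parse_bracketed_tree, parse_conllu_block

__all__ = [
    "X",
    "Y",
    "NEUTRAL",
    "LABELS",
    "ClassSpec",
    "LabeledSentence",
    "LabeledCorpus",
    "CorpusFormatError",
    "read_corpus",
    "write_corpus",
]

logger = logging.getLogger("deptc")

X = "x"
Y = "y"
NEUTRAL = "neutral"
LABELS = (X, Y, NEUTRAL)


class CorpusFormatError(ValueError):
    """Raised for malformed corpus records."""


@dataclass(frozen=True)
class ClassSpec:
    """One opinion class: an aspect that takes one of three label values."""

    class_id: str
    x_description: str = ""
    y_description: str = ""

    @property
    def labels(self) -> tuple[str, str, str]:
        return LABELS

    @property
    def label_count(self) -> int:
        return 3


@dataclass
class LabeledSentence:
    """A sentence, its dependency tree, and one label per declared class."""

    text: str
    tree: DependencyTree
    labels: dict[str, str] = field(default_factory=dict)

    def label(self, class_id: str) -> str:
        return self.labels.get(class_id, NEUTRAL)


@dataclass
class LabeledCorpus:
    """Training/evaluation substrate: class inventory plus labeled sentences."""

    class_specs: list[ClassSpec]
    sentences: list[LabeledSentence]

    @property
    def class_ids(self) -> list[str]:
        return [c.class_id for c in self.class_specs]

    def spec(self, class_id: str) -> ClassSpec:
        for c in self.class_specs:
            if c.class_id == class_id:
                return c
        raise KeyError(class_id)

    def labels_for(self, class_id: str) -> list[str]:
        self.spec(class_id)  # KeyError on unknown class
        return [s.label(class_id) for s in self.sentences]

    def subset(self, indices: Iterable[int]) -> "LabeledCorpus":
        sents = [self.sentences[i] for i in indices]
        return LabeledCorpus(class_specs=list(self.class_specs), sentences=sents)

    def __len__(self) -> int:
        return len(self.sentences)


def _resolve_label(value: Union[str, list], class_id: str, record_no: int) -> Optional[str]:
    """Collapse a possibly multi-annotator label value to one of the 3 labels.

    Returns ``None`` to signal an x/y conflict.
    """
    values = {value} if isinstance(value, str) else set(value)
    bad = values - set(LABELS)
    if bad:
        raise CorpusFormatError(
            f"record {record_no}: unknown label value(s) {sorted(bad)} for class {class_id!r}"
        )
    values.discard(NEUTRAL)  # any non-neutral annotation wins over neutral
    if values == {X, Y}:
        return None
    if not values:
        return NEUTRAL
    return values.pop()


def read_corpus(source: Union[str, Path, TextIO]) -> LabeledCorpus:
    """Load a JSON-lines corpus; see the module docstring for the format.

    Missing class entries default to ``neutral``. Records assigning both
    ``x`` and ``y`` to one class are excluded with a logged warning.
    Unknown class ids (when a header declares the inventory) and
    unparseable trees raise :class:`CorpusFormatError` with the record
    number.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return read_corpus(fh)

    declared: Optional[list[str]] = None
    sentences: list[LabeledSentence] = []
    seen_classes: list[str] = []
    for record_no, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line:
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as exc:
            raise CorpusFormatError(f"record {record_no}: invalid JSON") from exc
        if record_no == 1 and "classes" in rec and "labels" not in rec:
            declared = list(rec["classes"])
            continue
        if "tree" in rec:
            try:
                tree = parse_bracketed_tree(rec["tree"])
            except TreeFormatError as exc:
                raise CorpusFormatError(f"record {record_no}: {exc}") from exc
        elif "conllu" in rec:
            try:
                tree = parse_conllu_block(rec["conllu"].splitlines(), str(record_no))
            except TreeFormatError as exc:
                raise CorpusFormatError(f"record {record_no}: {exc}") from exc
        else:
            raise CorpusFormatError(f"record {record_no}: needs a 'tree' or 'conllu' field")
        labels: dict[str, str] = {}
        conflict = False
        for cid, value in dict(rec.get("labels", {})).items():
            if declared is not None and cid not in declared:
                raise CorpusFormatError(f"record {record_no}: undeclared class {cid!r}")
            if declared is None and cid not in seen_classes:
                seen_classes.append(cid)
            resolved = _resolve_label(value, cid, record_no)
            if resolved is None:
                logger.warning(
                    "record %d: conflicting x/y labels for class %r; record excluded",
                    record_no,
                    cid,
                )
                conflict = True
                break
            if resolved != NEUTRAL:
                labels[cid] = resolved
        if conflict:
            continue
        sentences.append(
            LabeledSentence(text=rec.get("text", tree.text), tree=tree, labels=labels)
        )
    class_ids = declared if declared is not None else seen_classes
    specs = [ClassSpec(class_id=c) for c in class_ids]
    return LabeledCorpus(class_specs=specs, sentences=sentences)


def write_corpus(corpus: LabeledCorpus, sink: Union[str, Path, TextIO]) -> None:
    """Write a corpus in the JSON-lines format read by :func:`read_corpus`."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            write_corpus(corpus, fh)
        return
    sink.write(json.dumps({"classes": corpus.class_ids}) + "\n")
    for s in corpus.sentences:
        rec = {
            "text": s.text,
            "tree": s.tree.serialize_bracketed(),
            "labels": {c: lab for c, lab in sorted(s.labels.items()) if lab != NEUTRAL},
        }
        sink.write(json.dumps(rec) + "\n")


def parse_with(parser, text: str) -> DependencyTree:
    """Adapter hook for an external dependency parser.

    ``parser`` is any callable mapping a sentence string to a CoNLL-U block
    (or a bracketed tree string starting with ``[``). The package itself
    ships no parser; gold trees come from the corpus formats or the
    synthetic generator.
    """
    out = parser(text)
    if out.lstrip().startswith("["):
        return parse_bracketed_tree(out)
    return parse_conllu_block(out.splitlines())
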