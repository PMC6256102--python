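"""Synthetic labeled corpora with gold dependency trees.

The generator emulates the statistical shape of sentence-level opinion
data: for each opinion class, a minority of sentences carry a
class-discriminative construction (the *motif* — e.g. a negated
"wait ... long" subtree for "short wait time"), embedded under random
filler structure, while the majority are neutral filler-only sentences.
Because trees are emitted directly (no parser in the loop), every other
module can be exercised without downloads and without parser variance.

What this emulates — and what it does not: planted motifs are exact and
filler words are drawn from a closed pseudo-word vocabulary, so recovery
results on this data bound the algorithm's behaviour under ideal parsing
and vocabulary conditions, not its accuracy on real reviews, where
paraphrase, parser errors and topical correlation blur the signal. Label
noise and motif dropout knobs reintroduce some of that blur.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .corpus import NEUTRAL, X, Y, ClassSpec, LabeledCorpus, LabeledSentence
from .extraction import DEFAULT_NEGATION_LABEL
from .semgrex import (
    AttrMatcher,
    NodeDescriptor,
    PatternNode,
    RelationConstraint,
    SemgrexPattern,
)
from .trees import DepEdge, DepNode, DependencyTree

__all__ = [
    "MotifNode",
    "MotifEdge",
    "Motif",
    "SyntheticClass",
    "GeneratorConfig",
    "generate",
    "planted_pattern",
    "default_classes",
    "default_config",
    "pseudo_vocabulary",
]

# UD-like relation labels for filler structure; the negation label is
# reserved for motifs so that negation stays a class signal.
_FILLER_RELATIONS = (
    "nsubj", "obj", "obl", "nmod", "amod", "advmod", "det",
    "case", "compound", "conj", "cc", "mark", "aux", "cop",
)


@dataclass(frozen=True)
class MotifEdge:
    child: "MotifNode"
    relation: Optional[str] = None  # None: draw a random non-negation label
    indirect: bool = False  # realized as a path through 1-2 filler nodes


@dataclass(frozen=True)
class MotifNode:
    """One node of a motif template.

    ``word`` None means a filler word is drawn at generation time;
    ``constrain`` says whether the recovery pattern pins the word (an
    unconstrained node appears as the wildcard ``{}``).
    """

    word: Optional[str] = None
    children: tuple[MotifEdge, ...] = ()
    constrain: bool = True
    pos: Optional[str] = None


@dataclass(frozen=True)
class Motif:
    """A planted discriminative subtree for one label value of one class."""

    label: str  # X or Y
    template: MotifNode

    def __post_init__(self) -> None:
        if self.label not in (X, Y):
            raise ValueError("motif label must be x or y")
        if not self.words():
            raise ValueError("motif template needs >=1 word-constrained node")

    def words(self) -> list[str]:
        out: list[str] = []

        def walk(n: MotifNode) -> None:
            if n.word is not None:
                out.append(n.word.lower())
            for e in n.children:
                walk(e.child)

        walk(self.template)
        return out

    def depth(self) -> int:
        def d(n: MotifNode) -> int:
            return 1 + max((d(e.child) + (2 if e.indirect else 0) for e in n.children), default=0)

        return d(self.template)


@dataclass(frozen=True)
class SyntheticClass:
    spec: ClassSpec
    x_motif: Motif
    y_motif: Motif

    def __post_init__(self) -> None:
        if self.x_motif.label != X or self.y_motif.label != Y:
            raise ValueError("motif labels must match their slots")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic corpus.

    Defaults: two opinion classes (wait time with a negation construction
    on the "yes" side, staff), 100 sentences per label value per class,
    a 1500-token pseudo-word filler vocabulary, 5-9 filler tokens per
    sentence, and no label noise or motif dropout. A large, sparse filler
    vocabulary mirrors the open vocabulary of real review text: chance
    co-occurrence of any two specific filler words is rare.
    """

    classes: tuple[SyntheticClass, ...] = ()
    n_per_label: int = 100
    vocab: Optional[tuple[str, ...]] = None  # None: pseudo_vocabulary(1500)
    label_noise: float = 0.0
    motif_dropout: float = 0.0
    seed: int = 0
    tokens_min: int = 5
    tokens_max: int = 9
    max_depth: int = 12

    def __post_init__(self) -> None:
        if not (0.0 <= self.label_noise <= 1.0) or not (0.0 <= self.motif_dropout <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_per_label < 1:
            raise ValueError("n_per_label must be >= 1")
        if self.tokens_min < 1 or self.tokens_max < self.tokens_min:
            raise ValueError("bad token-count bounds")


def pseudo_vocabulary(size: int) -> tuple[str, ...]:
    """Deterministic list of distinct 4-letter CVCV pseudo-words.

    The full combination table is shuffled with a fixed seed so that any
    prefix of the list is diverse in its leading letters.
    """
    consonants = "bdfgklmnprstvz"
    vowels = "aeiou"
    syllables = [c + v for c, v in itertools.product(consonants, vowels)]
    words = [a + b for a, b in itertools.product(syllables, repeat=2)]
    if size > len(words):
        raise ValueError("requested vocabulary too large")
    random.Random(0).shuffle(words)
    return tuple(words[:size])


def default_classes() -> tuple[SyntheticClass, ...]:
    """Two review-aspect classes with planted motifs.

    wait_time/x plants the canonical negated construction ("never ...
    wait long" — a wildcard governor with a negation dependent and, below
    it, wait > long); wait_time/y plants "waited ... hour". The staff
    class uses direct two-word motifs.
    """
    wait_x = Motif(
        label=X,
        template=MotifNode(
            word=None,
            children=(
                MotifEdge(
                    child=MotifNode(word="never", constrain=False, pos="RB"),
                    relation=DEFAULT_NEGATION_LABEL,
                ),
                MotifEdge(
                    child=MotifNode(
                        word="wait",
                        pos="NN",
                        children=(
                            MotifEdge(child=MotifNode(word="long", pos="JJ"), relation="amod"),
                        ),
                    ),
                    indirect=True,
                ),
            ),
        ),
    )
    wait_y = Motif(
        label=Y,
        template=MotifNode(
            word="waited",
            pos="VBD",
            children=(MotifEdge(child=MotifNode(word="hour", pos="NN"), relation="nmod"),),
        ),
    )
    staff_x = Motif(
        label=X,
        template=MotifNode(
            word="staff",
            pos="NN",
            children=(MotifEdge(child=MotifNode(word="friendly", pos="JJ"), relation="amod"),),
        ),
    )
    staff_y = Motif(
        label=Y,
        template=MotifNode(
            word="receptionist",
            pos="NN",
            children=(MotifEdge(child=MotifNode(word="rude", pos="JJ"), relation="amod"),),
        ),
    )
    return (
        SyntheticClass(
            spec=ClassSpec("wait_time", "short wait", "long wait"),
            x_motif=wait_x,
            y_motif=wait_y,
        ),
        SyntheticClass(
            spec=ClassSpec("staff", "friendly staff", "rude staff"),
            x_motif=staff_x,
            y_motif=staff_y,
        ),
    )


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    return GeneratorConfig(classes=default_classes(), seed=seed, **overrides)


def planted_pattern(
    motif: Motif, negation_label: str = DEFAULT_NEGATION_LABEL
) -> SemgrexPattern:
    """The semgrex pattern equivalent to a motif template (recovery truth)."""

    def convert(n: MotifNode) -> PatternNode:
        if n.word is not None and n.constrain:
            import re as _re

            desc = NodeDescriptor(
                (("word", AttrMatcher(value=_re.escape(n.word.lower()) + ".*", is_regex=True)),)
            )
        else:
            desc = NodeDescriptor()
        rels = []
        for e in n.children:
            target = convert(e.child)
            if e.indirect:
                rels.append(RelationConstraint(kind="indirect", label=None, target=target))
            elif e.relation == negation_label:
                rels.append(
                    RelationConstraint(kind="direct", label=negation_label, target=target)
                )
            else:
                rels.append(RelationConstraint(kind="direct", label=None, target=target))
        return PatternNode(descriptor=desc, relations=tuple(rels))

    return SemgrexPattern(root=convert(motif.template))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


class _TreeDraft:
    """Mutable nested tree under construction."""

    __slots__ = ("word", "pos", "children")

    def __init__(self, word: str, pos: Optional[str]):
        self.word = word
        self.pos = pos
        self.children: list[tuple[str, "_TreeDraft"]] = []

    def all_nodes(self) -> list["_TreeDraft"]:
        out = [self]
        for _, c in self.children:
            out.extend(c.all_nodes())
        return out

    def to_tree(self) -> DependencyTree:
        nodes: list[DepNode] = []
        edges: list[DepEdge] = []

        def add(d: "_TreeDraft") -> int:
            idx = len(nodes) + 1
            nodes.append(DepNode(index=idx, word=d.word, pos=d.pos))
            for rel, c in d.children:
                child = add(c)
                edges.append(DepEdge(governor=idx, relation=rel, dependent=child))
            return idx

        root = add(self)
        return DependencyTree(nodes, edges, root)


def _filler_tree(rng: random.Random, vocab: Sequence[str], n_tokens: int) -> _TreeDraft:
    words = rng.sample(list(vocab), n_tokens)
    root = _TreeDraft(words[0], "NN")
    nodes = [root]
    for w in words[1:]:
        parent = rng.choice(nodes)
        child = _TreeDraft(w, "NN")
        parent.children.append((rng.choice(_FILLER_RELATIONS), child))
        nodes.append(child)
    return root


def _realize_motif(
    motif: Motif, rng: random.Random, vocab: Sequence[str]
) -> _TreeDraft:
    def realize(n: MotifNode) -> _TreeDraft:
        word = n.word if n.word is not None else rng.choice(vocab)
        d = _TreeDraft(word, n.pos or "NN")
        for e in n.children:
            rel = e.relation if e.relation is not None else rng.choice(_FILLER_RELATIONS)
            child = realize(e.child)
            if e.indirect:
                # an indirect template edge becomes a path through 1-2 fillers
                hops = [
                    _TreeDraft(rng.choice(vocab), "NN") for _ in range(rng.randint(1, 2))
                ]
                top = hops[0]
                cur = hops[0]
                for nxt in hops[1:]:
                    cur.children.append((rng.choice(_FILLER_RELATIONS), nxt))
                    cur = nxt
                cur.children.append((rel if e.relation is not None else rng.choice(_FILLER_RELATIONS), child))
                d.children.append((rng.choice(_FILLER_RELATIONS), top))
            else:
                d.children.append((rel, child))
        return d

    return realize(motif.template)


def _noisy_label(label: str, rng: random.Random, p: float) -> str:
    if p > 0 and rng.random() < p:
        return rng.choice([lab for lab in (X, Y, NEUTRAL) if lab != label])
    return label


def generate(config: GeneratorConfig) -> LabeledCorpus:
    """Generate a labeled corpus; fully reproducible from ``config.seed``.

    Per class: ``n_per_label`` sentences embedding the x-motif,
    ``n_per_label`` embedding the y-motif, and ``n_per_label`` neutral
    filler-only sentences. Motif sentences are neutral for every other
    class. Labels are flipped with probability ``label_noise``; a motif
    sentence omits its motif with probability ``motif_dropout`` (keeping
    its label).
    """
    if not config.classes:
        raise ValueError("config declares no classes")
    rng = random.Random(config.seed)
    reserved = {w for sc in config.classes for mo in (sc.x_motif, sc.y_motif) for w in mo.words()}
    vocab = config.vocab if config.vocab is not None else pseudo_vocabulary(1500)
    # keep prefix matching clean: no filler may share a prefix with a motif word
    vocab = tuple(
        w
        for w in vocab
        if not any(w.startswith(r) or r.startswith(w) for r in reserved)
    )
    if len(vocab) < config.tokens_max + 4:
        raise ValueError("filler vocabulary too small after removing motif words")
    for sc in config.classes:
        for mo in (sc.x_motif, sc.y_motif):
            if mo.depth() > config.max_depth:
                raise ValueError(
                    f"motif for {sc.spec.class_id}/{mo.label} deeper than max_depth"
                )

    sentences: list[LabeledSentence] = []
    for sc in config.classes:
        cid = sc.spec.class_id
        for motif in (sc.x_motif, sc.y_motif):
            for _ in range(config.n_per_label):
                draft = _filler_tree(
                    rng, vocab, rng.randint(config.tokens_min, config.tokens_max)
                )
                if not (config.motif_dropout > 0 and rng.random() < config.motif_dropout):
                    host = rng.choice(draft.all_nodes())
                    host.children.append(
                        (rng.choice(_FILLER_RELATIONS), _realize_motif(motif, rng, vocab))
                    )
                label = _noisy_label(motif.label, rng, config.label_noise)
                tree = draft.to_tree()
                labels = {cid: label} if label != NEUTRAL else {}
                sentences.append(LabeledSentence(text=tree.text, tree=tree, labels=labels))
        for _ in range(config.n_per_label):
            draft = _filler_tree(
                rng, vocab, rng.randint(config.tokens_min, config.tokens_max)
            )
            label = _noisy_label(NEUTRAL, rng, config.label_noise)
            tree = draft.to_tree()
            labels = {cid: label} if label != NEUTRAL else {}
            sentences.append(LabeledSentence(text=tree.text, tree=tree, labels=labels))
    return LabeledCorpus(
        class_specs=[sc.spec for sc in config.classes], sentences=sentences
    )
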