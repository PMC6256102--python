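"""Subtree pattern extraction from labeled dependency trees.

Given a dependency tree of a sentence with a known class label and a set
``W`` of high-information words, extraction keeps only the parts of the
tree built from those words (plus negations, which are always preserved),
abstracts everything else to wildcards, and emits the resulting shapes as
semgrex patterns labeled with the sentence's class.

The three steps per working tree:

1. *prune*: repeatedly drop leaves whose word does not start with any word
   in ``W`` (case-insensitive prefix, so "wait" covers "waited") and whose
   incoming relation is not the negation label; then replace every
   surviving non-matching node by the wildcard ``*``.
2. *collapse*: descend past single-child wildcard roots; splice out
   interior single-child wildcards, marking the bridging edge indirect.
3. recurse on every >=2-sized combination of the surviving words, so that
   more general subpatterns are emitted as well.

Patterns that contain no word-constrained node at all match every tree
and are suppressed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

from .semgrex import (
    AttrMatcher,
    NodeDescriptor,
    PatternNode,
    RelationConstraint,
    SemgrexPattern,
)
from .trees import DepEdge, DepNode, DependencyTree

__all__ = ["WordSet", "WILDCARD", "prune", "collapse", "extract", "pattern_from_tree"]

WILDCARD = "*"
DEFAULT_NEGATION_LABEL = "neg"


@dataclass(frozen=True)
class WordSet:
    """Ordered, duplicate-free list of lowercase seed words with a cap."""

    words: tuple[str, ...]
    cap: int

    def __post_init__(self) -> None:
        lowered = tuple(w.lower() for w in self.words)
        if len(set(lowered)) != len(lowered):
            raise ValueError("WordSet contains duplicates")
        if len(lowered) > self.cap:
            raise ValueError(f"|words|={len(lowered)} exceeds cap={self.cap}")
        object.__setattr__(self, "words", lowered)

    def __iter__(self):
        return iter(self.words)

    def __len__(self) -> int:
        return len(self.words)


def _starts_with_any(word: str, seeds: Sequence[str]) -> bool:
    lw = word.lower()
    return any(lw.startswith(s) for s in seeds)


def prune(
    tree: DependencyTree,
    seeds: Iterable[str],
    negation_label: str = DEFAULT_NEGATION_LABEL,
) -> Optional[DependencyTree]:
    """Keep only seed-matching words, negations, and connecting wildcards.

    Returns a new tree (indices reassigned in pre-order) or ``None`` when
    everything is pruned away. Wildcard nodes carry the word ``*``.
    """
    seed_list = [s.lower() for s in seeds]

    def keep(index: int) -> Optional[tuple]:
        """Return (word, pos, [(relation, indirect, child)]) or None."""
        node = tree.node(index)
        kids = []
        for e in tree.children(index):
            sub = keep(e.dependent)
            if sub is not None:
                kids.append((e.relation, e.indirect, sub))
        matched = node.word != WILDCARD and _starts_with_any(node.word, seed_list)
        incoming = tree.incoming(index)
        negated = incoming is not None and not incoming.indirect and incoming.relation == negation_label
        if not kids and not matched and not negated:
            return None  # prunable leaf (recursively)
        word = node.word if matched else WILDCARD
        return (word, node.pos, kids)

    kept = keep(tree.root.index)
    if kept is None:
        return None
    return _build(kept)


def _build(shape: tuple) -> DependencyTree:
    nodes: list[DepNode] = []
    edges: list[DepEdge] = []

    def add(item: tuple) -> int:
        word, pos, kids = item
        idx = len(nodes) + 1
        nodes.append(DepNode(index=idx, word=word, pos=pos))
        for rel, indirect, sub in kids:
            child = add(sub)
            edges.append(DepEdge(governor=idx, relation=rel, dependent=child, indirect=indirect))
        return idx

    root = add(shape)
    return DependencyTree(nodes, edges, root)


def collapse(
    tree: DependencyTree,
    negation_label: str = DEFAULT_NEGATION_LABEL,
) -> DependencyTree:
    """Remove single-child wildcard nodes.

    The root descends past single-child wildcards; an interior single-child
    wildcard is spliced out and its parent is joined to its child by an
    indirect edge. Wildcards with two or more children are kept (they pin
    sibling structure together).
    """

    def to_shape(index: int) -> tuple:
        node = tree.node(index)
        kids = [(e.relation, e.indirect, to_shape(e.dependent)) for e in tree.children(index)]
        return (node.word, node.pos, kids)

    root = to_shape(tree.root.index)
    while root[0] == WILDCARD and len(root[2]) == 1:
        root = root[2][0][2]

    def splice(item: tuple) -> tuple:
        word, pos, kids = item
        new_kids = []
        for rel, indirect, sub in kids:
            sub = splice(sub)
            if sub[0] == WILDCARD and len(sub[2]) == 1:
                # bridge parent -> grandchild; the path is now indirect
                _, _, grandkids = sub
                new_kids.append(("", True, grandkids[0][2]))
            else:
                new_kids.append((rel, indirect, sub))
        return (word, pos, new_kids)

    prev = None
    while prev != root:  # splicing can cascade along wildcard chains
        prev = root
        root = splice(root)
    return _build(root)


def pattern_from_tree(
    tree: DependencyTree,
    negation_label: str = DEFAULT_NEGATION_LABEL,
) -> SemgrexPattern:
    """Convert a pruned+collapsed tree to its semgrex form.

    Wildcards become ``{}``; a word node becomes the anchored prefix regex
    ``{word:/w.*/}``; direct edges become ``>`` except the negation label,
    which is preserved as a typed relation; indirect edges become ``>>``.
    """

    def convert(index: int) -> PatternNode:
        node = tree.node(index)
        if node.word == WILDCARD:
            desc = NodeDescriptor()
        else:
            value = re.escape(node.word.lower()) + ".*"
            desc = NodeDescriptor((("word", AttrMatcher(value=value, is_regex=True)),))
        rels = []
        for e in tree.children(index):
            target = convert(e.dependent)
            if e.indirect:
                rels.append(RelationConstraint(kind="indirect", label=None, target=target))
            elif e.relation == negation_label:
                rels.append(RelationConstraint(kind="direct", label=negation_label, target=target))
            else:
                rels.append(RelationConstraint(kind="direct", label=None, target=target))
        return PatternNode(descriptor=desc, relations=tuple(rels))

    return SemgrexPattern(root=convert(tree.root.index))


def _seed_combinations(
    words: Sequence[str], m: int, tree: DependencyTree
) -> list[tuple[str, ...]]:
    """Distinct effective seed sets for the initial stack.

    The working loop prunes a copy of the tree with each combination ``C``
    of exactly ``min(|W|, m)`` words of ``W``; pruning only sees the words
    of ``C`` that prefix-match something in the tree, so combinations with
    equal intersections with that relevant subset produce identical
    results. We therefore enumerate the distinct realizable intersections
    (in lexicographic order) instead of all C(|W|, m) combinations — the
    emitted pattern set is identical.
    """
    k = min(len(words), m)
    tree_words = [n.word.lower() for n in tree.nodes]
    relevant = sorted(w for w in words if any(tw.startswith(w) for tw in tree_words))
    n_irrelevant = len(words) - len(relevant)
    seeds: list[tuple[str, ...]] = []
    for size in range(min(k, len(relevant)), -1, -1):
        if k - size > n_irrelevant:
            continue  # not realizable: too few padding words outside the tree
        seeds.extend(combinations(relevant, size))
    return seeds


def extract(
    word_set: WordSet,
    tree: DependencyTree,
    label: str,
    m: int,
    negation_label: str = DEFAULT_NEGATION_LABEL,
) -> set[tuple[SemgrexPattern, str]]:
    """Emit all (pattern, label) pairs extractable from one tree.

    ``m`` is the maximum number of seed words used in a single pattern;
    the initial working trees are pruned with every min(|W|, m)-sized
    combination of ``W``, and subpatterns recurse over >=2-sized
    combinations of surviving words. Output is a set keyed by canonical
    pattern text — deterministic across runs.
    """
    cap = m
    if cap < 1:
        raise ValueError("m must be >= 1")
    emitted: dict[str, SemgrexPattern] = {}
    out: set[tuple[SemgrexPattern, str]] = set()
    seeds = _seed_combinations(word_set.words, cap, tree)
    stack: list[tuple[DependencyTree, tuple[str, ...]]] = [
        (tree, c) for c in reversed(seeds)
    ]
    while stack:
        work_tree, combo = stack.pop()
        pruned = prune(work_tree, combo, negation_label)
        if pruned is None:
            continue
        collapsed = collapse(pruned, negation_label)
        pattern = pattern_from_tree(collapsed, negation_label)
        key = pattern.source_text
        if key in emitted:
            continue
        emitted[key] = pattern
        if pattern.word_constrained_nodes() > 0:
            out.add((pattern, label))
        surviving = sorted(
            {n.word.lower() for n in collapsed.nodes if n.word != WILDCARD}
        )
        for size in range(2, len(surviving) + 1):
            for sub in combinations(surviving, size):
                stack.append((collapsed, sub))
    return out
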