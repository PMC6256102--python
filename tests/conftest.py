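"""Shared fixtures: worked-example trees, random generators, oracle matcher."""

from __future__ import annotations

import itertools
import random

import pytest

from deptc.semgrex import (
    AttrMatcher,
    NodeDescriptor,
    PatternNode,
    RelationConstraint,
    SemgrexPattern,
)
from deptc.trees import DepEdge, DepNode, DependencyTree, parse_bracketed_tree

# the "there are never long wait times" tree and the pattern that matches it
FIG_TREE_STRING = (
    "[are/VBP expl>there/EX neg>never/RB nsubj>[times/NNS compound>[wait/NN amod>long/JJ]]]"
)
SAMPLE_PATTERN_TEXT = "{} >neg {} >> ({word:wait} > {word:long})"

# worked-example sentence tree (synthetic UD-style encoding, consistent
# with the four example patterns below: "time" is a direct dependent of
# "arrived", "room" and "hour" are direct dependents of "waited")
EXAMPLE_SENTENCE_TREE = (
    "[arrived/VBD nsubj>I/PRP nmod>[appointment/NN case>to/TO poss>my/PRP$] "
    "nmod>[time/NN case>on/IN] cc>and/CC conj>[waited/VBD "
    "nmod>[room/NN case>in/IN poss>his/PRP$ compound>waiting/NN] "
    "nmod>[hour/NN case>for/IN advmod>over/RB det>an/DT]]]"
)
EXAMPLE_PATTERNS = (
    "{} > {word:/time.*/} >> {word:/hour.*/}",
    "{word:/arrived.*/} > {word:/time.*/}",
    "{} > {word:/time.*/} > ({} > {word:/room.*/} > {word:/hour.*/})",
    "{word:/arrived.*/} >> {word:/hour.*/}",
)


@pytest.fixture
def neg_wait_tree() -> DependencyTree:
    return parse_bracketed_tree(FIG_TREE_STRING)


@pytest.fixture
def example_tree() -> DependencyTree:
    return parse_bracketed_tree(EXAMPLE_SENTENCE_TREE)


# ---------------------------------------------------------------------------
# random structures for property tests
# ---------------------------------------------------------------------------

TOY_WORDS = ["wait", "long", "time", "staff", "door", "care", "bill", "kind"]
TOY_RELATIONS = ["nsubj", "obj", "amod", "nmod", "det", "neg"]


def random_tree(
    rng: random.Random,
    max_nodes: int = 8,
    words: list[str] | None = None,
    relations: list[str] | None = None,
) -> DependencyTree:
    """Random dependency tree with repeated words and occasional neg edges."""
    words = words or TOY_WORDS
    relations = relations or TOY_RELATIONS
    n = rng.randint(1, max_nodes)
    nodes = [DepNode(index=i + 1, word=rng.choice(words), pos=rng.choice(["NN", "VB", "JJ"]))
             for i in range(n)]
    edges = [
        DepEdge(governor=rng.randint(1, i), relation=rng.choice(relations), dependent=i + 1)
        for i in range(1, n)
    ]
    return DependencyTree(nodes, edges, 1)


def random_pattern(
    rng: random.Random,
    max_nodes: int = 4,
    words: list[str] | None = None,
    relations: list[str] | None = None,
) -> SemgrexPattern:
    """Random pattern AST (governor-direction operators only)."""
    words = words or TOY_WORDS
    relations = relations or TOY_RELATIONS
    budget = rng.randint(1, max_nodes)

    def make_node(remaining: int) -> tuple[PatternNode, int]:
        kind = rng.random()
        if kind < 0.3:
            desc = NodeDescriptor()
        elif kind < 0.8:
            desc = NodeDescriptor(
                (("word", AttrMatcher(value=rng.choice(words), is_regex=False)),)
            )
        else:
            desc = NodeDescriptor(
                (("word", AttrMatcher(value=rng.choice(words)[:3] + ".*", is_regex=True)),)
            )
        remaining -= 1
        rels = []
        while remaining > 0 and rng.random() < 0.6:
            child, remaining = make_node(remaining)
            op = rng.random()
            if op < 0.4:
                rc = RelationConstraint(kind="direct", label=None, target=child)
            elif op < 0.7:
                rc = RelationConstraint(kind="direct", label=rng.choice(relations), target=child)
            else:
                rc = RelationConstraint(kind="indirect", label=None, target=child)
            rels.append(rc)
        return PatternNode(descriptor=desc, relations=tuple(rels)), remaining

    root, _ = make_node(budget)
    return SemgrexPattern(root=root)


# ---------------------------------------------------------------------------
# brute-force matching oracle: enumerate all pattern-node -> tree-node maps
# ---------------------------------------------------------------------------


def brute_force_matches(pattern: SemgrexPattern, tree: DependencyTree) -> bool:
    pnodes: list[PatternNode] = []
    constraints: list[tuple[int, int, RelationConstraint]] = []  # (parent slot, child slot, rc)

    def flatten(p: PatternNode) -> int:
        slot = len(pnodes)
        pnodes.append(p)
        for rc in p.relations:
            child_slot = flatten(rc.target)
            constraints.append((slot, child_slot, rc))
        return slot

    flatten(pattern.root)
    tnodes = tree.nodes
    descendant_ids = {
        n.index: {d.index for d in tree.descendants(n)} for n in tnodes
    }
    for assignment in itertools.product(tnodes, repeat=len(pnodes)):
        if not all(p.descriptor.test(t) for p, t in zip(pnodes, assignment)):
            continue
        ok = True
        for parent_slot, child_slot, rc in constraints:
            gov = assignment[parent_slot]
            dep = assignment[child_slot]
            if rc.kind == "direct":
                if not any(
                    e.dependent == dep.index
                    and (rc.label is None or e.relation == rc.label)
                    for e in tree.children(gov)
                ):
                    ok = False
                    break
            else:
                if dep.index not in descendant_ids[gov.index]:
                    ok = False
                    break
        if ok:
            return True
    return False
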