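"""Parser, serializer and matcher for the semgrex pattern subset.

Semgrex is a pattern language over dependency trees: node descriptors such
as ``{word:wait}`` or ``{lemma:run;pos:/VB.*/}`` constrain word attributes
(``{}`` is a wildcard matching any node), and relation operators connect
them: ``>`` (direct dependent), ``>label`` (direct dependent through a
specific relation, e.g. ``>neg``), and ``>>`` (dependent anywhere below,
i.e. a governor -> ... -> dependent path of length >= 1). Chained
relations all hang off the leading node unless parenthesized::

    {} >neg {} >> ({word:wait} > {word:long})

reads: some node governs a negation and, somewhere below it, a node "wait"
that directly governs "long".

Only the governor-direction operators are implemented (``<``, ``<<`` and
typed indirect relations never occur in extracted patterns). Attribute
comparison is case-insensitive; regex values (``/.../``) must match the
whole attribute. The mapping of pattern nodes to tree nodes is not
required to be injective.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property
from typing import Optional

from .trees import DepNode, DependencyTree

__all__ = [
    "AttrMatcher",
    "NodeDescriptor",
    "RelationConstraint",
    "PatternNode",
    "SemgrexPattern",
    "PatternParseError",
    "parse_pattern",
    "serialize_pattern",
    "matches",
]

_ATTRS = ("word", "lemma", "pos")


class PatternParseError(ValueError):
    """Raised for malformed pattern text; the message names the position."""


@dataclass(frozen=True)
class AttrMatcher:
    """Exact-string or regular-expression test on one node attribute."""

    value: str
    is_regex: bool = False

    @cached_property
    def _compiled(self) -> Optional[re.Pattern]:
        if not self.is_regex:
            return None
        try:
            return re.compile(self.value, re.IGNORECASE)
        except re.error as exc:  # pragma: no cover - caught at parse time too
            raise PatternParseError(f"bad regex /{self.value}/: {exc}") from exc

    def test(self, attr_value: Optional[str]) -> bool:
        if attr_value is None:
            return False
        if self.is_regex:
            return self._compiled.fullmatch(attr_value) is not None
        return attr_value.lower() == self.value.lower()

    def render(self) -> str:
        return f"/{self.value}/" if self.is_regex else self.value


@dataclass(frozen=True)
class NodeDescriptor:
    """Conjunction of attribute constraints; an empty map is the wildcard ``{}``."""

    constraints: tuple[tuple[str, AttrMatcher], ...] = ()

    def __post_init__(self) -> None:
        for attr, _ in self.constraints:
            if attr not in _ATTRS:
                raise PatternParseError(f"unknown attribute {attr!r}")

    @property
    def is_wildcard(self) -> bool:
        return not self.constraints

    def test(self, node: DepNode) -> bool:
        return all(m.test(node.attribute(a)) for a, m in self.constraints)

    def render(self) -> str:
        if not self.constraints:
            return "{}"
        order = {a: i for i, a in enumerate(sorted(_ATTRS))}
        items = sorted(self.constraints, key=lambda am: order[am[0]])
        return "{" + ";".join(f"{a}:{m.render()}" for a, m in items) + "}"


@dataclass(frozen=True)
class RelationConstraint:
    """One relation arc from a pattern node to a child pattern node."""

    kind: str  # "direct" | "indirect"
    label: Optional[str]  # relation type; None matches any relation
    target: "PatternNode"

    def __post_init__(self) -> None:
        if self.kind not in ("direct", "indirect"):
            raise ValueError(f"bad relation kind {self.kind!r}")
        if self.kind == "indirect" and self.label is not None:
            raise ValueError("typed indirect relations are not supported")


@dataclass(frozen=True)
class PatternNode:
    descriptor: NodeDescriptor
    relations: tuple[RelationConstraint, ...] = ()


@dataclass(frozen=True)
class SemgrexPattern:
    """A parsed pattern; equality and hashing go through the canonical text."""

    root: PatternNode

    @cached_property
    def source_text(self) -> str:
        return _render(self.root)

    def __str__(self) -> str:
        return self.source_text

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SemgrexPattern) and self.source_text == other.source_text

    def __hash__(self) -> int:
        return hash(self.source_text)

    def n_nodes(self) -> int:
        def count(p: PatternNode) -> int:
            return 1 + sum(count(rc.target) for rc in p.relations)

        return count(self.root)

    def word_constrained_nodes(self) -> int:
        def count(p: PatternNode) -> int:
            own = 0 if p.descriptor.is_wildcard else 1
            return own + sum(count(rc.target) for rc in p.relations)

        return count(self.root)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_LABEL_RE = re.compile(r"[A-Za-z_][\w:$-]*")  # relation labels (may contain ':')
_ATTR_RE = re.compile(r"[A-Za-z_]\w*")


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def err(self, msg: str) -> PatternParseError:
        return PatternParseError(f"{msg} at position {self.pos}")

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def parse_pattern(self) -> PatternNode:
        head = self.parse_node()
        relations: list[RelationConstraint] = []
        while True:
            self.skip_ws()
            if self.peek() == "&":
                self.pos += 1
                self.skip_ws()
                if self.peek() not in ("<", ">"):
                    raise self.err("dangling '&'")
            c = self.peek()
            if c in ("<",):
                raise self.err("dependent-direction operators '<'/'<<' are not supported")
            if c != ">":
                break
            self.pos += 1
            kind = "direct"
            label: Optional[str] = None
            if self.peek() == ">":
                self.pos += 1
                kind = "indirect"
                m = _LABEL_RE.match(self.text, self.pos)
                if m:
                    raise self.err("typed indirect relations are not supported")
            else:
                m = _LABEL_RE.match(self.text, self.pos)
                if m:
                    label = m.group(0)
                    self.pos = m.end()
            self.skip_ws()
            if self.peek() == "(":
                self.pos += 1
                target = self.parse_pattern()
                self.skip_ws()
                if self.peek() != ")":
                    raise self.err("expected ')'")
                self.pos += 1
            elif self.peek() == "{":
                target = self.parse_node()
            else:
                raise self.err("dangling relation: expected node or '('")
            relations.append(RelationConstraint(kind=kind, label=label, target=target))
        return PatternNode(descriptor=head.descriptor, relations=head.relations + tuple(relations))

    def parse_node(self) -> PatternNode:
        self.skip_ws()
        if self.peek() != "{":
            raise self.err("expected '{'")
        self.pos += 1
        constraints: list[tuple[str, AttrMatcher]] = []
        self.skip_ws()
        if self.peek() == "}":
            self.pos += 1
            return PatternNode(descriptor=NodeDescriptor())
        while True:
            self.skip_ws()
            m = _ATTR_RE.match(self.text, self.pos)
            if not m:
                raise self.err("expected attribute name")
            attr = m.group(0)
            if attr not in _ATTRS:
                raise self.err(f"unknown attribute {attr!r}")
            self.pos = m.end()
            self.skip_ws()
            if self.peek() != ":":
                raise self.err("expected ':'")
            self.pos += 1
            self.skip_ws()
            if self.peek() == "/":
                end = self.text.find("/", self.pos + 1)
                if end < 0:
                    raise self.err("unterminated regex")
                value = self.text[self.pos + 1 : end]
                try:
                    re.compile(value)
                except re.error as exc:
                    raise self.err(f"bad regex /{value}/: {exc}")
                matcher = AttrMatcher(value=value, is_regex=True)
                self.pos = end + 1
            else:
                start = self.pos
                while self.peek() not in (";", "}", ""):
                    self.pos += 1
                value = self.text[start : self.pos].strip()
                if not value:
                    raise self.err("empty attribute value")
                matcher = AttrMatcher(value=value, is_regex=False)
            constraints.append((attr, matcher))
            self.skip_ws()
            if self.peek() == ";":
                self.pos += 1
                continue
            if self.peek() == "}":
                self.pos += 1
                return PatternNode(descriptor=NodeDescriptor(tuple(constraints)))
            raise self.err("expected ';' or '}'")


def parse_pattern(text: str) -> SemgrexPattern:
    """Parse pattern text into a :class:`SemgrexPattern` AST."""
    p = _Parser(text)
    root = p.parse_pattern()
    p.skip_ws()
    if p.pos != len(p.text):
        raise p.err("trailing text after pattern")
    return SemgrexPattern(root=root)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _render(node: PatternNode) -> str:
    parts = []
    for rc in node.relations:
        op = ">>" if rc.kind == "indirect" else ">" + (rc.label or "")
        sub = _render(rc.target)
        if rc.target.relations:
            sub = f"({sub})"
        parts.append(f"{op} {sub}")
    parts.sort()  # deterministic child order
    return " ".join([node.descriptor.render()] + parts)


def serialize_pattern(pattern: SemgrexPattern) -> str:
    """Canonical text form: children sorted by their rendered string."""
    return pattern.source_text


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------


def _match_at(pnode: PatternNode, tnode: DepNode, tree: DependencyTree) -> bool:
    if not pnode.descriptor.test(tnode):
        return False
    for rc in pnode.relations:
        if rc.kind == "direct":
            candidates = (
                tree.node(e.dependent)
                for e in tree.children(tnode)
                if rc.label is None or e.relation == rc.label
            )
        else:
            candidates = tree.descendants(tnode)
        if not any(_match_at(rc.target, c, tree) for c in candidates):
            return False
    return True


def matches(pattern: SemgrexPattern, tree: DependencyTree) -> bool:
    """True iff the pattern matches any part of the tree.

    The pattern's leading node may map to any tree node (not only the
    root); a direct relation requires one edge, an indirect relation a
    downward path of length >= 1.
    """
    return any(_match_at(pattern.root, n, tree) for n in tree.nodes)


def cached_matches(pattern: SemgrexPattern, tree: DependencyTree) -> bool:
    """`matches` with per-tree memoisation keyed by the canonical pattern text.

    Training and cross-validation test the same (pattern, tree) pairs many
    times; the memo lives on the tree object, so repeated calls are O(1).
    """
    memo = tree._match_memo
    key = pattern.source_text
    hit = memo.get(key)
    if hit is None:
        hit = memo[key] = matches(pattern, tree)
    return hit
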