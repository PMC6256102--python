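"""Dependency-tree data model and text-format readers/writers.

A dependency tree is a rooted tree over the words of one sentence: every
word is a node, and every edge links a governor (head) word to a dependent
word through a typed grammatical relation such as ``nsubj`` or ``neg``.
Trees enter the package either as CoNLL-U sentence blocks or as bracketed
strings of the form::

    [are/VBP expl>there/EX neg>never/RB nsubj>[times/NNS compound>[wait/NN amod>long/JJ]]]

Relation labels are uninterpreted strings; the package works with any
dependency label inventory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, TextIO, Union

__all__ = [
    "DepNode",
    "DepEdge",
    "DependencyTree",
    "TreeFormatError",
    "parse_bracketed_tree",
    "read_conllu",
    "parse_conllu_block",
    "isomorphic",
]


class TreeFormatError(ValueError):
    """Raised for malformed bracketed-tree or CoNLL-U input."""


@dataclass(frozen=True)
class DepNode:
    """One word of a sentence: 1-based position plus string attributes."""

    index: int
    word: str
    lemma: Optional[str] = None
    pos: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.word:
            raise ValueError("DepNode.word must be non-empty")
        if self.index < 1:
            raise ValueError("DepNode.index is 1-based")

    def attribute(self, name: str) -> Optional[str]:
        if name == "word":
            return self.word
        if name == "lemma":
            return self.lemma
        if name == "pos":
            return self.pos
        raise KeyError(name)


@dataclass(frozen=True)
class DepEdge:
    """Typed governor -> dependent edge.

    ``indirect`` marks an edge standing for a governor -> ... -> dependent
    path of length >= 1; such edges only appear in the intermediate trees
    produced by pattern extraction, never in parsed sentences.
    """

    governor: int  # node index
    relation: str
    dependent: int  # node index
    indirect: bool = False


class DependencyTree:
    """Immutable rooted tree of :class:`DepNode` joined by :class:`DepEdge`.

    Child order is preserved (it carries no matching semantics but keeps
    serialization stable).
    """

    def __init__(self, nodes: Iterable[DepNode], edges: Iterable[DepEdge], root: int):
        self._nodes: dict[int, DepNode] = {}
        for n in nodes:
            if n.index in self._nodes:
                raise ValueError(f"duplicate node index {n.index}")
            self._nodes[n.index] = n
        self._edges: list[DepEdge] = list(edges)
        self._children: dict[int, list[DepEdge]] = {i: [] for i in self._nodes}
        self._incoming: dict[int, DepEdge] = {}
        for e in self._edges:
            if e.governor not in self._nodes or e.dependent not in self._nodes:
                raise ValueError("edge references unknown node index")
            if e.dependent in self._incoming:
                raise ValueError(f"node {e.dependent} has two governors")
            self._children[e.governor].append(e)
            self._incoming[e.dependent] = e
        if root not in self._nodes:
            raise ValueError("root index not among nodes")
        if root in self._incoming:
            raise ValueError("root must have no governor")
        if len(self._edges) != len(self._nodes) - 1:
            raise ValueError("edge count must be node count - 1")
        self._root = root
        # connectivity / acyclicity: every non-root node must reach the root
        for i in self._nodes:
            seen = set()
            j = i
            while j != root:
                if j in seen or j not in self._incoming:
                    raise ValueError("tree is cyclic or disconnected")
                seen.add(j)
                j = self._incoming[j].governor
        self._match_memo: dict[str, bool] = {}

    # -- accessors ---------------------------------------------------------
    @property
    def root(self) -> DepNode:
        return self._nodes[self._root]

    @property
    def nodes(self) -> list[DepNode]:
        return [self._nodes[i] for i in sorted(self._nodes)]

    @property
    def edges(self) -> list[DepEdge]:
        return list(self._edges)

    def __len__(self) -> int:
        return len(self._nodes)

    def node(self, index: int) -> DepNode:
        return self._nodes[index]

    def children(self, node: Union[DepNode, int]) -> list[DepEdge]:
        i = node.index if isinstance(node, DepNode) else node
        return list(self._children[i])

    def incoming(self, node: Union[DepNode, int]) -> Optional[DepEdge]:
        i = node.index if isinstance(node, DepNode) else node
        return self._incoming.get(i)

    def descendants(self, node: Union[DepNode, int]) -> Iterator[DepNode]:
        """Proper descendants of ``node`` in pre-order."""
        i = node.index if isinstance(node, DepNode) else node
        stack = [e.dependent for e in reversed(self._children[i])]
        while stack:
            j = stack.pop()
            yield self._nodes[j]
            stack.extend(e.dependent for e in reversed(self._children[j]))

    def words(self) -> list[str]:
        return [n.word for n in self.nodes]

    @property
    def text(self) -> str:
        return " ".join(self.words())

    # -- serialization -----------------------------------------------------
    def serialize_bracketed(self) -> str:
        """Bracketed-dialect string; leaf children are inlined as ``rel>word/POS``."""

        def render(i: int) -> str:
            n = self._nodes[i]
            head = f"{n.word}/{n.pos or '_'}"
            parts = [head]
            for e in self._children[i]:
                if self._children[e.dependent]:
                    parts.append(f"{e.relation}>{render(e.dependent)}")
                else:
                    d = self._nodes[e.dependent]
                    parts.append(f"{e.relation}>{d.word}/{d.pos or '_'}")
            return "[" + " ".join(parts) + "]"

        return render(self._root)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"DependencyTree({self.serialize_bracketed()!r})"


# ---------------------------------------------------------------------------
# bracketed dialect
# ---------------------------------------------------------------------------


def parse_bracketed_tree(text: str) -> DependencyTree:
    """Parse the bracketed tree dialect ``[word/POS rel>child ...]``.

    Children are either leaves ``rel>word/POS`` or bracketed subtrees
    ``rel>[...]``. Token indices are assigned in serialization (pre-order)
    order, 1-based. Raises :class:`TreeFormatError` naming the character
    offset of the first problem.
    """
    s = text.strip()
    pos = 0
    nodes: list[DepNode] = []
    edges: list[DepEdge] = []

    def err(msg: str, at: int) -> TreeFormatError:
        return TreeFormatError(f"{msg} at offset {at}")

    def skip_ws() -> None:
        nonlocal pos
        while pos < len(s) and s[pos].isspace():
            pos += 1

    def read_atom() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and not s[pos].isspace() and s[pos] not in "[]":
            pos += 1
        if pos == start:
            raise err("expected token", start)
        return s[start:pos]

    def make_node(atom: str, at: int) -> int:
        if "/" not in atom:
            raise err(f"missing /POS in {atom!r}", at)
        word, tag = atom.rsplit("/", 1)
        if not word or not tag:
            raise err(f"malformed word/POS token {atom!r}", at)
        idx = len(nodes) + 1
        nodes.append(DepNode(index=idx, word=word, pos=tag))
        return idx

    def parse_subtree() -> int:
        nonlocal pos
        skip_ws()
        if pos >= len(s) or s[pos] != "[":
            raise err("expected '['", pos)
        pos += 1
        skip_ws()
        at = pos
        head = make_node(read_atom(), at)
        while True:
            skip_ws()
            if pos >= len(s):
                raise err("unbalanced brackets: missing ']'", pos)
            if s[pos] == "]":
                pos += 1
                return head
            at = pos
            item = read_atom()
            if ">" not in item:
                raise err(f"missing 'rel>' in child {item!r}", at)
            rel, rest = item.split(">", 1)
            if not rel:
                raise err("empty relation label", at)
            if rest:
                child = make_node(rest, at)
            else:
                skip_ws()
                if pos >= len(s) or s[pos] != "[":
                    raise err("expected subtree after 'rel>'", pos)
                child = parse_subtree()
            edges.append(DepEdge(governor=head, relation=rel, dependent=child))

    root = parse_subtree()
    skip_ws()
    if pos != len(s):
        raise err("trailing text after tree", pos)
    return DependencyTree(nodes, edges, root)


# ---------------------------------------------------------------------------
# CoNLL-U
# ---------------------------------------------------------------------------


def parse_conllu_block(lines: list[str], sent_id: str = "?") -> DependencyTree:
    """Build one tree from the token lines of a CoNLL-U sentence block."""
    rows: list[tuple[int, str, Optional[str], Optional[str], int, str]] = []
    for ln in lines:
        cols = ln.rstrip("\n").split("\t")
        if len(cols) == 1:  # tolerate space-separated toy input
            cols = ln.split()
        if len(cols) < 8:
            raise TreeFormatError(f"sentence {sent_id}: expected >=8 columns: {ln!r}")
        tok_id = cols[0]
        if "-" in tok_id or "." in tok_id:
            continue  # multiword-token and empty-node lines carry no tree edge
        try:
            idx = int(tok_id)
            head = int(cols[6])
        except ValueError as exc:
            raise TreeFormatError(f"sentence {sent_id}: bad ID/HEAD in {ln!r}") from exc
        form = cols[1]
        lemma = None if cols[2] in ("_", "") else cols[2]
        upos = None if cols[3] in ("_", "") else cols[3]
        rows.append((idx, form, lemma, upos, head, cols[7]))
    if not rows:
        raise TreeFormatError(f"sentence {sent_id}: no token lines")
    nodes = [DepNode(index=i, word=w, lemma=lm, pos=p) for i, w, lm, p, _, _ in rows]
    ids = {n.index for n in nodes}
    edges = []
    roots = []
    for idx, _, _, _, head, rel in rows:
        if head == 0:
            roots.append(idx)
        elif head not in ids:
            raise TreeFormatError(f"sentence {sent_id}: HEAD {head} out of range")
        else:
            edges.append(DepEdge(governor=head, relation=rel, dependent=idx))
    if len(roots) != 1:
        raise TreeFormatError(f"sentence {sent_id}: expected exactly 1 root, got {len(roots)}")
    try:
        return DependencyTree(nodes, edges, roots[0])
    except ValueError as exc:
        raise TreeFormatError(f"sentence {sent_id}: {exc}") from exc


def read_conllu(stream: Union[TextIO, Iterable[str], str]) -> list[DependencyTree]:
    """Read all sentence blocks of a CoNLL-U document.

    ``stream`` may be an open file, an iterable of lines, or the document
    text itself. ``#`` comment lines are ignored; ``HEAD`` 0 marks the root.
    """
    if isinstance(stream, str):
        lines: Iterable[str] = stream.splitlines()
    else:
        lines = stream
    trees: list[DependencyTree] = []
    block: list[str] = []
    sent_id = None
    n_blocks = 0

    def flush() -> None:
        nonlocal block, sent_id, n_blocks
        if block:
            n_blocks += 1
            trees.append(parse_conllu_block(block, sent_id or str(n_blocks)))
        block = []
        sent_id = None

    for raw in lines:
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            if line[1:].strip().startswith("sent_id"):
                _, _, v = line.partition("=")
                sent_id = v.strip()
            continue
        block.append(line)
    flush()
    return trees


# ---------------------------------------------------------------------------
# structural comparison
# ---------------------------------------------------------------------------


def _structure_key(tree: DependencyTree, index: int) -> tuple:
    n = tree.node(index)
    kids = sorted(
        (e.relation, e.indirect, _structure_key(tree, e.dependent))
        for e in tree.children(index)
    )
    return (n.word.lower(), (n.pos or "").lower(), tuple(kids))


def isomorphic(a: DependencyTree, b: DependencyTree) -> bool:
    """True when the two trees are equal up to token indices and child order.

    Words and POS tags are compared case-insensitively; lemmas are ignored
    (the bracketed dialect does not carry them).
    """
    return _structure_key(a, a.root.index) == _structure_key(b, b.root.index)
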