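"""Constituency parse trees in Penn-bracketed notation, plus typed-dependency graphs.

These are the two syntactic containers the pipeline consumes.  Trees are
produced by an external constituency parser and read from one-tree-per-line
bracketed text; dependencies arrive as a small CoNLL-like table.  Both are
plain in-memory structures — no parser is bundled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import networkx as nx

__all__ = [
    "ParseNode",
    "DependencyGraph",
    "TreeParseError",
    "parse_bracketed",
    "write_bracketed",
    "assign_spans",
]


class TreeParseError(ValueError):
    """Malformed bracketed tree; carries the character position of the fault."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at character {position})")
        self.position = position


@dataclass
class ParseNode:
    """A node of a constituency tree.

    A leaf carries the surface token in ``word`` (its ``label`` equals the
    word); a pre-terminal is a node whose single child is a leaf (a POS tag
    node).  ``start``/``end`` are 0-based half-open token spans filled in by
    :func:`assign_spans`.
    """

    label: str
    children: list["ParseNode"] = field(default_factory=list)
    word: Optional[str] = None
    start: int = -1
    end: int = -1

    @property
    def is_leaf(self) -> bool:
        return self.word is not None

    @property
    def is_preterminal(self) -> bool:
        return len(self.children) == 1 and self.children[0].is_leaf

    def leaves(self) -> list["ParseNode"]:
        if self.is_leaf:
            return [self]
        out: list[ParseNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def iter_nodes(self) -> Iterator["ParseNode"]:
        """All nodes in pre-order, leaves included."""
        yield self
        for c in self.children:
            yield from c.iter_nodes()

    def internal_nodes(self) -> list["ParseNode"]:
        """Non-leaf nodes; the node set the tree kernel sums over."""
        return [n for n in self.iter_nodes() if not n.is_leaf]

    def production(self) -> tuple:
        """Node label together with the ordered labels of its direct children.

        Leaf children contribute their surface word, so two pre-terminals over
        different words have different productions.
        """
        return (self.label,) + tuple(c.label for c in self.children)

    def copy(self) -> "ParseNode":
        return ParseNode(
            self.label,
            [c.copy() for c in self.children],
            self.word,
            self.start,
            self.end,
        )

    def tokens(self) -> list[str]:
        return [leaf.word for leaf in self.leaves()]

    def __str__(self) -> str:
        return write_bracketed(self)

    # Structural equality on labels/words/shape (spans are derived data).
    def equals(self, other: "ParseNode") -> bool:
        if self.label != other.label or self.word != other.word:
            return False
        if len(self.children) != len(other.children):
            return False
        return all(a.equals(b) for a, b in zip(self.children, other.children))


def parse_bracketed(text: str) -> ParseNode:
    """Parse a single Penn-bracketed tree such as ``(S (NP (NN a)) ...)``.

    Labels and leaves are whitespace-delimited; raises :class:`TreeParseError`
    with the character position on unbalanced or truncated input.
    """
    pos = 0
    n = len(text)

    def skip_ws() -> None:
        nonlocal pos
        while pos < n and text[pos].isspace():
            pos += 1

    def read_token() -> str:
        nonlocal pos
        start = pos
        while pos < n and not text[pos].isspace() and text[pos] not in "()":
            pos += 1
        if pos == start:
            raise TreeParseError("expected a label or token", pos)
        return text[start:pos]

    def read_node() -> ParseNode:
        nonlocal pos
        skip_ws()
        if pos >= n or text[pos] != "(":
            raise TreeParseError("expected '('", pos)
        pos += 1
        skip_ws()
        label = read_token()
        node = ParseNode(label)
        while True:
            skip_ws()
            if pos >= n:
                raise TreeParseError("unbalanced parentheses: unexpected end of input", pos)
            if text[pos] == ")":
                pos += 1
                if not node.children:
                    raise TreeParseError("node without children or leaf", pos)
                return node
            if text[pos] == "(":
                node.children.append(read_node())
            else:
                word = read_token()
                node.children.append(ParseNode(word, word=word))
        # unreachable

    skip_ws()
    root = read_node()
    skip_ws()
    if pos != n:
        raise TreeParseError("trailing content after tree", pos)
    assign_spans(root)
    return root


def write_bracketed(node: ParseNode) -> str:
    if node.is_leaf:
        return node.word
    inner = " ".join(write_bracketed(c) for c in node.children)
    return f"({node.label} {inner})"


def assign_spans(root: ParseNode) -> ParseNode:
    """Number leaves left to right and set 0-based half-open token spans."""
    counter = [0]

    def visit(node: ParseNode) -> None:
        if node.is_leaf:
            node.start = counter[0]
            node.end = counter[0] + 1
            counter[0] += 1
            return
        for c in node.children:
            visit(c)
        node.start = node.children[0].start
        node.end = node.children[-1].end

    visit(root)
    return root


@dataclass
class DependencyGraph:
    """Typed dependencies over a token sequence.

    Each edge is ``(relation, governor index, dependent index)``.  The graph
    is traversed undirected when searching for the protein dependency path.
    """

    tokens: list[str]
    edges: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ntok = len(self.tokens)
        for rel, gov, dep in self.edges:
            if not (0 <= gov < ntok) or not (0 <= dep < ntok):
                raise ValueError(
                    f"dependency '{rel}' references token index out of range "
                    f"(governor={gov}, dependent={dep}, {ntok} tokens)"
                )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.tokens)))
        for rel, gov, dep in self.edges:
            g.add_edge(gov, dep, relation=rel)
        return g
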