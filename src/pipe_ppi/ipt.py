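"""Interaction Pattern Tree (IPT) construction.

The IPT of a candidate sentence is its shortest-path-enclosed tree (SPET,
the minimal constituency subtree linking the two target proteins) enhanced by
three operators applied in a fixed order: branching (re-attach a trailing
verb that forms a verb phrase with the second protein), pruning (remove
middle clauses off the protein dependency path, stop-word leaves, and
duplicate unary same-label nodes) and ornamenting (attach an IP tag per
matched interaction pattern under the root).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx

from .candidates import PROTEIN_LABELS, ExpandedCandidate
from .formats_io import RunConfig, TriggerLexicon
from .mining import InteractionPattern, match_pattern
from .semantic import label_semantic_classes
from .stemming import porter_stem
from .tree import DependencyGraph, ParseNode, assign_spans

__all__ = [
    "IPT",
    "StopwordList",
    "extract_spet",
    "branch",
    "protein_dependency_path",
    "prune_middle_clauses",
    "build_stopword_list",
    "prune_stopwords",
    "remove_duplicate_nodes",
    "ornament",
    "construct_ipt",
]

_CLAUSE_LABELS = {"SBAR", "SBARQ"}


@dataclass
class StopwordList:
    """Stemmed high-frequency words to prune; never verbs or protein labels."""

    stems: set[str] = field(default_factory=set)

    def __contains__(self, token: str) -> bool:
        return porter_stem(token) in self.stems


@dataclass
class IPT:
    """The transformed SPET together with the ids of matched patterns."""

    root: ParseNode
    ip_tags: list[str] = field(default_factory=list)


def _find_lca(root: ParseNode, span1: tuple[int, int], span2: tuple[int, int]) -> ParseNode:
    lo, hi = span1[0], span2[1]
    node = root
    while True:
        nxt = None
        for c in node.children:
            if not c.is_leaf and c.start <= lo and c.end >= hi:
                nxt = c
                break
        if nxt is None:
            return node
        node = nxt


def extract_spet(
    tree: ParseNode,
    m1: tuple[int, int],
    m2: tuple[int, int],
) -> ParseNode:
    """Shortest-path-enclosed tree for the mention token spans ``m1 < m2``.

    Returns a copy of the lowest common ancestor restricted to leaves inside
    the half-open token interval [start(m1), end(m2)); material before the
    first or after the second mention is dropped.
    """
    assign_spans(tree)
    lo, hi = m1[0], m2[1]
    n_tok = tree.end
    if not (0 <= m1[0] < m1[1] <= n_tok) or not (0 <= m2[0] < m2[1] <= n_tok):
        raise ValueError("mention span outside the tree's token range")
    if m1[0] >= m2[0]:
        raise ValueError("first mention must precede the second")
    lca = _find_lca(tree, m1, m2)

    def restrict(node: ParseNode) -> Optional[ParseNode]:
        if node.is_leaf:
            if lo <= node.start < hi:
                return node.copy()
            return None
        kept = [restrict(c) for c in node.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        out = ParseNode(node.label, kept)
        return out

    spet = restrict(lca)
    if spet is None:
        raise ValueError("mentions not found under the computed ancestor")
    return assign_spans_offset(spet, lo)


def assign_spans_offset(root: ParseNode, offset: int = 0) -> ParseNode:
    """Like :func:`tree.assign_spans` but numbering leaves from ``offset`` so
    subtree spans stay aligned with the original sentence."""
    counter = [offset]

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


def _respan_sparse(root: ParseNode) -> ParseNode:
    """Recompute internal spans from (possibly non-contiguous) leaf spans."""

    def visit(node: ParseNode) -> None:
        if node.is_leaf:
            return
        for c in node.children:
            visit(c)
        node.start = min(c.start for c in node.children)
        node.end = max(c.end for c in node.children)

    visit(root)
    return root


def branch(
    ipt: ParseNode,
    full_tree: ParseNode,
    m2: tuple[int, int],
) -> ParseNode:
    """Branching operator: re-attach a trailing verb to the IPT.

    If some verb (POS tag starting with VB) follows the second target protein
    in the full tree and both sit under a common VP whose span covers the
    protein, the verb modifies the protein: its pre-terminal, wrapped in the
    VP spine connecting it to that shared VP, is appended to the IPT root.
    Otherwise the IPT is returned unchanged.
    """
    assign_spans(full_tree)
    out = ipt.copy()

    def vp_path_to_verb(node: ParseNode, path: list[ParseNode]) -> Optional[list[ParseNode]]:
        """Deepest-first search for the first verb pre-terminal after m2."""
        if node.is_preterminal:
            if node.label.startswith("VB") and node.start >= m2[1]:
                return path + [node]
            return None
        for c in node.children:
            if c.is_leaf:
                continue
            found = vp_path_to_verb(c, path + [node])
            if found is not None:
                return found
        return None

    # candidate shared VPs: cover m2, contain a later verb
    best: Optional[list[ParseNode]] = None
    for node in full_tree.iter_nodes():
        if node.is_leaf or node.label != "VP":
            continue
        if not (node.start <= m2[0] and node.end >= m2[1]):
            continue
        found = vp_path_to_verb(node, [])
        if found is not None and (best is None or len(found) > len(best)):
            best = found  # innermost shared VP gives the longest remaining path

    if best is None:
        return out
    verb = best[-1]
    spine = verb.copy()
    for anc in reversed(best[:-1]):
        if anc.label == "VP":
            spine = ParseNode("VP", [spine])
    out.children.append(spine)
    return _respan_sparse(out)


def protein_dependency_path(
    deps: DependencyGraph,
    m1: tuple[int, int],
    m2: tuple[int, int],
) -> list[int]:
    """Shortest undirected path between the mention head tokens.

    The head of a multi-token mention is its last token.  Ties are broken by
    the lexicographically smallest index sequence; a disconnected pair yields
    an empty path (no pruning possible).
    """
    g = deps.to_networkx()
    src, dst = m1[1] - 1, m2[1] - 1
    if src == dst:
        return [src]
    try:
        paths = nx.all_shortest_paths(g, src, dst)
        return min(paths)
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        return []


def prune_middle_clauses(
    ipt: ParseNode,
    dep_path: Sequence[int],
    m1: tuple[int, int],
    m2: tuple[int, int],
) -> ParseNode:
    """Remove middle clauses that the protein dependency path does not touch.

    A clause is an SBAR-labeled node (or a clause-level node opening with a
    WH-word) lying strictly between the two mentions.  With an empty
    dependency path the operator is skipped.
    """
    out = ipt.copy()
    if not dep_path:
        return out
    on_path = set(dep_path)

    def is_middle_clause(node: ParseNode) -> bool:
        if node.is_leaf:
            return False
        if node.label not in _CLAUSE_LABELS:
            return False
        return node.start >= m1[1] and node.end <= m2[0]

    def prune(node: ParseNode) -> Optional[ParseNode]:
        if node.is_leaf:
            return node
        if is_middle_clause(node) and not any(
                leaf.start in on_path for leaf in node.leaves()):
            return None
        kept = [prune(c) for c in node.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        node.children = kept
        return node

    pruned = prune(out)
    if pruned is None:  # degenerate: everything was clause material
        return ipt.copy()
    return _respan_sparse(pruned)


def build_stopword_list(
    token_pos_pairs: list[tuple[str, str]],
    config: RunConfig | None = None,
    protein_names: set[str] | None = None,
) -> StopwordList:
    """Compile the stop-word list from corpus frequency.

    Words are sorted by descending frequency; the smallest prefix reaching
    ``stopword_cumfreq`` of the total count is kept, then verbs (any VB* POS
    occurrence) and protein names/labels are removed.
    """
    config = config or RunConfig()
    protein_names = protein_names or set()
    freq: Counter[str] = Counter()
    verb_words: set[str] = set()
    for tok, pos in token_pos_pairs:
        tok_l = tok.lower()
        freq[tok_l] += 1
        if pos.startswith("VB"):
            verb_words.add(tok_l)
    total = sum(freq.values())
    if total == 0:
        return StopwordList(set())
    kept: list[str] = []
    cum = 0
    for word, n in sorted(freq.items(), key=lambda kv: (-kv[1], kv[0])):
        if cum >= config.stopword_cumfreq * total:
            break
        kept.append(word)
        cum += n
    excluded = verb_words | {p.lower() for p in protein_names} | {
        p.lower() for p in PROTEIN_LABELS}
    return StopwordList({porter_stem(w) for w in kept if w not in excluded})


def prune_stopwords(ipt: ParseNode, stopwords: StopwordList) -> ParseNode:
    """Remove stop-word leaves and any ancestors left childless.

    Protein placeholder leaves are always kept, so the cascade can never
    delete the root while a protein leaf remains.
    """

    def prune(node: ParseNode) -> Optional[ParseNode]:
        if node.is_leaf:
            if node.word in PROTEIN_LABELS:
                return node
            return None if node.word in stopwords else node
        kept = [prune(c) for c in node.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        node.children = kept
        return node

    out = prune(ipt.copy())
    if out is None:
        return ipt.copy()
    return _respan_sparse(out)


def remove_duplicate_nodes(ipt: ParseNode) -> ParseNode:
    """Collapse unary same-label chains (a node whose single child repeats its
    tag) to a fixed point; afterwards no unary same-label edge remains."""
    out = ipt.copy()

    def collapse(node: ParseNode) -> ParseNode:
        node.children = [collapse(c) for c in node.children]
        while (len(node.children) == 1
               and not node.children[0].is_leaf
               and node.children[0].label == node.label):
            node.children = node.children[0].children
        return node

    return _respan_sparse(collapse(out))


def ornament(ipt: ParseNode, matched_pattern_ids: list[str]) -> IPT:
    """Append one (IP <pattern id>) child under the root per matched pattern,
    in rank order."""
    root = ipt.copy()
    for pid in matched_pattern_ids:
        root.children.append(ParseNode("IP", [ParseNode(pid, word=pid)]))
    return IPT(root=root, ip_tags=list(matched_pattern_ids))


def pattern_ids(patterns: list[InteractionPattern]) -> list[str]:
    """Stable rank-order ids (IP1, IP2, ...) for a selected pattern list."""
    return [f"IP{i + 1}" for i in range(len(patterns))]


def construct_ipt(
    candidate: ExpandedCandidate,
    patterns: list[InteractionPattern],
    stopwords: StopwordList,
    lexicon: TriggerLexicon,
    config: RunConfig | None = None,
) -> IPT:
    """Full IPT pipeline for one expanded candidate.

    SPET -> branching -> middle-clause pruning -> stop-word pruning ->
    duplicate-node removal -> ornamenting, in that fixed order.  Degenerate
    stages (no trailing verb, empty dependency path, no matches) are skipped
    rather than failing.
    """
    if candidate.parse is None:
        raise ValueError("candidate has no parse tree")
    tree = candidate.parse
    m1, m2 = candidate.m1, candidate.m2
    ipt = extract_spet(tree, m1, m2)
    ipt = branch(ipt, tree, m2)
    dep_path = (protein_dependency_path(candidate.deps, m1, m2)
                if candidate.deps is not None else [])
    ipt = prune_middle_clauses(ipt, dep_path, m1, m2)
    ipt = prune_stopwords(ipt, stopwords)
    ipt = remove_duplicate_nodes(ipt)
    seq = label_semantic_classes(candidate.normalized, lexicon, require_pair=False)
    ids = pattern_ids(patterns)
    matched = [pid for pid, pat in zip(ids, patterns) if match_pattern(pat, seq)]
    return ornament(ipt, matched)
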