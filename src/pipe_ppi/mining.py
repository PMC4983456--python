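"""Interaction-pattern mining.

Frequent semantic classes are selected by a Zipf cumulative-frequency cutoff
over the positive sentences, a directed co-occurrence graph with
association-rule support/confidence thresholds is built over them, candidate
patterns are harvested by seeded random walks on the row-stochastic
transition matrix, merged (coverage removal and pivot concatenation), scored
by the sum of their member classes' log-likelihood-ratio values and the
top k retained.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .candidates import PROTEIN_LABELS
from .formats_io import RunConfig
from .semantic import SCSequence

__all__ = [
    "SemanticGraph",
    "InteractionPattern",
    "ContingencyCounts",
    "select_frequent_scs",
    "build_semantic_graph",
    "random_walk_patterns",
    "merge_patterns",
    "llr_score",
    "llr_map",
    "rank_and_select_patterns",
    "match_pattern",
    "mine_patterns",
]

_EPS = 1e-9


@dataclass(frozen=True)
class InteractionPattern:
    """An ordered semantic-class sequence with its summed-LLR score."""

    labels: tuple[str, ...]
    score: float = 0.0

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError("an interaction pattern needs at least 2 labels")
        if not math.isfinite(self.score):
            raise ValueError("pattern score must be finite")

    def __len__(self) -> int:
        return len(self.labels)

    def render(self) -> str:
        return "->".join(f"[{x}]" for x in self.labels)


@dataclass
class SemanticGraph:
    """Directed SC co-occurrence graph with association-rule statistics.

    ``edges[(i, j)]`` holds ``(support, confidence, weight)`` where the
    weight row M[i, .] is the confidence renormalized over retained
    out-edges, so every vertex with out-edges has a row summing to 1.
    """

    vertices: list[str]
    edges: dict[tuple[str, str], tuple[int, float, float]] = field(default_factory=dict)

    def out_edges(self, sc: str) -> list[tuple[str, float]]:
        return [(j, w) for (i, j), (_, _, w) in self.edges.items() if i == sc]

    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class ContingencyCounts:
    """Sentence counts for one semantic class against the positive label."""

    n_pos: int
    n_neg: int
    n_sc_pos: int
    n_sc_neg: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_sc_pos <= self.n_pos) or not (0 <= self.n_sc_neg <= self.n_neg):
            raise ValueError("contingency counts out of range")


def select_frequent_scs(
    sequences: list[SCSequence],
    labels: list[int],
    config: RunConfig | None = None,
) -> set[str]:
    """Frequent trigger semantic classes in the positive sentences.

    Classes are sorted by descending occurrence frequency (ties
    alphabetical); the smallest prefix whose cumulative frequency first
    exceeds ``sc_cumfreq`` of the total is kept, and every member must in
    addition occur strictly more than ``support_min`` times.  The protein
    placeholder labels anchor every pattern and are exempt from the cutoff:
    they are always returned when present.
    """
    config = config or RunConfig()
    positives = [seq for seq, y in zip(sequences, labels) if y > 0]
    if not positives:
        raise ValueError("frequent-SC selection requires at least one positive sentence")
    freq: Counter[str] = Counter()
    proteins: set[str] = set()
    for seq in positives:
        for lab in seq:
            if lab in PROTEIN_LABELS:
                proteins.add(lab)
            else:
                freq[lab] += 1
    total = sum(freq.values())
    selected: set[str] = set()
    if total > 0:
        cum = 0
        for lab, n in sorted(freq.items(), key=lambda kv: (-kv[1], kv[0])):
            if cum > config.sc_cumfreq * total:
                break
            selected.add(lab)
            cum += n
    selected = {lab for lab in selected if freq[lab] > config.support_min}
    return selected | proteins


def build_semantic_graph(
    sequences: list[SCSequence],
    frequent_scs: set[str],
    config: RunConfig | None = None,
    labels: list[int] | None = None,
) -> SemanticGraph:
    """Directed co-occurrence graph over the frequent semantic classes.

    An edge SC_i -> SC_j is created when SC_i immediately precedes SC_j in a
    (by default positive) sequence restricted to the frequent classes.
    Support counts the sequences containing the adjacency;
    confidence(SC_i => SC_j) = support(SC_i u SC_j) / support(SC_i).  Edges
    below ``support_min`` (inclusive threshold) or ``confidence_min`` are
    dropped, and surviving confidences are renormalized per row so the
    transition matrix is row-stochastic.
    """
    config = config or RunConfig()
    if not frequent_scs:
        raise ValueError("frequent_scs must be nonempty")
    if labels is not None:
        sequences = [s for s, y in zip(sequences, labels) if y > 0]
    vertex_support: Counter[str] = Counter()
    pair_support: Counter[tuple[str, str]] = Counter()
    for seq in sequences:
        restricted = [lab for lab in seq if lab in frequent_scs]
        vs = set(restricted)
        pairs = {(a, b) for a, b in zip(restricted, restricted[1:]) if a != b}
        for v in vs:
            vertex_support[v] += 1
        for p in pairs:
            pair_support[p] += 1

    retained: dict[tuple[str, str], tuple[int, float, float]] = {}
    for (a, b), sup in pair_support.items():
        if sup < config.support_min:
            continue
        conf = sup / vertex_support[a]
        if conf < config.confidence_min:
            continue
        retained[(a, b)] = (sup, conf, 0.0)

    # renormalize confidences into row-stochastic transition weights
    row_sum: Counter[str] = Counter()
    for (a, _), (_, conf, _) in retained.items():
        row_sum[a] += conf
    for key, (sup, conf, _) in list(retained.items()):
        retained[key] = (sup, conf, conf / row_sum[key[0]])

    vertices = sorted(frequent_scs & (set(vertex_support) | {v for e in retained for v in e}))
    return SemanticGraph(vertices=vertices, edges=retained)


def random_walk_patterns(
    graph: SemanticGraph,
    seed: int = 0,
    frequent_scs: set[str] | None = None,
) -> list[InteractionPattern]:
    """Harvest candidate patterns by random walks on the semantic graph.

    Walks start at every frequent class and at each of its out-neighbors,
    cycling through the start set; each step samples the next class from the
    transition weights.  A walk ends at a sink or after |V| steps, and every
    visited prefix of length >= 2 is emitted.  The total number of steps
    across all walks is capped at 4|E|^2 (a cover-time bound for random
    walks), so the procedure terminates on any graph.  Deterministic for a
    given seed.
    """
    if not graph.vertices or not graph.edges:
        return []
    starts_from = sorted(frequent_scs & set(graph.vertices)) if frequent_scs else list(graph.vertices)
    starts: list[str] = []
    for v in starts_from:
        if v not in starts:
            starts.append(v)
        for m, _ in sorted(graph.out_edges(v)):
            if m not in starts:
                starts.append(m)
    rng = np.random.default_rng(seed)
    budget = 4 * graph.n_edges() ** 2
    max_len = max(len(graph.vertices), 2)
    out: list[InteractionPattern] = []
    steps = 0
    start_i = 0
    while steps < budget:
        v = starts[start_i % len(starts)]
        start_i += 1
        walk = [v]
        while steps < budget and len(walk) < max_len:
            nbrs = sorted(graph.out_edges(walk[-1]))
            if not nbrs:
                break
            weights = np.array([w for _, w in nbrs])
            nxt = nbrs[rng.choice(len(nbrs), p=weights / weights.sum())][0]
            walk.append(nxt)
            steps += 1
            out.append(InteractionPattern(labels=tuple(walk)))
        if not graph.out_edges(v):
            steps += 1  # a sunk start still consumes budget
    # deduplicate, preserving the multiset order-insensitively
    seen: dict[tuple[str, ...], InteractionPattern] = {}
    for p in out:
        seen.setdefault(p.labels, p)
    return list(seen.values())


def _contiguous_subseq(small: tuple[str, ...], big: tuple[str, ...]) -> bool:
    if len(small) > len(big):
        return False
    return any(big[i:i + len(small)] == small for i in range(len(big) - len(small) + 1))


def merge_patterns(patterns: list[InteractionPattern]) -> list[InteractionPattern]:
    """Merge redundant walk patterns to a fixed point.

    (1) A pattern that is a contiguous subsequence of another is removed;
    (2) a bigram whose tail equals the head class of another pattern is
    concatenated with it at that pivot.  Output order is deterministic
    (longest first, then lexicographic).
    """
    current = {p.labels for p in patterns}
    max_len = 4 * max((len(p) for p in current), default=2)
    for _ in range(32):
        changed = False
        # pivot concatenation of bigrams
        additions: set[tuple[str, ...]] = set()
        for b in sorted(current):
            if len(b) != 2:
                continue
            for p in sorted(current):
                if p is b or p == b:
                    continue
                if p[0] == b[1] and len(b) + len(p) - 1 <= max_len:
                    additions.add(b[:1] + p)
        if additions - current:
            current |= additions
            changed = True
        # coverage removal
        keep = {p for p in current
                if not any(p != q and _contiguous_subseq(p, q) for q in current)}
        if keep != current:
            current = keep
            changed = True
        if not changed:
            break
    ordered = sorted(current, key=lambda p: (-len(p), p))
    return [InteractionPattern(labels=p) for p in ordered]


def llr_score(counts: ContingencyCounts) -> float:
    """-2 log likelihood-ratio that a class occurs independently of the label.

    The null pools both sentence sets (rate p(SC)); the alternative uses the
    class-conditional rates p(SC|I) and p(SC|not I), all by maximum
    likelihood.  Zero probabilities are clamped at 1e-9 to keep the statistic
    finite; the value is >= 0 up to floating error and 0 when the conditional
    rates are equal.
    """
    n1, n2 = counts.n_pos, counts.n_neg
    k1, k2 = counts.n_sc_pos, counts.n_sc_neg
    if n1 == 0 and n2 == 0:
        raise ValueError("LLR undefined without any sentences")

    def _clamp(p: float) -> float:
        return min(max(p, _EPS), 1.0 - _EPS)

    p0 = _clamp((k1 + k2) / (n1 + n2))
    p_pos = _clamp(k1 / n1) if n1 else p0
    p_neg = _clamp(k2 / n2) if n2 else p0

    def _ll(k: int, n: int, p: float) -> float:
        return k * math.log(p) + (n - k) * math.log(1.0 - p)

    null = _ll(k1, n1, p0) + _ll(k2, n2, p0)
    alt = _ll(k1, n1, p_pos) + _ll(k2, n2, p_neg)
    return -2.0 * (null - alt)


def llr_map(sequences: list[SCSequence], labels: list[int]) -> dict[str, float]:
    """Per-class LLR values from sentence-level presence counts."""
    n_pos = sum(1 for y in labels if y > 0)
    n_neg = len(labels) - n_pos
    presence_pos: Counter[str] = Counter()
    presence_neg: Counter[str] = Counter()
    for seq, y in zip(sequences, labels):
        for lab in set(seq.labels):
            (presence_pos if y > 0 else presence_neg)[lab] += 1
    out: dict[str, float] = {}
    for lab in set(presence_pos) | set(presence_neg):
        out[lab] = llr_score(ContingencyCounts(
            n_pos=n_pos, n_neg=n_neg,
            n_sc_pos=presence_pos[lab], n_sc_neg=presence_neg[lab]))
    return out


def rank_and_select_patterns(
    patterns: list[InteractionPattern],
    llr_by_sc: dict[str, float],
    k: int = 20,
) -> list[InteractionPattern]:
    """Rank patterns by the sum of member-class LLR values and keep the top k.

    A class with no LLR value contributes 0.  Ties go to the longer pattern,
    then lexicographic label order.
    """
    scored = [InteractionPattern(labels=p.labels,
                                 score=sum(llr_by_sc.get(lab, 0.0) for lab in p.labels))
              for p in patterns]
    scored.sort(key=lambda p: (-p.score, -len(p), p.labels))
    return scored[:k]


def match_pattern(pattern: InteractionPattern, seq: SCSequence) -> bool:
    """True iff the pattern labels occur as an ordered (not necessarily
    contiguous) subsequence of the sequence labels."""
    it = iter(seq.labels)
    return all(lab in it for lab in pattern.labels)


def mine_patterns(
    sequences: list[SCSequence],
    labels: list[int],
    config: RunConfig | None = None,
) -> list[InteractionPattern]:
    """Full mining pipeline: frequent SCs -> graph -> walks -> merge -> rank."""
    config = config or RunConfig()
    frequent = select_frequent_scs(sequences, labels, config)
    graph = build_semantic_graph(sequences, frequent, config, labels=labels)
    raw = random_walk_patterns(graph, seed=config.seed, frequent_scs=frequent)
    merged = merge_patterns(raw)
    return rank_and_select_patterns(merged, llr_map(sequences, labels),
                                    k=config.top_k_patterns)
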