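"""Seeded synthetic PPI corpora with planted interaction patterns.

Positive sentences realize a planted semantic-class pattern as ordered
trigger words around a protein pair; negative sentences contain two proteins
but no trigger words, so pattern presence separates the classes by
construction.  Parse trees and dependencies are derived deterministically
from sentence templates, which removes any parser dependency from tests.
The module also ships three hand-authored worked-example fixtures (the
CREB/CBP relative-clause sentence, the gp130/hLIF binding-site sentence and
the Sec24p/Iss1p/Sec16p three-protein sentence) used throughout the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

import re

from .candidates import PROTEIN1, PROTEIN2, ExpandedCandidate
from .formats_io import AnnotatedDocument, ProteinAnnotation, write_dependency_graph
from .tree import DependencyGraph, ParseNode, assign_spans, parse_bracketed, write_bracketed

__all__ = [
    "FixtureSpec",
    "SyntheticCorpus",
    "WorkedFixture",
    "generate_corpus",
    "worked_example_fixtures",
]

DEFAULT_PLANTED_PATTERNS = (
    ("PROTEIN1", "Binding", "PROTEIN2"),
    ("PROTEIN1", "Binding", "Regulation", "PROTEIN2"),
)

_PROTEIN_POOL = [
    "CREB", "CBP", "Sec24p", "Iss1p", "Sec16p", "gp130", "hLIF", "NPY",
    "Pma1p", "Lst1p", "RAD51", "BRCA2",
]

# verb and noun realizations per semantic class; stems resolve to the
# default trigger lexicon
_VERB_FORMS = {
    "Binding": ["binds", "interacts"],
    "Regulation": ["regulates", "modulates"],
    "Positive_regulation": ["activates", "stimulates", "induces"],
    "Negative_regulation": ["inhibits", "represses", "reduces"],
    "Gene_expression": ["expresses"],
    "Transcription": ["transcribes"],
    "Localization": ["transports"],
    "Phosphorylation": ["phosphorylates"],
    "Antagonist": ["antagonizes"],
}
_NOUN_FORMS = {
    "Binding": ["binding", "interaction"],
    "Regulation": ["regulation", "modulation"],
    "Positive_regulation": ["activation", "induction"],
    "Negative_regulation": ["inhibition", "suppression"],
    "Gene_expression": ["expression"],
    "Transcription": ["transcription"],
    "Localization": ["secretion", "localization"],
    "Phosphorylation": ["phosphorylation"],
    "Antagonist": ["antagonism"],
}

# non-trigger filler vocabulary (no stem collides with a lexicon entry)
_NOISE_WORDS = ["cells", "tissue", "culture", "assays", "samples", "vivo", "vitro"]

_NEGATIVE_TEMPLATES = [
    ["{A}", "and", "{B}", "were", "measured", "in", "cells", "."],
    ["{A}", "was", "detected", "near", "{B}", "in", "tissue", "."],
    ["the", "levels", "of", "{A}", "and", "{B}", "varied", "."],
    ["{A}", "appeared", "alongside", "{B}", "in", "the", "sample", "."],
]
_NEGATIVE_VERBS = {"were", "was", "varied", "appeared", "measured", "detected"}


@dataclass
class FixtureSpec:
    """Conditions for one synthetic corpus.

    ``p_positive`` fixes the class balance exactly (round(n * p) positives);
    ``planted_patterns`` are the semantic-class sequences positives realize;
    ``noise_word_rate`` is the per-slot probability of inserting a
    non-trigger filler word.
    """

    n_sentences: int = 400
    p_positive: float = 0.5
    n_protein_names: int = 12
    planted_patterns: tuple[tuple[str, ...], ...] = DEFAULT_PLANTED_PATTERNS
    noise_word_rate: float = 0.15
    seed: int = 0
    n_pos: int | None = None  # exact-count mode overrides p_positive
    n_neg: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_positive <= 1.0):
            raise ValueError("p_positive must lie in [0, 1]")
        if self.resolved_counts()[0] > 0 and not self.planted_patterns:
            raise ValueError("positive sentences require nonempty planted_patterns")

    def resolved_counts(self) -> tuple[int, int]:
        if self.n_pos is not None and self.n_neg is not None:
            return self.n_pos, self.n_neg
        n_pos = round(self.n_sentences * self.p_positive)
        return n_pos, self.n_sentences - n_pos


@dataclass
class SyntheticCorpus:
    """A generated corpus in every representation downstream stages need."""

    documents: list[AnnotatedDocument]
    instances: list[ExpandedCandidate]
    labels: list[int]
    trees_text: str  # one bracketed tree per line, aligned with instances
    deps_text: str   # blank-line-separated dependency blocks


def _pos_tag(token: str, names: set[str]) -> str:
    if token in (PROTEIN1, PROTEIN2, "PROTEIN") or token in names:
        return "NN"
    if token in _NEGATIVE_VERBS:
        return "VBD"
    for forms in _VERB_FORMS.values():
        if token in forms:
            return "VBZ"
    if token in ("the", "a"):
        return "DT"
    if token in ("of", "in", "via", "near", "with", "between", "alongside", "through"):
        return "IN"
    if token == "and":
        return "CC"
    if token == ".":
        return "."
    return "NN"


def _build_tree(tokens: list[str], verb_idx: int, names: set[str]) -> ParseNode:
    """Deterministic template tree: (S (NP subject) (VP verb object) (. .))."""

    def pre(tok: str) -> ParseNode:
        return ParseNode(_pos_tag(tok, names), [ParseNode(tok, word=tok)])

    has_period = tokens and tokens[-1] == "."
    body = tokens[:-1] if has_period else tokens
    subject = body[:verb_idx]
    obj = body[verb_idx + 1:]
    s_children: list[ParseNode] = []
    if subject:
        s_children.append(ParseNode("NP", [pre(t) for t in subject]))
    vp_children = [pre(body[verb_idx])]
    if obj:
        vp_children.append(ParseNode("NP", [pre(t) for t in obj]))
    s_children.append(ParseNode("VP", vp_children))
    if has_period:
        s_children.append(pre("."))
    return assign_spans(ParseNode("S", s_children))


def _chain_deps(tokens: list[str]) -> DependencyGraph:
    edges = [("dep", i, i + 1) for i in range(len(tokens) - 1)]
    return DependencyGraph(tokens=list(tokens), edges=edges)


def _realize_positive(pattern: tuple[str, ...], a: str, b: str,
                      rng: np.random.Generator, noise_rate: float) -> tuple[list[str], int]:
    """Token list realizing ``pattern`` as ordered trigger words, plus the
    main-verb token index."""
    assert pattern[0] == PROTEIN1 and PROTEIN2 in pattern
    p2_at = pattern.index(PROTEIN2)
    middles = pattern[1:p2_at]      # classes between the pair
    trailing = pattern[p2_at + 1:]  # classes after the pair
    tokens = [a]
    verb_idx = 1
    if middles:
        first, rest = middles[0], middles[1:]
        tokens.append(_VERB_FORMS[first][rng.integers(len(_VERB_FORMS[first]))])
        for cls in rest:
            noun = _NOUN_FORMS[cls][rng.integers(len(_NOUN_FORMS[cls]))]
            tokens.extend(["the", noun, "of"])
    else:
        tokens.append("joins")  # non-trigger verb; pattern classes all trail
    tokens.append(b)
    for cls in trailing:
        noun = _NOUN_FORMS[cls][rng.integers(len(_NOUN_FORMS[cls]))]
        tokens.extend(["via", noun])
    if rng.random() < noise_rate:
        tokens.extend(["in", str(_NOISE_WORDS[rng.integers(len(_NOISE_WORDS))])])
    tokens.append(".")
    return tokens, verb_idx


def _realize_negative(a: str, b: str, rng: np.random.Generator,
                      noise_rate: float) -> tuple[list[str], int]:
    template = _NEGATIVE_TEMPLATES[rng.integers(len(_NEGATIVE_TEMPLATES))]
    tokens = [t.format(A=a, B=b) for t in template]
    if rng.random() < noise_rate:
        noise = str(_NOISE_WORDS[rng.integers(len(_NOISE_WORDS))])
        tokens = tokens[:-1] + ["in", noise, "."]
    verb_idx = next(i for i, t in enumerate(tokens) if t in _NEGATIVE_VERBS)
    return tokens, verb_idx


def generate_corpus(spec: FixtureSpec) -> SyntheticCorpus:
    """Generate a labeled corpus; byte-identical output for equal specs."""
    rng = np.random.default_rng(spec.seed)
    n_pos, n_neg = spec.resolved_counts()
    names = _PROTEIN_POOL[:spec.n_protein_names]
    if spec.n_protein_names > len(_PROTEIN_POOL):
        names = names + [f"PROT{i}" for i in range(len(_PROTEIN_POOL), spec.n_protein_names)]
    name_set = set(names)

    flags = [1] * n_pos + [-1] * n_neg
    rng.shuffle(flags)

    instances: list[ExpandedCandidate] = []
    labels: list[int] = []
    tree_lines: list[str] = []
    dep_blocks: list[str] = []
    passages: list[tuple[str, int]] = []
    annotations: list[ProteinAnnotation] = []
    offset = 0
    pos_counter = 0

    for sent_i, y in enumerate(flags):
        i_a = int(rng.integers(len(names)))
        i_b = int((i_a + 1 + rng.integers(len(names) - 1)) % len(names))
        a, b = names[i_a], names[i_b]
        if y > 0:
            pattern = spec.planted_patterns[pos_counter % len(spec.planted_patterns)]
            pos_counter += 1
            tokens, verb_idx = _realize_positive(pattern, a, b, rng, spec.noise_word_rate)
        else:
            tokens, verb_idx = _realize_negative(a, b, rng, spec.noise_word_rate)

        normalized = [PROTEIN1 if t == a else PROTEIN2 if t == b
                      else "PROTEIN" if t in name_set else t for t in tokens]
        m1 = (tokens.index(a), tokens.index(a) + 1)
        m2 = (tokens.index(b), tokens.index(b) + 1)
        tree = _build_tree(normalized, verb_idx, name_set)
        deps = _chain_deps(normalized)

        text = " ".join(tokens)
        passage_index = len(passages)
        passages.append((text, offset))
        for mention, (lo, hi) in ((a, m1), (b, m2)):
            char_start = len(" ".join(tokens[:lo])) + (1 if lo else 0)
            annotations.append(ProteinAnnotation(
                surface=mention, start=char_start,
                end=char_start + len(mention), passage_index=passage_index))
        offset += len(text) + 1

        instances.append(ExpandedCandidate(
            normalized=normalized, m1=m1, m2=m2, parse=tree, deps=deps,
            label=y, uid=f"s{sent_i}"))
        labels.append(y)
        tree_lines.append(write_bracketed(tree))
        dep_blocks.append(write_dependency_graph(deps))

    doc = AnnotatedDocument(doc_id="synthetic", passages=passages,
                            annotations=annotations)
    return SyntheticCorpus(
        documents=[doc], instances=instances, labels=labels,
        trees_text="\n".join(tree_lines) + "\n",
        deps_text="\n".join(dep_blocks))


# ---------------------------------------------------------------------------
# worked-example fixtures


@dataclass
class WorkedFixture:
    name: str
    text: str
    protein_surfaces: list[str]
    tree: ParseNode
    deps: DependencyGraph
    document: AnnotatedDocument
    mention_spans: dict[str, tuple[int, int]] = field(default_factory=dict)


_CREB_TEXT = ("Active, phosphorylated CREB, which is important to brain "
              "development, effects CRE-dependent genes via interaction with "
              "CBP which tightened the connection between CREB and downstream "
              "components.")

_CREB_TREE = """(S
  (NP
    (NP (JJ Active) (, ,) (VBN phosphorylated) (NN CREB))
    (, ,)
    (SBAR (WHNP (WDT which))
      (S (VP (VBZ is)
        (ADJP (JJ important) (PP (TO to) (NP (NN brain) (NN development)))))))
    (, ,))
  (VP (VBZ effects)
    (NP (JJ CRE-dependent) (NNS genes))
    (PP (IN via)
      (NP (NP (NN interaction))
        (PP (IN with)
          (NP (NP (NN CBP))
            (SBAR (WHNP (WDT which))
              (S (VP (VBD tightened)
                (NP (NP (DT the) (NN connection))
                  (PP (IN between)
                    (NP (NN CREB) (CC and) (JJ downstream) (NNS components))))))))))))
  (. .))"""

# (relation, governor, dependent) over the CREB sentence tokens; the shortest
# undirected CREB..CBP path runs CREB-effects-genes-interaction-CBP
_CREB_DEPS = [
    ("amod", 3, 0), ("punct", 3, 1), ("amod", 3, 2), ("punct", 3, 4),
    ("acl:relcl", 3, 7), ("nsubj", 7, 5), ("cop", 7, 6),
    ("case", 10, 8), ("compound", 10, 9), ("nmod", 7, 10),
    ("punct", 12, 11), ("conj", 12, 3),
    ("amod", 14, 13), ("dobj", 12, 14),
    ("case", 16, 15), ("nmod", 14, 16),
    ("case", 18, 17), ("nmod", 16, 18),
    ("acl:relcl", 18, 20), ("nsubj", 20, 19),
    ("det", 22, 21), ("dobj", 20, 22),
    ("case", 24, 23), ("nmod", 22, 24),
    ("cc", 24, 25), ("amod", 27, 26), ("conj", 24, 27),
    ("punct", 12, 28),
]

_GP130_TEXT = ("Abolition of the gp130 binding site in hLIF created "
               "antagonists of LIF action")

_GP130_TREE = """(S
  (NP
    (NP (NN Abolition))
    (PP (IN of) (NP (DT the) (NN gp130) (NN binding) (NN site)))
    (PP (IN in) (NP (NN hLIF))))
  (VP (VBD created)
    (NP (NP (NNS antagonists)) (PP (IN of) (NP (NN LIF) (NN action))))))"""

_SEC24_TEXT = ("We have identified a third Sec24p family member, which we "
               "call Iss1p, as a protein that binds to Sec16p.")

_SEC24_TREE = """(S
  (NP (PRP We))
  (VP (VBP have)
    (VP (VBN identified)
      (NP
        (NP (DT a) (JJ third) (NN Sec24p) (NN family) (NN member))
        (, ,)
        (SBAR (WHNP (WDT which))
          (S (NP (PRP we)) (VP (VBP call) (NP (NN Iss1p)))))
        (, ,))
      (PP (IN as)
        (NP
          (NP (DT a) (NN protein))
          (SBAR (WHNP (WDT that))
            (S (VP (VBZ binds) (PP (TO to) (NP (NN Sec16p))))))))))
  (. .))"""


def _fixture(name: str, text: str, surfaces: list[str], tree_src: str,
             dep_rows: list[tuple[str, int, int]] | None = None) -> WorkedFixture:
    tree = parse_bracketed(tree_src)
    tokens = tree.tokens()
    deps = DependencyGraph(tokens=tokens, edges=list(dep_rows or
                           [("dep", i, i + 1) for i in range(len(tokens) - 1)]))
    annotations = []
    for s in surfaces:
        # whole-word match so e.g. "LIF" is not located inside "hLIF"
        pos = re.search(rf"(?<!\w){re.escape(s)}(?!\w)", text).start()
        annotations.append(ProteinAnnotation(surface=s, start=pos,
                                             end=pos + len(s), passage_index=0))
    doc = AnnotatedDocument(doc_id=name, passages=[(text, 0)],
                            annotations=annotations)
    spans = {}
    for s in surfaces:
        for i, tok in enumerate(tokens):
            if tok == s:
                spans.setdefault(s, (i, i + 1))
    return WorkedFixture(name=name, text=text, protein_surfaces=surfaces,
                         tree=tree, deps=deps, document=doc,
                         mention_spans=spans)


def worked_example_fixtures() -> dict[str, WorkedFixture]:
    """The three hand-authored sentences used as structural ground truth."""
    return {
        "creb_cbp": _fixture("creb_cbp", _CREB_TEXT, ["CREB", "CBP"],
                             _CREB_TREE, _CREB_DEPS),
        "gp130_hlif": _fixture("gp130_hlif", _GP130_TEXT,
                               ["gp130", "hLIF", "LIF"], _GP130_TREE),
        "sec24p": _fixture("sec24p", _SEC24_TEXT,
                           ["Sec24p", "Iss1p", "Sec16p"], _SEC24_TREE),
    }
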