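"""Candidate sentence generation.

Passages are split into sentences with a rule-based splitter tuned for
biomedical prose (decimal numbers, "et al.", abbreviations), protein mentions
are located from the document's annotation set, every pairwise combination of
distinct protein names in a sentence becomes one candidate, and candidates
are normalized by replacing the target pair with PROTEIN1/PROTEIN2 and every
other recognized protein with PROTEIN.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

from .formats_io import AnnotatedDocument
from .tree import DependencyGraph, ParseNode

__all__ = [
    "Sentence",
    "Mention",
    "CandidateSentence",
    "ExpandedCandidate",
    "split_sentences",
    "tokenize",
    "find_protein_mentions",
    "enumerate_candidates",
    "normalize_candidate",
    "candidates_from_document",
]

PROTEIN1 = "PROTEIN1"
PROTEIN2 = "PROTEIN2"
PROTEIN = "PROTEIN"
PROTEIN_LABELS = (PROTEIN1, PROTEIN2, PROTEIN)

# Tokens after which a period never ends a sentence.
_ABBREVIATIONS = {
    "al", "fig", "figs", "e.g", "i.e", "vs", "sp", "spp", "approx", "ca",
    "cf", "et", "ref", "no", "dr", "prof", "inc", "st",
}

_TOKEN_RE = re.compile(r"\w+(?:[-/.]\w+)*|\S")


@dataclass
class Sentence:
    """A sentence with its offset in the passage and offset-preserving tokens."""

    text: str
    start: int  # 0-based character offset in the passage
    tokens: list[tuple[str, int, int]] = field(default_factory=list)

    def token_surfaces(self) -> list[str]:
        return [t[0] for t in self.tokens]


@dataclass(frozen=True)
class Mention:
    """A protein mention as a token span (0-based half-open) in a sentence."""

    surface: str
    tok_start: int
    tok_end: int


@dataclass
class CandidateSentence:
    """A sentence paired with one ordered target protein pair.

    ``first``/``second`` are the target mentions ordered by text position;
    ``other_proteins`` are the remaining recognized mentions.
    """

    sentence: Sentence
    first: Mention
    second: Mention
    other_proteins: list[Mention] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.first.tok_start >= self.second.tok_start:
            raise ValueError("first mention of a candidate pair must precede the second")


@dataclass
class ExpandedCandidate:
    """A candidate sentence with its normalized form, parse and dependencies.

    ``normalized`` is token-parallel to the sentence; the target pair tokens
    carry PROTEIN1/PROTEIN2, other recognized proteins PROTEIN.  ``m1``/``m2``
    are the token spans of the target pair.  ``parse`` leaves and ``deps``
    tokens align with ``normalized``.
    """

    normalized: list[str]
    m1: tuple[int, int]
    m2: tuple[int, int]
    parse: Optional[ParseNode] = None
    deps: Optional[DependencyGraph] = None
    candidate: Optional[CandidateSentence] = None
    label: Optional[int] = None
    uid: str = ""


def tokenize(text: str, base_offset: int = 0) -> list[tuple[str, int, int]]:
    """Whitespace/punctuation tokenization preserving character offsets.

    Word-internal hyphens, slashes and periods stay attached (CRE-dependent,
    ph 6.5), so tokens tile the text left to right without overlap.
    """
    return [(m.group(0), base_offset + m.start(), base_offset + m.end())
            for m in _TOKEN_RE.finditer(text)]


def _is_boundary(text: str, i: int) -> bool:
    """Decide whether the terminator at position ``i`` ends a sentence."""
    ch = text[i]
    after = text[i + 1:]
    # Must be followed by whitespace then an uppercase letter (or end of text).
    m = re.match(r"\s+(\S)", after)
    if after.strip() == "":
        return True
    if m is None or not m.group(1).isupper():
        return False
    if ch in "!?":
        return True
    # Period inside a decimal number: digit on both sides.
    if i > 0 and text[i - 1].isdigit() and i + 1 < len(text) and text[i + 1].isdigit():
        return False
    # Word immediately before the period.
    wm = re.search(r"(\S+)$", text[:i])
    prev = wm.group(1) if wm else ""
    prev_clean = prev.rstrip(".").lower()
    if prev_clean in _ABBREVIATIONS:
        return False
    # Single capital initial, e.g. "J. Smith".
    if re.fullmatch(r"[A-Z]", prev):
        return False
    return True


def split_sentences(passage_text: str) -> list[Sentence]:
    """Split a passage at '.', '!' or '?' boundaries, ignoring periods in
    decimal numbers, after abbreviations ("et al.", "Fig.", "e.g.", ...) and
    after single capital initials.  Always returns >= 1 sentence for nonempty
    input."""
    if not passage_text.strip():
        return []
    boundaries = [i for i, ch in enumerate(passage_text)
                  if ch in ".!?" and _is_boundary(passage_text, i)]
    sentences: list[Sentence] = []
    start = 0
    for b in boundaries:
        chunk = passage_text[start:b + 1]
        if chunk.strip():
            lead = len(chunk) - len(chunk.lstrip())
            s_start = start + lead
            s_text = chunk.strip()
            sentences.append(Sentence(text=s_text, start=s_start,
                                      tokens=tokenize(s_text)))
        start = b + 1
    tail = passage_text[start:]
    if tail.strip():
        lead = len(tail) - len(tail.lstrip())
        s_text = tail.strip()
        sentences.append(Sentence(text=s_text, start=start + lead,
                                  tokens=tokenize(s_text)))
    return sentences


def find_protein_mentions(sentence: Sentence, names: set[str]) -> list[Mention]:
    """Locate protein names in a sentence.

    Unigram names are matched by exact token equality; names containing
    spaces by substring search over the sentence text (mapped back to token
    spans).  Overlapping matches are resolved longest-first.
    """
    if not names:
        raise ValueError("names must be nonempty")
    raw: list[Mention] = []
    surfaces = sentence.token_surfaces()
    unigram = {n for n in names if " " not in n}
    multi = sorted((n for n in names if " " in n), key=len, reverse=True)

    for i, tok in enumerate(surfaces):
        if tok in unigram:
            raw.append(Mention(surface=tok, tok_start=i, tok_end=i + 1))
    for name in multi:
        for m in re.finditer(re.escape(name), sentence.text):
            toks = [i for i, (_, s, e) in enumerate(sentence.tokens)
                    if s >= m.start() and e <= m.end()]
            if toks:
                raw.append(Mention(surface=name, tok_start=toks[0],
                                   tok_end=toks[-1] + 1))
    # longest-first overlap resolution
    raw.sort(key=lambda mn: (-(mn.tok_end - mn.tok_start), mn.tok_start))
    chosen: list[Mention] = []
    taken: set[int] = set()
    for mn in raw:
        span = set(range(mn.tok_start, mn.tok_end))
        if span & taken:
            continue
        taken |= span
        chosen.append(mn)
    chosen.sort(key=lambda mn: mn.tok_start)
    return chosen


def enumerate_candidates(sentence: Sentence, mentions: list[Mention]) -> list[CandidateSentence]:
    """All pairwise combinations of distinct protein names in the sentence.

    A sentence with fewer than two distinct names yields no candidates
    (first-level filter).  For k distinct names exactly C(k, 2) candidates
    are produced, each pair ordered by first occurrence; enumeration order is
    deterministic (by text position of the first occurrences).
    """
    first_occurrence: dict[str, Mention] = {}
    for mn in mentions:
        first_occurrence.setdefault(mn.surface, mn)
    distinct = sorted(first_occurrence.values(), key=lambda mn: mn.tok_start)
    if len(distinct) < 2:
        return []
    out: list[CandidateSentence] = []
    for a, b in combinations(distinct, 2):
        others = [mn for mn in mentions if mn.surface not in (a.surface, b.surface)]
        out.append(CandidateSentence(sentence=sentence, first=a, second=b,
                                     other_proteins=others))
    return out


def normalize_candidate(c: CandidateSentence, all_mentions: Optional[list[Mention]] = None) -> list[str]:
    """Token-parallel normalized form of a candidate sentence.

    Every occurrence of the first target name becomes PROTEIN1, of the second
    PROTEIN2, and of any other recognized protein PROTEIN; all remaining
    tokens are unchanged.  Token count is preserved (each token of a
    multi-token mention receives the label).
    """
    tokens = list(c.sentence.token_surfaces())
    mentions = list(all_mentions) if all_mentions is not None else (
        [c.first, c.second] + list(c.other_proteins))
    found1 = found2 = False
    for mn in mentions:
        if mn.surface == c.first.surface:
            label = PROTEIN1
            found1 = True
        elif mn.surface == c.second.surface:
            label = PROTEIN2
            found2 = True
        else:
            label = PROTEIN
        for i in range(mn.tok_start, mn.tok_end):
            tokens[i] = label
    if not (found1 and found2):
        raise ValueError(
            f"candidate pair ({c.first.surface!r}, {c.second.surface!r}) "
            "not found among sentence mentions")
    return tokens


def candidates_from_document(doc: AnnotatedDocument) -> list[tuple[Sentence, list[Mention], CandidateSentence]]:
    """End-to-end candidate enumeration for one annotated document."""
    names = doc.protein_names()
    out = []
    if not names:
        return out
    for p_index, (text, _offset) in enumerate(doc.passages):
        for sent in split_sentences(text):
            mentions = find_protein_mentions(sent, names)
            for cand in enumerate_candidates(sent, mentions):
                out.append((sent, mentions, cand))
    return out
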