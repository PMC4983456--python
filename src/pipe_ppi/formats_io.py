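"""Readers and writers for every external format the pipeline touches.

Formats: a minimal BioC-style XML dialect (collection/document/passage/
annotation/relation, absolute character offsets, unknown elements ignored),
Penn-bracketed constituency trees (one per line), a CoNLL-like dependency
table, a two-column trigger-word lexicon, and a flat ``key=value`` run
configuration.  All character offsets are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from typing import Optional

from lxml import etree

from .stemming import porter_stem
from .tree import DependencyGraph, ParseNode, parse_bracketed, write_bracketed

__all__ = [
    "ProteinAnnotation",
    "AnnotatedDocument",
    "TriggerLexicon",
    "RunConfig",
    "StageCounters",
    "read_bioc_collection",
    "write_bioc_collection",
    "read_bracketed_tree",
    "write_bracketed_tree",
    "read_dependency_graph",
    "write_dependency_graph",
    "load_trigger_lexicon",
    "default_trigger_lexicon",
    "load_config",
    "dump_config",
    "check_span",
]

logger = logging.getLogger("pipe_ppi")


def check_span(text: str, start: int, end: int, expected: str, what: str = "span") -> None:
    """Assert that ``text[start:end] == expected`` (0-based half-open).

    The single enforcement point for offset/text agreement.
    """
    if not (0 <= start < end <= len(text)):
        raise ValueError(f"{what}: offsets [{start}, {end}) outside text of length {len(text)}")
    got = text[start:end]
    if got != expected:
        raise ValueError(f"{what}: text at [{start}, {end}) is {got!r}, expected {expected!r}")


@dataclass(frozen=True)
class ProteinAnnotation:
    """A protein-name mention: surface form plus its passage-relative span."""

    surface: str
    start: int
    end: int
    passage_index: int = 0

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("annotation surface must be nonempty")
        if self.start >= self.end:
            raise ValueError(f"annotation span [{self.start}, {self.end}) is empty or inverted")


@dataclass
class AnnotatedDocument:
    """A document as a list of passages with protein-name annotations."""

    doc_id: str
    passages: list[tuple[str, int]]  # (text, collection-level character offset)
    annotations: list[ProteinAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for ann in self.annotations:
            if not (0 <= ann.passage_index < len(self.passages)):
                raise ValueError(
                    f"document {self.doc_id}: annotation {ann.surface!r} references "
                    f"passage {ann.passage_index} of {len(self.passages)}"
                )
            text = self.passages[ann.passage_index][0]
            check_span(text, ann.start, ann.end, ann.surface,
                       what=f"document {self.doc_id}, annotation {ann.surface!r}")

    def protein_names(self) -> set[str]:
        """The set PG of distinct protein names in the document."""
        return {a.surface for a in self.annotations}


@dataclass
class TriggerLexicon:
    """Trigger word -> semantic-class map, keyed by Porter stem.

    Lookup is case-insensitive and stems its argument, so any inflectional
    variant of a listed trigger resolves to the same class.
    """

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for stem, label in self.entries.items():
            if not label:
                raise ValueError(f"trigger lexicon: empty class label for stem {stem!r}")

    def lookup(self, token: str) -> Optional[str]:
        return self.entries.get(porter_stem(token))

    def classes(self) -> set[str]:
        return set(self.entries.values())


@dataclass
class RunConfig:
    """Pipeline-wide tunables.

    support_min / confidence_min are the association-rule thresholds of the
    semantic graph; sc_cumfreq and stopword_cumfreq are the Zipf cumulative-
    frequency cutoffs for frequent semantic classes and stop words;
    top_k_patterns caps the LLR-ranked pattern list; lambda_decay is the
    convolution-tree-kernel decay factor.
    """

    support_min: int = 20
    confidence_min: float = 0.5
    sc_cumfreq: float = 0.70
    stopword_cumfreq: float = 0.80
    top_k_patterns: int = 20
    lambda_decay: float = 0.4
    normalize_kernel: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.lambda_decay < 1.0):
            raise ValueError(f"lambda_decay must lie in (0, 1), got {self.lambda_decay}")
        for name in ("confidence_min", "sc_cumfreq", "stopword_cumfreq"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        for name in ("support_min", "top_k_patterns"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


class StageCounters(dict):
    """Structured per-stage counters (sentences, candidates, patterns, ...)."""

    def bump(self, key: str, by: int = 1) -> None:
        self[key] = self.get(key, 0) + by
        logger.debug("counter %s = %d", key, self[key])


# ---------------------------------------------------------------------------
# BioC-style XML


def read_bioc_collection(xml_text: str | bytes) -> list[AnnotatedDocument]:
    """Parse a minimal BioC-style collection into annotated documents.

    Annotation offsets in the XML are absolute character positions; they are
    validated against the passage text and stored passage-relative.  Unknown
    elements are ignored.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed BioC XML: {exc}") from exc

    docs: list[AnnotatedDocument] = []
    for doc_el in root.iter("document"):
        doc_id = (doc_el.findtext("id") or "").strip()
        passages: list[tuple[str, int]] = []
        annotations: list[ProteinAnnotation] = []
        for p_index, p_el in enumerate(doc_el.iter("passage")):
            offset = int((p_el.findtext("offset") or "0").strip())
            text = p_el.findtext("text") or ""
            passages.append((text, offset))
            for a_el in p_el.iter("annotation"):
                loc = a_el.find("location")
                if loc is None:
                    raise ValueError(
                        f"document {doc_id}: annotation without a location element")
                abs_start = int(loc.get("offset"))
                length = int(loc.get("length"))
                surface = a_el.findtext("text") or ""
                start = abs_start - offset
                annotations.append(
                    ProteinAnnotation(surface=surface, start=start,
                                      end=start + length, passage_index=p_index))
        docs.append(AnnotatedDocument(doc_id=doc_id, passages=passages,
                                      annotations=annotations))
    return docs


def write_bioc_collection(
    docs: list[AnnotatedDocument],
    predictions: Optional[list[tuple[str, str, str, str]]] = None,
) -> str:
    """Serialize documents back to the BioC-style dialect.

    ``predictions`` is an optional list of (doc_id, protein_1, protein_2,
    label) tuples; each is emitted as a ``relation`` element with a ``label``
    attribute on the matching document.
    """
    root = etree.Element("collection")
    etree.SubElement(root, "source").text = "pipe_ppi"
    by_doc: dict[str, list[tuple[str, str, str]]] = {}
    for doc_id, p1, p2, label in predictions or []:
        by_doc.setdefault(doc_id, []).append((p1, p2, label))

    for doc in docs:
        doc_el = etree.SubElement(root, "document")
        etree.SubElement(doc_el, "id").text = doc.doc_id
        ann_counter = 0
        for p_index, (text, offset) in enumerate(doc.passages):
            p_el = etree.SubElement(doc_el, "passage")
            etree.SubElement(p_el, "offset").text = str(offset)
            etree.SubElement(p_el, "text").text = text
            for ann in doc.annotations:
                if ann.passage_index != p_index:
                    continue
                a_el = etree.SubElement(p_el, "annotation", id=f"T{ann_counter}")
                ann_counter += 1
                infon = etree.SubElement(a_el, "infon", key="type")
                infon.text = "protein"
                etree.SubElement(a_el, "location",
                                 offset=str(offset + ann.start),
                                 length=str(ann.end - ann.start))
                etree.SubElement(a_el, "text").text = ann.surface
        for i, (p1, p2, label) in enumerate(by_doc.get(doc.doc_id, [])):
            r_el = etree.SubElement(doc_el, "relation", id=f"R{i}", label=label)
            etree.SubElement(r_el, "node", refid=p1, role="protein1")
            etree.SubElement(r_el, "node", refid=p2, role="protein2")
    return etree.tostring(root, pretty_print=True, encoding="unicode")


# ---------------------------------------------------------------------------
# Trees and dependencies


def read_bracketed_tree(text: str) -> ParseNode:
    """Read a single Penn-bracketed tree (see :func:`tree.parse_bracketed`)."""
    return parse_bracketed(text)


def write_bracketed_tree(node: ParseNode) -> str:
    return write_bracketed(node)


def read_dependency_graph(table: str) -> DependencyGraph:
    """Read a dependency block: a tab-separated token header line followed by
    one ``relation<TAB>governor<TAB>dependent`` row per dependency."""
    lines = [ln for ln in table.strip().splitlines()]
    if not lines:
        raise ValueError("empty dependency table")
    tokens = lines[0].rstrip("\n").split("\t")
    edges: list[tuple[str, int, int]] = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != 3:
            raise ValueError(f"dependency row must have 3 fields: {ln!r}")
        rel, gov, dep = parts[0], int(parts[1]), int(parts[2])
        edges.append((rel, gov, dep))
    return DependencyGraph(tokens=tokens, edges=edges)


def write_dependency_graph(graph: DependencyGraph) -> str:
    lines = ["\t".join(graph.tokens)]
    for rel, gov, dep in graph.edges:
        lines.append(f"{rel}\t{gov}\t{dep}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Trigger lexicon

#: Small default trigger lexicon. The semantic classes follow event-annotation
#: practice in biomedical corpora (Binding, Regulation, ... , Localization)
#: plus an Antagonist class; it is illustrative and user-replaceable.
_DEFAULT_TRIGGERS = """\
bind\tBinding
binding\tBinding
bound\tBinding
interact\tBinding
interaction\tBinding
associate\tBinding
association\tBinding
complex\tBinding
regulate\tRegulation
regulation\tRegulation
modulate\tRegulation
modulation\tRegulation
control\tRegulation
activate\tPositive_regulation
activation\tPositive_regulation
induce\tPositive_regulation
induction\tPositive_regulation
stimulate\tPositive_regulation
stimulation\tPositive_regulation
enhance\tPositive_regulation
promote\tPositive_regulation
inhibit\tNegative_regulation
inhibition\tNegative_regulation
suppress\tNegative_regulation
suppression\tNegative_regulation
repress\tNegative_regulation
reduce\tNegative_regulation
reduction\tNegative_regulation
block\tNegative_regulation
express\tGene_expression
expression\tGene_expression
transcribe\tTranscription
transcription\tTranscription
secrete\tLocalization
secretion\tLocalization
localize\tLocalization
localization\tLocalization
translocation\tLocalization
transport\tLocalization
phosphorylate\tPhosphorylation
phosphorylation\tPhosphorylation
antagonist\tAntagonist
antagonize\tAntagonist
antagonism\tAntagonist
"""


def load_trigger_lexicon(tsv: str) -> TriggerLexicon:
    """Load a two-column ``term<TAB>class`` lexicon, keying terms by Porter stem.

    Terms whose stems collide must agree on the class; a conflicting duplicate
    raises an error naming the stem.
    """
    entries: dict[str, str] = {}
    for lineno, ln in enumerate(tsv.splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ValueError(f"trigger lexicon line {lineno}: expected 2 columns, got {ln!r}")
        term, label = parts[0].strip(), parts[1].strip()
        stem = porter_stem(term)
        if stem in entries and entries[stem] != label:
            raise ValueError(
                f"trigger lexicon: conflicting classes for stem {stem!r} "
                f"({entries[stem]!r} vs {label!r})")
        entries[stem] = label
    return TriggerLexicon(entries=entries)


def default_trigger_lexicon() -> TriggerLexicon:
    return load_trigger_lexicon(_DEFAULT_TRIGGERS)


# ---------------------------------------------------------------------------
# Run configuration as flat key=value text

_BOOL_FIELDS = {"normalize_kernel"}
_INT_FIELDS = {"support_min", "top_k_patterns", "seed"}


def load_config(text: str) -> RunConfig:
    kwargs = {}
    valid = {f.name for f in fields(RunConfig)}
    for lineno, ln in enumerate(text.splitlines(), start=1):
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        if "=" not in ln:
            raise ValueError(f"config line {lineno}: expected key=value, got {ln!r}")
        key, _, value = ln.partition("=")
        key, value = key.strip(), value.strip()
        if key not in valid:
            raise ValueError(f"config line {lineno}: unknown key {key!r}")
        if key in _BOOL_FIELDS:
            kwargs[key] = value.lower() in ("1", "true", "yes", "on")
        elif key in _INT_FIELDS:
            kwargs[key] = int(value)
        else:
            kwargs[key] = float(value)
    return RunConfig(**kwargs)


def dump_config(config: RunConfig) -> str:
    return "".join(f"{f.name}={getattr(config, f.name)}\n" for f in fields(RunConfig))
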