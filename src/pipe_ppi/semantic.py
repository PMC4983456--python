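"""Semantic class labeling (SCL).

A normalized candidate sentence is reduced to an ordered sequence of semantic
classes: the protein placeholders pass through as labels, every other token
is Porter-stemmed and looked up in the trigger lexicon, and tokens matching
no trigger are dropped.  Stemming makes inflectional variants of a trigger
("binds", "binding") emit the same class, which is what lets the pattern
miner group synonyms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .candidates import PROTEIN_LABELS
from .formats_io import TriggerLexicon
from .stemming import porter_stem

__all__ = ["SCSequence", "label_semantic_classes", "porter_stem"]


@dataclass
class SCSequence:
    """Ordered semantic-class labels with their source token indices."""

    labels: list[str]
    token_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.token_indices and len(self.token_indices) != len(self.labels):
            raise ValueError("labels and token_indices must be parallel")

    def __iter__(self):
        return iter(self.labels)

    def __len__(self) -> int:
        return len(self.labels)


def label_semantic_classes(
    normalized_tokens: list[str],
    lexicon: TriggerLexicon,
    require_pair: bool = True,
) -> SCSequence:
    """Map a normalized token list to its semantic-class sequence.

    The target-pair tokens PROTEIN1/PROTEIN2 pass through (a multi-token
    mention, i.e. a run of consecutive identical protein labels, emits one
    label); non-target PROTEIN placeholders stay in the token string but
    emit no class — the sequence describes the interaction semantics of the
    target pair only.  Other tokens emit their trigger class when the stem
    is in the lexicon and nothing otherwise.
    """
    labels: list[str] = []
    indices: list[int] = []
    prev_protein = None
    for i, tok in enumerate(normalized_tokens):
        if tok in PROTEIN_LABELS:
            if tok == prev_protein:
                continue  # continuation of a multi-token mention
            prev_protein = tok
            if tok != "PROTEIN":
                labels.append(tok)
                indices.append(i)
            continue
        prev_protein = None
        if not any(ch.isalpha() for ch in tok):
            continue
        cls = lexicon.lookup(tok)
        if cls is not None:
            labels.append(cls)
            indices.append(i)
    if require_pair and not ({"PROTEIN1", "PROTEIN2"} <= set(labels)):
        raise ValueError("normalized sentence lacks PROTEIN1/PROTEIN2 target pair")
    return SCSequence(labels=labels, token_indices=indices)
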