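"""Top-level modelling API: fit the full pattern-mining + IPT + tree-kernel
+ SVM pipeline on a labeled candidate corpus and predict on new candidates.

``PipeModel`` plays the role of a model class built from data; ``fit()``
returns a ``PipeResults`` carrying the mined patterns, the stop-word list,
the trained kernel machine, training diagnostics and a ``summary()`` table.
Every data-derived artifact (frequent classes, patterns, stop words, the
penalty C) is computed from the training instances only, so the same object
drives the leak-free cross-validation / cross-learning / cross-corpus
protocols.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .candidates import ExpandedCandidate
from .classify import KernelSVM, TrainConfig, compute_metrics, predict, train
from .formats_io import RunConfig, StageCounters, TriggerLexicon, default_trigger_lexicon
from .ipt import IPT, StopwordList, build_stopword_list, construct_ipt
from .kernel import KernelConfig, gram_matrix, kernel_rows
from .mining import InteractionPattern, mine_patterns
from .semantic import label_semantic_classes

__all__ = ["PipeModel", "PipeResults", "make_fit_predict"]


class PipeModel:
    """PPI passage-extraction pipeline as a fittable model.

    Parameters
    ----------
    instances : list of ExpandedCandidate
        Labeled training candidates (normalized tokens, parse, dependencies).
    labels : sequence of {+1, -1}, optional
        Taken from the instances when omitted.
    lexicon : TriggerLexicon, optional
        Trigger-word lexicon; the packaged default when omitted.
    config : RunConfig, optional
        Mining/kernel thresholds; spec defaults when omitted.
    """

    def __init__(
        self,
        instances: list[ExpandedCandidate],
        labels: Optional[Sequence[int]] = None,
        lexicon: Optional[TriggerLexicon] = None,
        config: Optional[RunConfig] = None,
    ):
        self.instances = list(instances)
        if labels is None:
            labels = [i.label for i in self.instances]
            if any(l is None for l in labels):
                raise ValueError("instances lack labels; pass labels explicitly")
        self.labels = np.asarray(list(labels))
        if len(self.labels) != len(self.instances):
            raise ValueError("labels and instances must be parallel")
        self.lexicon = lexicon or default_trigger_lexicon()
        self.config = config or RunConfig()
        self.counters = StageCounters()

    # -- helpers ------------------------------------------------------------

    def _sequences(self, instances: list[ExpandedCandidate]):
        return [label_semantic_classes(i.normalized, self.lexicon,
                                       require_pair=False)
                for i in instances]

    def _token_pos_pairs(self, instances: list[ExpandedCandidate]):
        pairs = []
        for inst in instances:
            for node in inst.parse.internal_nodes():
                if node.is_preterminal:
                    pairs.append((node.children[0].word, node.label))
        return pairs

    def _build_ipts(self, instances, patterns, stopwords) -> list[IPT]:
        return [construct_ipt(i, patterns, stopwords, self.lexicon, self.config)
                for i in instances]

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "PipeResults":
        cfg = self.config
        self.counters.bump("candidates", len(self.instances))
        sequences = self._sequences(self.instances)
        patterns = mine_patterns(sequences, list(self.labels), cfg)
        self.counters.bump("patterns", len(patterns))
        stopwords = build_stopword_list(self._token_pos_pairs(self.instances), cfg)
        ipts = self._build_ipts(self.instances, patterns, stopwords)
        kcfg = KernelConfig.from_run_config(cfg)
        gram = gram_matrix([t.root for t in ipts], kcfg,
                           index=[i.uid or str(k) for k, i in enumerate(self.instances)])
        self.counters.bump("kernel_evaluations", len(ipts) * (len(ipts) + 1) // 2)
        svm = train(gram.values, self.labels, TrainConfig(derived_C=True))
        fitted = predict(svm, gram.values)
        return PipeResults(model=self, patterns=patterns, stopwords=stopwords,
                           train_ipts=ipts, gram=gram.values, svm=svm,
                           fitted_labels=fitted)


@dataclass
class PipeResults:
    """Fit artifacts: mined patterns, stop words, kernel machine, diagnostics."""

    model: PipeModel
    patterns: list[InteractionPattern]
    stopwords: StopwordList
    train_ipts: list[IPT]
    gram: np.ndarray
    svm: KernelSVM
    fitted_labels: np.ndarray = field(repr=False, default=None)

    @property
    def C(self) -> float:
        return self.svm.C

    def predict(self, instances: list[ExpandedCandidate]) -> np.ndarray:
        """Predict +1/-1 for new candidates using the fitted artifacts."""
        ipts = self.model._build_ipts(instances, self.patterns, self.stopwords)
        kcfg = KernelConfig.from_run_config(self.model.config)
        rows = kernel_rows([t.root for t in ipts],
                           [t.root for t in self.train_ipts], kcfg)
        return predict(self.svm, rows)

    def training_metrics(self):
        return compute_metrics(self.fitted_labels, self.model.labels)

    def summary(self) -> str:
        m = self.training_metrics()
        y = self.model.labels
        lines = [
            "PPI passage extraction pipeline",
            "=" * 47,
            f"candidates:        {len(y)} ({int((y > 0).sum())} pos / {int((y <= 0).sum())} neg)",
            f"SVM penalty C:     {self.C:.4f} (neg/pos ratio)",
            f"kernel:            convolution tree kernel, lambda="
            f"{self.model.config.lambda_decay}, "
            f"{'normalized' if self.model.config.normalize_kernel else 'raw'}",
            f"mined patterns:    {len(self.patterns)} (top "
            f"{self.model.config.top_k_patterns} by summed LLR)",
            f"stop-word stems:   {len(self.stopwords.stems)}",
            f"training P/R/F1:   {m.precision:.3f}/{m.recall:.3f}/{m.f1:.3f}",
            "-" * 47,
            "patterns (rank, score, labels):",
        ]
        for r, p in enumerate(self.patterns, start=1):
            lines.append(f"  {r:>2}  {p.score:8.2f}  {p.render()}")
        return "\n".join(lines)


def make_fit_predict(lexicon: Optional[TriggerLexicon] = None,
                     config: Optional[RunConfig] = None):
    """A ``fit_predict(train_instances, train_labels, test_instances)``
    closure for the evaluation protocols, re-fitting the whole pipeline on
    each training split."""

    def fit_predict(train_instances, train_labels, test_instances):
        model = PipeModel(train_instances, labels=train_labels,
                          lexicon=lexicon, config=config)
        return model.fit().predict(test_instances)

    return fit_predict
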