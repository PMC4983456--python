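# pipe-ppi

Protein–protein interaction (PPI) passage extraction from biomedical text.

Given sentences with annotated protein names, the package decides for every
pair of co-occurring proteins whether the sentence asserts an interaction
between them.  It is written for text-mining and biocuration pipelines
(e.g. BioC-style collections feeding interaction databases) whose output
populates PPI networks.

## Method

Every candidate — a sentence plus one ordered protein pair — flows through
four stages:

1. **Candidate generation**: rule-based sentence splitting, mention lookup,
   enumeration of all C(k, 2) pairs of the k distinct protein names, and
   normalization of the pair to `PROTEIN1`/`PROTEIN2` (other proteins to
   `PROTEIN`).
2. **Interaction pattern mining**: tokens are Porter-stemmed and mapped to
   semantic classes via a trigger lexicon (Binding, Regulation,
   Negative_regulation, ...).  Over positive training sentences a directed
   class co-occurrence graph is built with association-rule thresholds
   (support ≥ 20, confidence(SC_i ⇒ SC_j) = support(SC_i ∪ SC_j)/support(SC_i)
   ≥ 0.5), its confidences renormalized into a row-stochastic transition
   matrix M.  Seeded random walks on M (step budget 4|E|²) harvest candidate
   patterns, which are merged (coverage removal, pivot concatenation),
   ranked by summed per-class log-likelihood-ratio scores, and the top 20
   kept — e.g. `[PROTEIN1]->[Binding]->[Regulation]->[PROTEIN2]`.
3. **Interaction pattern tree (IPT)**: the shortest-path-enclosed parse
   subtree linking the pair, refined by *branching* (re-attach a trailing
   verb forming a verb phrase with the second protein), *pruning* (middle
   clauses off the protein dependency path, stop-word leaves, duplicate
   unary nodes) and *ornamenting* (an `(IP id)` child per matched pattern).
4. **Classification**: the convolution (subset-tree) kernel

       Δ(n1,n2) = 0                      if productions differ
       Δ(n1,n2) = λ                      if both are pre-terminals
       Δ(n1,n2) = λ ∏_k (1 + Δ(ch_k, ch'_k))   otherwise
       K(T1,T2) = Σ_{n1∈N1, n2∈N2} Δ(n1,n2)

   with λ = 0.4, normalized, feeds an SVM in precomputed-kernel mode with
   penalty C = #neg/#pos.  Evaluation protocols: 10-fold cross-validation,
   cross-learning (train on the union of the other corpora) and
   cross-corpus, with P/R/F1 and pooled or printed-formula micro-averages.

See `docs/methods.md` for assumptions, parameter semantics and limitations.

## Worked example

A seeded synthetic corpus plants interaction patterns in its positive
sentences; fitting the full pipeline recovers them and separates the
classes:

```python
from pipe_ppi import FixtureSpec, PipeModel, RunConfig, generate_corpus

corpus = generate_corpus(FixtureSpec(n_sentences=120, seed=3))
res = PipeModel(corpus.instances, labels=corpus.labels,
                config=RunConfig(support_min=5)).fit()
print(res.summary())
```

prints

```
PPI passage extraction pipeline
===============================================
candidates:        120 (60 pos / 60 neg)
SVM penalty C:     1.0000 (neg/pos ratio)
kernel:            convolution tree kernel, lambda=0.4, normalized
mined patterns:    2 (top 20 by summed LLR)
stop-word stems:   7
training P/R/F1:   1.000/1.000/1.000
-----------------------------------------------
patterns (rank, score, labels):
   1    218.14  [PROTEIN1]->[Binding]->[Regulation]->[PROTEIN2]
   2    166.36  [PROTEIN1]->[Binding]->[PROTEIN2]
```

Both planted patterns were mined from the data (their scores are the summed
LLR values of their member classes), the SVM penalty equals the
negative/positive ratio of the corpus, and the separable-by-construction
corpus is fit perfectly.  `res.predict(new_instances)` classifies further
candidates with the fitted patterns, stop words and kernel machine.

The `pipe-ppi` command line drives the same stages file by file
(`make-fixtures`, `candidates`, `label`, `mine-patterns`, `gram`,
`evaluate`); see `pipe-ppi --help`.

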