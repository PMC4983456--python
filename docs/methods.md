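# Methods

## Problem and model

`pipe_ppi` decides, for every ordered pair of distinct protein names
co-occurring in a sentence of biomedical text, whether the sentence asserts
an interaction between them.  The decision is a binary classification of
*candidate sentences* — a sentence plus one target pair — with four stages:

1. **Candidate generation.**  Passages are split into sentences with a
   rule-based splitter (periods inside decimal numbers, after abbreviations
   such as "et al." / "Fig." / "e.g.", and after single capital initials are
   not boundaries).  Protein mentions come from the document's annotations:
   unigram names match by exact token equality, multi-word names by
   substring search, overlaps resolved longest-first.  A sentence with k ≥ 2
   distinct names yields C(k, 2) candidates; the pair is ordered by first
   occurrence.  Normalization maps the target pair to PROTEIN1/PROTEIN2 and
   every other recognized protein to PROTEIN, token-parallel to the
   sentence.

2. **Semantic class labeling and pattern mining.**  Tokens are Porter-stemmed
   and looked up in a trigger lexicon (stem → event class such as Binding,
   Regulation, Negative_regulation, Localization, Antagonist); the sequence
   of classes, anchored by PROTEIN1/PROTEIN2, describes the interaction
   semantics of the candidate.  Over the positive training sequences a
   directed class-co-occurrence graph is built with association-rule
   statistics: an edge SC_i → SC_j is the adjacency "SC_i immediately
   precedes SC_j", support counts sequences containing it,
   confidence(SC_i ⇒ SC_j) = support(SC_i ∪ SC_j)/support(SC_i).  Edges with
   support < 20 or confidence < 0.5 are dropped, surviving confidences are
   renormalized per row, so the edge weights form a row-stochastic Markov
   transition matrix.  Candidate patterns are harvested by seeded random
   walks started at every frequent class and its out-neighbors, with a
   global step budget of 4|E|² (a cover-time bound) and per-walk length cap
   |V|; every visited prefix of length ≥ 2 is a candidate.  Merging removes
   patterns that are contiguous subsequences of others and concatenates a
   bigram onto a pattern whose head equals the bigram's tail, to a fixed
   point.  Patterns are ranked by the sum of their member classes'
   log-likelihood-ratio (LLR) scores — the −2 log ratio of a pooled-rate
   binomial likelihood to class-conditional-rate likelihoods over sentence
   presence counts — and the top 20 retained.

3. **Interaction pattern tree (IPT).**  The candidate's constituency parse
   is reduced to the shortest-path-enclosed tree (SPET): the lowest common
   ancestor of the two mentions restricted to the token interval between
   them.  Three operators then refine it, in this fixed order: *branching*
   re-attaches a verb that follows the second protein when both sit under a
   common VP (the verb's pre-terminal wrapped in its VP spine is appended to
   the root); *pruning* removes (a) middle clauses — SBAR nodes strictly
   between the mentions whose span contains no token of the protein
   dependency path, the shortest undirected path between the mention heads
   in the typed-dependency graph — (b) stop-word leaves (corpus-frequent
   words minus verbs and protein names, matched by stem, with childless
   ancestors cascaded away; the protein leaves are always protected) and
   (c) duplicate nodes — unary same-label chains collapsed to a fixed
   point; *ornamenting* appends one (IP patternId) child under the root per
   matched pattern (ordered-subsequence match against the candidate's class
   sequence), in rank order.

4. **Classification.**  Similarity between IPTs is the convolution
   (subset-tree) kernel: Δ(n1, n2) = 0 when productions differ, λ when both
   nodes are pre-terminals, λ·∏_k (1 + Δ(ch_k, ch'_k)) otherwise, and
   K(T1, T2) = Σ_{n1, n2} Δ.  IP ornament nodes participate as ordinary
   nodes, which is how matched patterns influence similarity.  Kernel values
   are normalized to K/√(K11·K22) by default.  The Gram matrix feeds an SVM
   in precomputed-kernel mode with penalty C = #neg/#pos derived from the
   training labels; a decision value of exactly 0 is called positive.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `support_min` | 20 | minimum class frequency and minimum edge support (counts) |
| `confidence_min` | 0.5 | minimum association-rule confidence (probability) |
| `sc_cumfreq` | 0.70 | cumulative-frequency cutoff selecting frequent trigger classes |
| `stopword_cumfreq` | 0.80 | cumulative-frequency cutoff compiling the stop-word list |
| `top_k_patterns` | 20 | patterns retained after LLR ranking |
| `lambda_decay` | 0.4 | CTK decay λ ∈ (0, 1); larger values weight deep fragments more |
| `normalize_kernel` | true | divide kernel values by the geometric mean of self-similarities |
| `seed` | 0 | seeds the random walks and fold assignment |

The cumulative cutoffs implement a Zipf argument: rare classes/words carry
little signal, so the frequency-sorted prefix reaching the cutoff fraction
of total count is kept.  Two boundary conventions matter and are fixed here:
class frequency must be strictly greater than `support_min`, while edge
support and confidence thresholds are inclusive.

## Design choices where the design was open

- **Frequent-class cutoff and protein placeholders.**  PROTEIN1/PROTEIN2
  occur in every positive sequence, so including them in the 70% cumulative
  count would saturate the prefix before any trigger class enters.  The
  cutoff is therefore computed over trigger-class occurrences only, and the
  placeholders are always retained as graph vertices.
- **Non-target proteins in the class sequence.**  Normalization replaces
  every recognized protein in the token string (PROTEIN), but only the
  target pair emits sequence labels: the sequence describes the semantics of
  the pair under classification, and patterns anchor on PROTEIN1/PROTEIN2.
- **Graph edges from positives only**, matching the frequent-class
  selection; configurable via the `labels` argument of
  `build_semantic_graph`.
- **Edge definition** is adjacent precedence (bigram co-occurrence), which
  is what makes the bigram-oriented merging rules well-posed.
- **Walk mechanics** (restart cycling over start vertices, per-walk cap |V|,
  budget 4|E|², emission of every prefix ≥ 2) guarantee termination and
  make short frequent motifs available to the merger even when a long walk
  is never sampled; pivot concatenation then reassembles full paths.
- **Branching condition**: a shared VP whose span covers the second mention
  and dominates a later verb.  The appended spine keeps every VP on the
  path, deliberately producing unary VP chains that the duplicate-collapse
  step removes.
- **Dependency path** is undirected breadth-first shortest path (mention
  head = last token of the mention), ties broken by lexicographically
  smallest index sequence; an empty path skips clause pruning rather than
  failing.
- **Tie-breaks** everywhere are deterministic: frequency sorts break ties
  alphabetically, pattern ranking prefers longer patterns then
  lexicographic order, and all stochastic steps consume a single seeded
  generator.
- **LLR smoothing**: maximum-likelihood probabilities are clamped to
  [1e−9, 1−1e−9] so degenerate tables stay finite; the statistic is 0 iff
  the class-conditional rates coincide and grows strictly with their
  separation.
- **Kernel normalization** defaults to on (self-similarity 1) to control
  magnitude across sentence lengths; the raw mode is available because the
  printed recursion itself is unnormalized.

## Synthetic data: what it emulates and what it does not

`synthetic.generate_corpus` emulates the *shape* of PPI benchmark corpora:
sentences with ≥ 2 distinct protein names, exact class balance
(n_pos = round(n·p_positive), or explicit counts for corpus-shaped
fixtures), trigger words realizing planted class patterns in order for
positives, trigger-free co-occurrence for negatives, and filler-word noise.
Trees and dependencies are derived from a small set of deterministic
templates (subject NP, verb, object NP; chain dependencies), so the same
seed reproduces the corpus byte for byte and no parser is needed.

The default planted patterns are
`[PROTEIN1, Binding, PROTEIN2]` and
`[PROTEIN1, Binding, Regulation, PROTEIN2]`, assigned round-robin to
positives.  They were chosen so that, at the default thresholds and a
400-sentence corpus, every transition clears the support and confidence
floors (the shared first transition has confidence 1.0, the branch after
Binding splits 0.5/0.5 — exactly at the inclusive threshold) and both
trigger classes survive the 70% cutoff.  This makes the mining problem
solvable but not trivial: recovery of the longer pattern exercises either a
full walk or bigram pivot concatenation.

What the generator does **not** emulate: lexical and syntactic diversity of
real abstracts, parser errors, annotation noise, coreference, overlapping or
nested mentions, and negative sentences that contain trigger words in
non-interactive contexts.  Passing tests therefore demonstrate correctness
of the machinery (mining recovers what was planted; the classifier separates
what is separable by construction), not benchmark-level extraction quality
on LLL/IEPA/HPRD50/AIMed/BioInfer-class corpora, which would require the
original corpora, parser and a curated trigger lexicon.

## Numerical and degenerate-input conventions

- Character offsets are 0-based half-open everywhere; a single helper
  (`formats_io.check_span`) enforces span/text agreement.
- The kernel is evaluated over a compiled post-order form that only visits
  node pairs with equal productions (O(|N1|·|N2|) worst case); it agrees
  exactly with the naive memoized recursion, and with the brute-force
  fragment enumeration weighted by λ^(#productions) to 1e−9 on small trees.
  The enumeration oracle is guarded to ≤ 12 internal nodes.
- Gram matrices are symmetric positive semidefinite up to −1e−8 eigenvalue
  tolerance; normalized diagonals are exactly 1.
- Undefined precision or recall (0/0) is reported as 0 and flagged.
- Stratified cross-validation degrades to unstratified folds with a warning
  when a class has fewer members than folds.
- Problem sizes used by the shipped checks: the synthetic corpus is 400
  sentences (10-fold cross-validation refits the full pipeline per fold),
  kernel oracle equivalence uses 50 random tree pairs of ≤ 8 internal
  nodes, and spectral checks use 60-tree Gram matrices.

## Known limitations

- The trigger lexicon is a small illustrative default; real deployments
  should supply a curated list (`load_trigger_lexicon`).
- Multi-word triggers are unsupported (unigram stems only).
- Clause detection is SBAR-based; reduced relatives without an SBAR node
  are not treated as clauses.
- Coreferent mentions (pronouns) are not linked to protein names, so
  candidate enumeration misses pairs expressed through anaphora.
- The BioC-style reader/writer covers the minimal element set
  (collection/document/passage/annotation/relation) and ignores everything
  else.
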