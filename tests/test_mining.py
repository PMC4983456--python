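"""Pattern mining: frequent classes, semantic graph, walks, merging, LLR."""

import math

import numpy as np
import pytest

from pipe_ppi.formats_io import RunConfig
from pipe_ppi.mining import (
    ContingencyCounts,
    InteractionPattern,
    build_semantic_graph,
    llr_score,
    match_pattern,
    merge_patterns,
    mine_patterns,
    random_walk_patterns,
    rank_and_select_patterns,
    select_frequent_scs,
)
from pipe_ppi.semantic import SCSequence


def _seqs(label_lists):
    return [SCSequence(labels=list(ls)) for ls in label_lists]


def _pat(*labels, score=0.0):
    return InteractionPattern(labels=tuple(labels), score=score)


class TestSelectFrequentSCs:
    def test_cumulative_cutoff_and_support_boundary(self):
        # A:50 B:30 C:20 -> prefix {A,B} exceeds 70%; C also fails
        # the strict support filter (20 is not more than 20)
        seqs = _seqs([["PROTEIN1", "A", "PROTEIN2"]] * 50
                     + [["PROTEIN1", "B", "PROTEIN2"]] * 30
                     + [["PROTEIN1", "C", "PROTEIN2"]] * 20)
        labels = [1] * 100
        out = select_frequent_scs(seqs, labels)
        assert out == {"A", "B", "PROTEIN1", "PROTEIN2"}

    def test_single_class(self):
        seqs = _seqs([["PROTEIN1", "A", "PROTEIN2"]] * 100)
        out = select_frequent_scs(seqs, [1] * 100)
        assert "A" in out

    def test_all_below_support_min(self):
        seqs = _seqs([["PROTEIN1", "A", "PROTEIN2"]] * 10)
        out = select_frequent_scs(seqs, [1] * 10)
        assert out == {"PROTEIN1", "PROTEIN2"}  # A dropped, placeholders exempt

    def test_no_positives_is_error(self):
        with pytest.raises(ValueError, match="positive"):
            select_frequent_scs(_seqs([["PROTEIN1", "A", "PROTEIN2"]]), [-1])


class TestSemanticGraph:
    def test_full_confidence_edge(self):
        seqs = _seqs([["A", "B"]] * 30)
        g = build_semantic_graph(seqs, {"A", "B"})
        sup, conf, w = g.edges[("A", "B")]
        assert (sup, conf, w) == (30, 1.0, 1.0)

    def test_confidence_at_threshold_retained(self):
        seqs = _seqs([["A", "B"]] * 10 + [["A", "C"]] * 10 + [["A"]] * 0)
        cfg = RunConfig(support_min=10)
        g = build_semantic_graph(seqs, {"A", "B", "C"}, cfg)
        assert g.edges[("A", "B")][1] == 0.5  # exactly at confidence_min, kept
        assert g.edges[("A", "C")][1] == 0.5

    def test_edge_below_support_dropped(self):
        seqs = _seqs([["A", "B"]] * 19)
        g = build_semantic_graph(seqs, {"A", "B"})
        assert ("A", "B") not in g.edges

    def test_rows_stochastic(self, rng):
        # property: any constructed graph has out-weight rows summing to 1
        classes = ["A", "B", "C", "D"]
        for _ in range(10):
            seq_list = [
                list(rng.choice(classes, size=rng.integers(2, 5), replace=False))
                for _ in range(60)]
            g = build_semantic_graph(_seqs(seq_list), set(classes),
                                     RunConfig(support_min=1, confidence_min=0.05))
            rows = {}
            for (a, _), (_, _, w) in g.edges.items():
                rows[a] = rows.get(a, 0.0) + w
            for total in rows.values():
                assert total == pytest.approx(1.0)

    def test_positives_only_when_labels_given(self):
        seqs = _seqs([["A", "B"]] * 30 + [["A", "C"]] * 30)
        labels = [1] * 30 + [-1] * 30
        g = build_semantic_graph(seqs, {"A", "B", "C"}, labels=labels)
        assert ("A", "B") in g.edges and ("A", "C") not in g.edges


class TestRandomWalks:
    def _chain(self):
        seqs = _seqs([["A", "B", "C"]] * 30)
        return build_semantic_graph(seqs, {"A", "B", "C"})

    def test_chain_paths_enumerated(self):
        pats = {p.labels for p in random_walk_patterns(self._chain(), seed=0)}
        assert {("A", "B"), ("A", "B", "C"), ("B", "C")} <= pats

    def test_walks_stay_on_graph_paths(self):
        # every emitted pattern is a path of the enumerable path set (DAG)
        g = self._chain()
        valid = {("A", "B"), ("A", "B", "C"), ("B", "C")}
        for seed in range(5):
            pats = {p.labels for p in random_walk_patterns(g, seed=seed)}
            assert pats <= valid

    def test_empty_graph_no_patterns(self):
        from pipe_ppi.mining import SemanticGraph
        assert random_walk_patterns(SemanticGraph(vertices=["A"], edges={})) == []

    def test_deterministic_given_seed(self):
        g = self._chain()
        a = [p.labels for p in random_walk_patterns(g, seed=7)]
        b = [p.labels for p in random_walk_patterns(g, seed=7)]
        assert a == b


class TestMergePatterns:
    def test_covered_bigram_absorbed(self):
        big = _pat("PROTEIN1", "Binding", "Regulation", "Transcription", "PROTEIN2")
        out = merge_patterns([_pat("PROTEIN1", "Binding"), big])
        assert [p.labels for p in out] == [big.labels]

    def test_pivot_concatenation(self):
        out = merge_patterns([
            _pat("Positive_regulation", "Regulation"),
            _pat("Regulation", "Gene_expression", "PROTEIN1"),
        ])
        assert [p.labels for p in out] == [
            ("Positive_regulation", "Regulation", "Gene_expression", "PROTEIN1")]

    def test_singleton_unchanged(self):
        p = _pat("A", "B", "C")
        assert [q.labels for q in merge_patterns([p])] == [p.labels]

    def test_idempotent(self, rng):
        classes = ["A", "B", "C", "D", "PROTEIN1"]
        pats = []
        for _ in range(12):
            k = int(rng.integers(2, 5))
            pats.append(_pat(*rng.choice(classes, size=k, replace=False)))
        once = merge_patterns(pats)
        twice = merge_patterns(once)
        assert [p.labels for p in once] == [p.labels for p in twice]


class TestLLR:
    def test_zero_when_rates_equal(self):
        c = ContingencyCounts(n_pos=10, n_neg=10, n_sc_pos=5, n_sc_neg=5)
        assert llr_score(c) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_four_factor_evaluation(self):
        # independent arithmetic oracle: evaluate the printed expression
        n1 = n2 = 10
        k1, k2 = 8, 2
        p = (k1 + k2) / (n1 + n2)
        p1, p2 = k1 / n1, k2 / n2
        num = (p ** k1 * (1 - p) ** (n1 - k1)) * (p ** k2 * (1 - p) ** (n2 - k2))
        den = (p1 ** k1 * (1 - p1) ** (n1 - k1)) * (p2 ** k2 * (1 - p2) ** (n2 - k2))
        expected = -2.0 * math.log(num / den)
        got = llr_score(ContingencyCounts(n1, n2, k1, k2))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(7.709790, abs=1e-5)

    def test_extreme_separation_finite_and_monotone_in_n(self):
        vals = [llr_score(ContingencyCounts(n, n, n, 0)) for n in range(2, 21)]
        assert all(math.isfinite(v) and v > 0 for v in vals)
        assert vals == sorted(vals)

    def test_monotone_in_rate_separation(self):
        # fixed margins, growing |p(SC|I) - p(SC|not I)|
        vals = [llr_score(ContingencyCounts(20, 20, 10 + d, 10 - d))
                for d in range(0, 11)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_no_sentences_is_error(self):
        with pytest.raises(ValueError):
            llr_score(ContingencyCounts(0, 0, 0, 0))

    def test_nonnegative_random_tables(self, rng):
        for _ in range(200):
            n1, n2 = int(rng.integers(1, 30)), int(rng.integers(1, 30))
            c = ContingencyCounts(n1, n2, int(rng.integers(0, n1 + 1)),
                                  int(rng.integers(0, n2 + 1)))
            assert llr_score(c) >= -1e-9


class TestRankAndMatch:
    def test_top_k_cap(self):
        pats = [_pat("A", f"B{i}") for i in range(25)]
        out = rank_and_select_patterns(pats, {"A": 1.0}, k=20)
        assert len(out) == 20

    def test_fewer_than_k(self):
        pats = [_pat("A", "B"), _pat("A", "C"), _pat("B", "C")]
        assert len(rank_and_select_patterns(pats, {}, k=20)) == 3

    def test_tie_breaks_prefer_longer(self):
        llr = {"A": 1.0, "B": 1.0, "C": 0.0, "D": 0.0}
        short = _pat("A", "B")
        long = _pat("A", "B", "C", "D")
        out = rank_and_select_patterns([short, long], llr, k=2)
        assert out[0].labels == long.labels
        assert out[0].score == out[1].score == 2.0

    def test_match_subsequence(self):
        seq = SCSequence(labels=["PROTEIN1", "Binding", "PROTEIN2", "Antagonist"])
        assert match_pattern(_pat("PROTEIN1", "Binding", "PROTEIN2"), seq)
        assert match_pattern(_pat("PROTEIN1", "Antagonist"), seq)

    def test_match_rejects_wrong_order_and_overlong(self):
        seq = SCSequence(labels=["PROTEIN1", "Binding", "PROTEIN2"])
        assert not match_pattern(_pat("Binding", "PROTEIN1"), seq)
        assert not match_pattern(_pat("PROTEIN1", "Binding", "PROTEIN2", "X"), seq)


class TestEndToEndMining:
    def test_planted_patterns_recovered(self, small_corpus, small_config, lexicon):
        from pipe_ppi.semantic import label_semantic_classes
        from pipe_ppi.synthetic import DEFAULT_PLANTED_PATTERNS

        seqs = [label_semantic_classes(i.normalized, lexicon, require_pair=False)
                for i in small_corpus.instances]
        mined = mine_patterns(seqs, small_corpus.labels, small_config)
        mined_labels = [p.labels for p in mined]
        for planted in DEFAULT_PLANTED_PATTERNS:
            found = any(
                len(m) >= len(planted)
                and any(m[i:i + len(planted)] == planted
                        for i in range(len(m) - len(planted) + 1))
                for m in mined_labels)
            assert found, f"planted pattern {planted} not recovered"
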