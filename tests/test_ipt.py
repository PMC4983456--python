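"""IPT construction: SPET, branching, pruning, duplicate removal, ornament."""

import pytest

from pipe_ppi.candidates import ExpandedCandidate
from pipe_ppi.formats_io import RunConfig, default_trigger_lexicon
from pipe_ppi.ipt import (
    StopwordList,
    branch,
    build_stopword_list,
    construct_ipt,
    extract_spet,
    ornament,
    protein_dependency_path,
    prune_middle_clauses,
    prune_stopwords,
    remove_duplicate_nodes,
)
from pipe_ppi.mining import InteractionPattern
from pipe_ppi.tree import DependencyGraph, parse_bracketed, write_bracketed

CLAUSE_WORDS = {"which", "is", "important", "brain", "development"}


@pytest.fixture
def creb(worked):
    fx = worked["creb_cbp"]
    return fx, fx.mention_spans["CREB"], fx.mention_spans["CBP"]


class TestExtractSpet:
    def test_excludes_trailing_verb(self, creb):
        fx, m1, m2 = creb
        spet = extract_spet(fx.tree, m1, m2)
        assert "tightened" not in spet.tokens()

    def test_leaf_set_is_exactly_the_enclosed_tokens(self, creb):
        fx, m1, m2 = creb
        spet = extract_spet(fx.tree, m1, m2)
        expected = fx.tree.tokens()[m1[0]:m2[1]]
        assert spet.tokens() == expected

    def test_pair_under_one_np(self):
        t = parse_bracketed("(S (NP (NN PROTEIN1) (CC and) (NN PROTEIN2)) (VP (VB act)))")
        spet = extract_spet(t, (0, 1), (2, 3))
        assert spet.label == "NP"
        assert spet.tokens() == ["PROTEIN1", "and", "PROTEIN2"]

    def test_mention_outside_tree_is_error(self):
        t = parse_bracketed("(NP (NN a))")
        with pytest.raises(ValueError):
            extract_spet(t, (0, 1), (5, 6))


class TestBranch:
    def test_adds_trailing_verb(self, creb):
        fx, m1, m2 = creb
        spet = extract_spet(fx.tree, m1, m2)
        out = branch(spet, fx.tree, m2)
        assert "tightened" in out.tokens()

    def test_sentence_ending_at_second_protein_is_identity(self):
        t = parse_bracketed("(S (NP (NN PROTEIN1)) (VP (VB binds) (NP (NN PROTEIN2))))")
        spet = extract_spet(t, (0, 1), (2, 3))
        out = branch(spet, t, (2, 3))
        assert write_bracketed(out) == write_bracketed(spet)

    def test_verb_in_unrelated_clause_is_identity(self):
        # the later verb sits under an S sibling, not a VP covering PROTEIN2
        t = parse_bracketed(
            "(S (S (NP (NN PROTEIN1)) (VP (VB binds) (NP (NN PROTEIN2))))"
            " (CC but) (S (NP (NN cells)) (VP (VB died))))")
        spet = extract_spet(t, (0, 1), (2, 3))
        out = branch(spet, t, (2, 3))
        assert "died" not in out.tokens()


class TestDependencyPath:
    def test_worked_example_path(self, creb):
        fx, m1, m2 = creb
        path = protein_dependency_path(fx.deps, m1, m2)
        assert [fx.deps.tokens[i] for i in path] == [
            "CREB", "effects", "genes", "interaction", "CBP"]

    def test_direct_edge(self):
        deps = DependencyGraph(tokens=["a", "b"], edges=[("nsubj", 1, 0)])
        assert protein_dependency_path(deps, (0, 1), (1, 2)) == [0, 1]

    def test_disconnected_yields_empty(self):
        deps = DependencyGraph(tokens=["a", "b", "c"], edges=[("dep", 0, 1)])
        assert protein_dependency_path(deps, (0, 1), (2, 3)) == []


class TestPruneMiddleClauses:
    def test_off_path_clause_removed(self, creb):
        fx, m1, m2 = creb
        spet = extract_spet(fx.tree, m1, m2)
        path = protein_dependency_path(fx.deps, m1, m2)
        out = prune_middle_clauses(spet, path, m1, m2)
        assert not (set(out.tokens()) & CLAUSE_WORDS)
        assert {"CREB", "CBP"} <= set(out.tokens())

    def test_clause_on_path_retained(self, creb):
        fx, m1, m2 = creb
        spet = extract_spet(fx.tree, m1, m2)
        # pretend a clause token lies on the dependency path
        path_with_clause = [m1[0], 7, m2[0]]
        out = prune_middle_clauses(spet, path_with_clause, m1, m2)
        assert "important" in out.tokens()

    def test_empty_path_skips_pruning(self, creb):
        fx, m1, m2 = creb
        spet = extract_spet(fx.tree, m1, m2)
        out = prune_middle_clauses(spet, [], m1, m2)
        assert write_bracketed(out) == write_bracketed(spet)


class TestStopwords:
    def test_cutoff_then_exclusions(self):
        pairs = ([("the", "DT")] * 50 + [("of", "IN")] * 30
                 + [("binds", "VBZ")] * 15 + [("PROTEIN1", "NN")] * 5)
        sw = build_stopword_list(pairs, RunConfig())
        assert sw.stems == {"the", "of"}

    def test_all_verbs_gives_empty_list(self):
        sw = build_stopword_list([("binds", "VBZ")] * 10 + [("bound", "VBD")] * 10)
        assert sw.stems == set()

    def test_with_is_listed_when_corpus_frequent(self, creb):
        # "with" enters the list through its corpus frequency as a common
        # preposition; emulate that by repeating function words corpus-wide
        fx, _, _ = creb
        pairs = [(n.children[0].word, n.label)
                 for n in fx.tree.internal_nodes() if n.is_preterminal]
        pairs += [("with", "IN"), ("the", "DT"), ("of", "IN")] * 10
        sw = build_stopword_list(pairs, RunConfig())
        assert "with" in sw.stems
        assert "tightened" not in sw.stems  # verbs never listed

    def test_prune_removes_leaf_and_preterminal(self):
        t = parse_bracketed("(PP (IN with) (NP (NN CBP)))")
        out = prune_stopwords(t, StopwordList({"with"}))
        assert write_bracketed(out) == "(PP (NP (NN CBP)))"

    def test_no_stopwords_is_identity(self):
        t = parse_bracketed("(NP (NN CREB))")
        assert write_bracketed(prune_stopwords(t, StopwordList({"the"}))) == str(t)

    def test_protein_leaves_survive_any_stopword_list(self, rng):
        from conftest import make_random_tree

        everything = StopwordList({w for w in
                                   ("a b binds the protein".split())})
        for _ in range(20):
            t = make_random_tree(rng)
            # plant a protein leaf
            t.children[0].children[0].children = []
            t.children[0].children[0].word = None
            from pipe_ppi.tree import ParseNode
            t.children[0].children[0].children = [
                ParseNode("PROTEIN1", word="PROTEIN1")]
            out = prune_stopwords(t, everything)
            assert "PROTEIN1" in out.tokens()


class TestRemoveDuplicates:
    @pytest.mark.parametrize("src,expected", [
        ("(VP (VP (VB binds)))", "(VP (VB binds))"),
        ("(X (X (X leaf)))", "(X leaf)"),
        ("(S (NP (NN a)) (VP (VB b)))", "(S (NP (NN a)) (VP (VB b)))"),
    ])
    def test_collapse(self, src, expected):
        assert write_bracketed(remove_duplicate_nodes(parse_bracketed(src))) == expected

    def test_no_unary_same_label_chain_remains(self, rng):
        from conftest import make_random_tree

        for _ in range(20):
            out = remove_duplicate_nodes(make_random_tree(rng))
            for node in out.internal_nodes():
                if len(node.children) == 1 and not node.children[0].is_leaf:
                    assert node.children[0].label != node.label


class TestOrnament:
    def test_ip_children_match_count_and_order(self):
        t = parse_bracketed("(S (NP (NN PROTEIN1)) (VP (VB binds) (NP (NN PROTEIN2))))")
        for ids in ([], ["IP1"], ["IP1", "IP2", "IP3"]):
            out = ornament(t, ids)
            ip_children = [c for c in out.root.children if c.label == "IP"]
            assert [c.children[0].word for c in ip_children] == ids
            assert out.ip_tags == ids


class TestConstructIpt:
    def _creb_candidate(self, fx):
        tokens = fx.tree.tokens()
        return ExpandedCandidate(
            normalized=["PROTEIN1" if i == 3 else "PROTEIN2" if i == 18 else t
                        for i, t in enumerate(tokens)],
            m1=fx.mention_spans["CREB"], m2=fx.mention_spans["CBP"],
            parse=fx.tree, deps=fx.deps)

    def test_worked_example_end_to_end(self, worked, lexicon):
        fx = worked["creb_cbp"]
        cand = self._creb_candidate(fx)
        stopwords = StopwordList({"with", "the", "of", "via", ",", "."})
        patterns = [InteractionPattern(labels=("PROTEIN1", "Binding", "PROTEIN2"))]
        ipt = construct_ipt(cand, patterns, stopwords, lexicon)
        tokens = ipt.root.tokens()
        assert "tightened" in tokens
        assert not (set(tokens) & CLAUSE_WORDS)
        assert "with" not in tokens
        for node in ipt.root.internal_nodes():
            if len(node.children) == 1 and not node.children[0].is_leaf:
                assert node.children[0].label != node.label

    def test_minimal_tree_survives_unchanged(self, lexicon):
        t = parse_bracketed("(S (NP (NN PROTEIN1)) (VP (VB binds) (NP (NN PROTEIN2))))")
        cand = ExpandedCandidate(
            normalized=["PROTEIN1", "binds", "PROTEIN2"],
            m1=(0, 1), m2=(2, 3), parse=t,
            deps=DependencyGraph(tokens=["PROTEIN1", "binds", "PROTEIN2"],
                                 edges=[("nsubj", 1, 0), ("dobj", 1, 2)]))
        ipt = construct_ipt(cand, [], StopwordList(set()), lexicon)
        assert write_bracketed(ipt.root) == write_bracketed(t)

    def test_deterministic(self, worked, lexicon):
        fx = worked["creb_cbp"]
        cand = self._creb_candidate(fx)
        sw = StopwordList({"with", "the"})
        a = construct_ipt(cand, [], sw, lexicon)
        b = construct_ipt(cand, [], sw, lexicon)
        assert write_bracketed(a.root) == write_bracketed(b.root)

    def test_pair_retained_through_all_operators(self, small_corpus, lexicon):
        sw = StopwordList({"the", "of", "in", "via", "and", ".", ","})
        for inst in small_corpus.instances[:40]:
            ipt = construct_ipt(inst, [], sw, lexicon)
            assert {"PROTEIN1", "PROTEIN2"} <= set(ipt.root.tokens())
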