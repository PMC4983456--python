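import numpy as np
import pytest

from pipe_ppi import (
    FixtureSpec,
    RunConfig,
    default_trigger_lexicon,
    generate_corpus,
    worked_example_fixtures,
)
from pipe_ppi.tree import ParseNode, assign_spans

_LABELS = ["S", "NP", "VP", "PP"]
_POS = ["NN", "VB", "DT", "IN"]
_WORDS = ["a", "b", "binds", "the", "protein"]


def make_random_tree(rng: np.random.Generator, max_internal: int = 8) -> ParseNode:
    """A small random constituency tree over a tiny shared vocabulary, so
    random tree pairs have common productions with nonzero probability."""
    budget = [int(rng.integers(2, max_internal + 1))]

    def node(depth: int) -> ParseNode:
        budget[0] -= 1
        if budget[0] <= 0 or depth >= 3 or rng.random() < 0.4:
            pos = _POS[rng.integers(len(_POS))]
            word = _WORDS[rng.integers(len(_WORDS))]
            return ParseNode(pos, [ParseNode(word, word=word)])
        label = _LABELS[rng.integers(len(_LABELS))]
        n_children = int(rng.integers(1, 3))
        return ParseNode(label, [node(depth + 1) for _ in range(n_children)])

    root = ParseNode("S", [node(1) for _ in range(int(rng.integers(1, 3)))])
    return assign_spans(root)


@pytest.fixture(scope="session")
def lexicon():
    return default_trigger_lexicon()


@pytest.fixture(scope="session")
def worked():
    return worked_example_fixtures()


@pytest.fixture(scope="session")
def small_corpus():
    """120-sentence planted corpus with thresholds scaled to its size."""
    return generate_corpus(FixtureSpec(n_sentences=120, seed=3))


@pytest.fixture(scope="session")
def small_config():
    return RunConfig(support_min=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
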