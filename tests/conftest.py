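import numpy as np
import pytest

from pathcnn import synthetic
from pathcnn.corpus_io import DependencyParse, Token


@pytest.fixture
def fig_sentence():
    """The hand-transcribed worked-example parse and its instance."""
    return synthetic.worked_example()


@pytest.fixture
def small_corpus():
    """60-instance balanced synthetic corpus."""
    config = synthetic.SynthConfig(n_instances=60, seed=123)
    return synthetic.generate(config)


def random_tree_parse(rng: np.random.Generator, n: int, sentence_id: str = "t") -> DependencyParse:
    """A random connected dependency tree over n tokens (random root,
    every other token attaches to a random earlier token in a shuffled
    order), used as ground for path-finding oracles."""
    order = rng.permutation(n) + 1
    heads = {int(order[0]): 0}
    for pos in range(1, n):
        heads[int(order[pos])] = int(order[rng.integers(0, pos)])
    tokens = tuple(
        Token(i, f"w{i}", heads[i], "dep" if heads[i] else "root") for i in range(1, n + 1)
    )
    return DependencyParse(sentence_id, tokens)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
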