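import numpy as np
import pytest

from melgram.grammar import default_grammar, generate_corpus


@pytest.fixture(scope="session")
def spec():
    return default_grammar()


@pytest.fixture(scope="session")
def exposure_corpus(spec):
    """A seeded 5000-melody exposure corpus, shared across tests."""
    return generate_corpus(spec, 5000, seed=1)


@pytest.fixture(scope="session")
def test_corpus(spec):
    """A seeded 2000-melody forced-choice corpus."""
    return generate_corpus(spec, 2000, seed=2, kind="test")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
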