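import numpy as np
import pytest

from kmerlm.kmer_tokens import build_vocabulary
from kmerlm.model_core import ModelConfig, build_model


@pytest.fixture(scope="session")
def vocab3():
    return build_vocabulary(3)


@pytest.fixture(scope="session")
def vocab5():
    return build_vocabulary(5)


@pytest.fixture(scope="session")
def mini_model():
    """Tiny untrained model used across structural tests."""
    return build_model(ModelConfig(k=3, hidden=32, layers=2, heads=2,
                                   ffn=64, max_positions=64, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
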