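import numpy as np
import pytest

from riskembed import Embedding, make_world


@pytest.fixture(scope="session")
def small_world():
    """A compact world shared by read-only tests."""
    return make_world(n_words=200, k_latent=5, seed=7, target_ceiling_r2=0.8)


@pytest.fixture()
def toy_embedding():
    rng = np.random.default_rng(0)
    tokens = [f"t{i}" for i in range(10)]
    return Embedding(tokens=tokens, vectors=rng.standard_normal((10, 5)))
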