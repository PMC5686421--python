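import numpy as np
import pytest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_world():
    """A small synthetic world shared by integration-level tests."""
    from termrank.synth import SyntheticConfig, generate_world

    cfg = SyntheticConfig(
        vocab_size=200,
        n_docs=30,
        doc_length=40,
        embedding_dim=12,
        n_terms=400,
        n_annotated=260,
        seed=7,
    )
    return generate_world(cfg)


def make_separable(n: int, F: int, rng: np.random.Generator, margin: float = 1.0):
    """Linearly separable 2-class data with a known direction."""
    w = rng.normal(size=F)
    w /= np.linalg.norm(w)
    X = rng.normal(size=(n, F))
    z = X @ w
    y = (z > 0).astype(float)
    X += margin * np.outer(2 * y - 1, w)
    return X, y
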