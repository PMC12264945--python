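import numpy as np
import pytest

from attnprobe import (
    SyntheticSpec,
    gen_corpus,
    process_stack,
)


@pytest.fixture(scope="session")
def small_corpus():
    """Ten short molecules with strong planted signal (alpha=0.8)."""
    return gen_corpus(
        SyntheticSpec(n_molecules=10, length_range=(30, 50), alpha=0.8, seed=42)
    )


@pytest.fixture(scope="session")
def small_processed(small_corpus):
    return [process_stack(s) for s in small_corpus.stacks]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
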