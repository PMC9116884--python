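import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_501)


@pytest.fixture
def random_dna():
    """Factory for random DNA strings of a given length."""
    gen = np.random.default_rng(7)

    def make(length: int, seed: int | None = None) -> str:
        r = gen if seed is None else np.random.default_rng(seed)
        return "".join(r.choice(list("ACGT"), size=length))

    return make
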