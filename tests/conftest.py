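import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def make_seq(rng):
    def _make(n):
        return random_seq(rng, n)

    return _make
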