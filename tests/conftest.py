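import numpy as np
import pytest
from hypothesis import settings

from castvote import generate_profile

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")


@pytest.fixture
def random_profile_factory():
    """Seeded factory for distinct-ability profiles of a given length."""

    def make(n: int, seed: int):
        return generate_profile("random_distinct", n=n, seed=seed)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
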