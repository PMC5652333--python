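import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_peptides(rng):
    """1,000 random peptides over the standard alphabet, lengths 1-60."""
    from acpml import AMINO_ACIDS

    alphabet = list(AMINO_ACIDS)
    seqs = []
    for _ in range(1000):
        length = int(rng.integers(1, 61))
        seqs.append("".join(rng.choice(alphabet, size=length)))
    return seqs
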