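import random

import pytest


@pytest.fixture
def rng():
    """Suite-wide deterministic RNG."""
    return random.Random(0)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(alphabet) for _ in range(n))
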