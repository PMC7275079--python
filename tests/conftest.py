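import random

import pytest


def random_edges(rng: random.Random, n: int, p: float):
    """Erdos-Renyi edge list on n nodes."""
    return [(u, v) for u in range(n) for v in range(u + 1, n) if rng.random() < p]


@pytest.fixture
def rng():
    return random.Random(20240613)
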