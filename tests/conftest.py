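import numpy as np
import pytest

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def mutate_seq(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base with probability ``rate`` (never to itself)."""
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        cur = "ACGT".index(out[i])
        out[i] = "ACGT"[(cur + int(rng.integers(1, 4))) % 4]
    return "".join(out)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
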