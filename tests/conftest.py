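import numpy as np
import pytest

from circkit.model import Circle


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genome(rng):
    """Two-chromosome synthetic genome, 150 kb total."""
    return {
        "chr1": "".join(rng.choice(list("ACGT"), 100_000)),
        "chr2": "".join(rng.choice(list("ACGT"), 50_000)),
    }


def random_circles(rng, n, chroms=("chr1", "chr2"), max_pos=100_000,
                   with_splits=True, tool=None):
    """Random valid circles for property-style tests."""
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos - 200))
        length = int(rng.integers(100, 5000))
        out.append(
            Circle(
                str(rng.choice(list(chroms))),
                start,
                start + length,
                split_reads=int(rng.integers(0, 20)) if with_splits else None,
                tool=tool,
            )
        )
    return out
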