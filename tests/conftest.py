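import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from balsel.haplotypes import HaplotypeAlignment


def random_alignment(rng, n=None, S=None, L=200, pops=None) -> HaplotypeAlignment:
    """Random polymorphic alignment; every site genuinely segregating."""
    n = n if n is not None else int(rng.integers(4, 11))
    S = S if S is not None else int(rng.integers(2, 13))
    H = np.zeros((n, S), dtype=np.int8)
    for j in range(S):
        c = int(rng.integers(1, n))
        rows = rng.choice(n, size=c, replace=False)
        H[rows, j] = 1
    positions = np.sort(rng.choice(np.arange(1, L + 1), size=S, replace=False))
    labels = list(pops) if pops else ["pop1"] * n
    return HaplotypeAlignment(
        chrom="rand",
        start=1,
        end=L,
        positions=positions,
        H=H,
        sample_ids=[f"h{i}" for i in range(n)],
        pop_labels=labels,
        polarized=np.ones(S, dtype=bool),
        outgroup=np.zeros(S, dtype=np.int8),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def make_alignment(rng):
    def _make(**kw):
        return random_alignment(rng, **kw)

    return _make
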