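import numpy as np
import pytest

from pvb.data_model import CellCounts, counts_to_dataset


@pytest.fixture
def toy_counts() -> CellCounts:
    """Module-wide toy table: T=1 stratum fully verified (40 diseased, 10
    not), T=0 stratum half verified (5 diseased, 20 not, 25 unverified)."""
    return CellCounts(s11=40, s10=10, s01=5, s00=20, u1=0, u0=25)


@pytest.fixture
def toy_dataset(toy_counts):
    return counts_to_dataset(toy_counts)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
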