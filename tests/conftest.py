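import numpy as np
import pytest

from dfppi import STANDARD_RESIDUES, ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_sequence(rng):
    """Factory for random standard-residue sequences."""

    def make(length: int) -> str:
        return "".join(rng.choice(list(STANDARD_RESIDUES), size=length))

    return make


@pytest.fixture
def random_records(random_sequence):
    def make(n: int, min_len: int = 50, max_len: int = 150, prefix: str = "r") -> list[ProteinRecord]:
        rng2 = np.random.default_rng(999)
        return [
            ProteinRecord(f"{prefix}{i}", random_sequence(int(rng2.integers(min_len, max_len + 1))))
            for i in range(n)
        ]

    return make
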