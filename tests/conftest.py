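import numpy as np
import pytest

import scoredel as sd

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


@pytest.fixture(scope="session")
def locus():
    """A small seeded locus: 100%-identity repeats, one planted guide."""
    return sd.simulate_locus(
        lcr_length=1_000, inter_lcr_length=5_000, flank_length=2_000, seed=101
    )


@pytest.fixture(scope="session")
def preset_locus():
    """The 22q-like preset geometry: 5-kb repeats, 50-kb spacer."""
    return sd.simulate_locus(seed=202)
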