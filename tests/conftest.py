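import pytest

from regulonmap import LLDR_BOX, parse_consensus
from regulonmap.synthetic import simulate_dataset


@pytest.fixture(scope="session")
def lldr_box():
    return parse_consensus(LLDR_BOX)


@pytest.fixture(scope="session")
def small_dataset():
    """Noise-free 4-site dataset with perfect planted boxes."""
    return simulate_dataset(seed=11, n_sites=4, mismatches=0, amplitude=10.0,
                            noise_sd=0.0)
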