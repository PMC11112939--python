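import numpy as np
import pytest

from nics.genome import make_genome

TOY_CONFIG = {
    "bin_size": 1_000_000,
    "chromosomes": [
        {"name": "chr1", "length": 100_000_000, "centromere": 40_000_000},
        {"name": "chr2", "length": 60_000_000, "centromere": 25_000_000},
        {"name": "chrX", "length": 50_000_000, "centromere": 20_000_000},
        {"name": "chrY", "length": 20_000_000, "centromere": 8_000_000},
    ],
}


@pytest.fixture(scope="session")
def toy_genome():
    return make_genome(TOY_CONFIG)


@pytest.fixture(scope="session")
def default_genome():
    return make_genome()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
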