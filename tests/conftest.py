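import numpy as np
import pytest

from trquant.synthetic import SimConfig
from trquant.variants import load_packaged_variants


@pytest.fixture(scope="session")
def packaged_table():
    return load_packaged_variants()


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture
def small_simconfig():
    """Down-scaled generator (fewer events) for fast module tests."""
    return SimConfig(
        truth_table={("R198X", "none"): 0.014},
        n_events_per_well=2_000,
        seed=11,
    )
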