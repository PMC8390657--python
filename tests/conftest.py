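import numpy as np
import pytest

import soilvirome as sv
from soilvirome import rna_screen


@pytest.fixture(scope="session")
def small_truth() -> sv.CommunityTruth:
    """A small fixed community shared by read-only tests."""
    cfg = sv.CommunityConfig(n_hosts=5, n_viral=12, n_rna_viral=3)
    return sv.make_community(cfg, seed=7)


@pytest.fixture(scope="session")
def calibrated_profiles() -> list:
    """Contig-scale calibrated RdRP profiles (expensive; built once)."""
    return rna_screen.default_profiles(seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
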