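import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bathyphy as bp

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def yule_tree():
    """A 12-leaf pure-birth tree, fixed seed."""
    return bp.simulate_yule_tree(12, birth_rate=1.0, seed=11)


@pytest.fixture(scope="session")
def reference_fixture():
    """The standard barcode study: 3 genera x 4 species, within ~1%, between ~10%."""
    return bp.make_reference_fixture(
        n_genera=3, species_per_genus=4, within_d=0.01, between_d=0.10, seed=101
    )
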