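import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bridgekit as bk

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def scaffold177():
    """A placeholder 177-nt scaffold with the conserved bases planted."""
    return bk.random_scaffold(np.random.default_rng(42))


@pytest.fixture
def target_window():
    return bk.make_window("ACGTACGCTGACTA", role="target")


@pytest.fixture
def donor_window():
    return bk.make_window("TTCAGATCTTGATT", role="donor")


@pytest.fixture
def designed(scaffold177, target_window, donor_window):
    """Post-HSB design against the worked-example window pair."""
    return bk.design_bridge_rna(scaffold177, target_window, donor_window)
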