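import numpy as np
import pytest

from mirrornet.fixtures import build_fixture_bundle


@pytest.fixture(scope="session")
def bundle():
    """Tiny seeded fixture bundle covering every study family."""
    return build_fixture_bundle(seed=7, per_family=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
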