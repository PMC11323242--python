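import pytest

from divhits.chem import DEFAULT_FP_CONFIG, tanimoto_distance
from divhits.fixtures import make_library


@pytest.fixture(scope="session")
def fp_config():
    return DEFAULT_FP_CONFIG


@pytest.fixture(scope="session")
def library100():
    """Small deterministic synthetic library shared across test modules."""
    return make_library(100, seed=7)


@pytest.fixture(scope="session")
def library_fps(library100):
    return [r.fingerprint for r in library100.records]


@pytest.fixture(scope="session")
def dist():
    return tanimoto_distance
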