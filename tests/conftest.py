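import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import tracenet as tn


@pytest.fixture(scope="session")
def fixtures():
    return tn.fixtures()


@pytest.fixture
def toy4(fixtures):
    return fixtures["TOY4"]


@pytest.fixture
def toy7(fixtures):
    return fixtures["TOY7"]


@pytest.fixture
def k4(fixtures):
    return fixtures["K4"]


@pytest.fixture
def ring5(fixtures):
    return fixtures["RING5"]


@pytest.fixture(scope="session")
def macaque_like():
    """A 29-node synthetic connectome at the study's conditions."""
    return tn.generate(tn.SynthSpec(seed=2024))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
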