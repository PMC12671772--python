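import numpy as np
import pytest

from tmsplast.model import build_model
from tmsplast.morphology import build_reduced_ca1
from tmsplast.membrane import assign_biophysics
from tmsplast.cable import discretize


@pytest.fixture(scope="session")
def morph():
    return build_reduced_ca1()


@pytest.fixture(scope="session")
def biophys(morph):
    return assign_biophysics(morph)


@pytest.fixture(scope="session")
def cell(morph, biophys):
    return discretize(morph, biophys)


@pytest.fixture(scope="session")
def model():
    """Default calibrated model, placement seed 0."""
    return build_model()


@pytest.fixture(scope="session")
def run_cache():
    """Session-wide memoisation for expensive simulation runs."""
    return {}
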