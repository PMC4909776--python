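import numpy as np
import pytest
from hypothesis import settings

from respsnn.harness import REFERENCE_PLANT, reference_controller

settings.register_profile("repro", derandomize=True, database=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def plant_params():
    """The shipped calibrated plant (a dedicated test pins it against a
    fresh calibration run)."""
    return REFERENCE_PLANT


@pytest.fixture()
def open_loop_controller():
    return reference_controller("open_loop")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
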