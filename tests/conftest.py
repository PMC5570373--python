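import numpy as np
import pytest

from spinesim.calcium import run_simulation
from spinesim.config import load_config
from spinesim.geometry import derive_geometry
from spinesim.glutamate import glutamate_params
from spinesim.protocols import control_perturbation, make_train, single_pulse


@pytest.fixture(scope="session")
def config():
    return load_config()


@pytest.fixture(scope="session")
def geometry(config):
    return derive_geometry(config)


@pytest.fixture(scope="session")
def glu_params(config):
    return glutamate_params(config)


@pytest.fixture(scope="session")
def hfs_protocol(config):
    return make_train(100.0, duration_ms=1000.0)


@pytest.fixture(scope="session")
def control_hfs_result(hfs_protocol, config):
    """One control HFS run shared by several tests (the expensive fixture)."""
    return run_simulation(hfs_protocol, control_perturbation(), config)


@pytest.fixture(scope="session")
def single_pulse_result(config):
    return run_simulation(single_pulse(post_ms=300.0), control_perturbation(),
                          config)
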