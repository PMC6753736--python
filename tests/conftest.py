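import numpy as np
import pytest

from linacqa import (
    MachineConstants,
    TestPlan,
    baseline_collimator_module,
    baseline_table_module,
)


@pytest.fixture(scope="session")
def machine():
    return MachineConstants()


@pytest.fixture(scope="session")
def table6():
    return baseline_table_module()


@pytest.fixture(scope="session")
def coll4():
    return baseline_collimator_module()


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


def grid_plan(n_gantry=5, n_collimator=5, sigma_mm=0.0, machine=None):
    return TestPlan.grid(n_gantry, n_collimator, sigma_mm=sigma_mm, machine=machine)


@pytest.fixture
def plan55():
    return grid_plan(5, 5, 0.0)
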