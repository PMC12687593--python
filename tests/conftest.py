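import numpy as np
import pytest

from vwfsim.parameters import SimulationConfig, VWFParams, bond_preset


@pytest.fixture(scope="session")
def vwf_params():
    return VWFParams()


@pytest.fixture(scope="session")
def m1():
    return bond_preset("m1")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A tiny but complete simulation configuration for engine tests."""
    return SimulationConfig(
        seed=42,
        n_vwf=2,
        n_platelet=4,
        duration_tau=1.0,
        bond_model="m1",
        flow={"type": "couette", "shear_rate_per_s": 4000.0},
        domain={"Lx_um": 10.0, "Ly_um": 10.0, "Lz_um": 10.0, "walls": True},
    )
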