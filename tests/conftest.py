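import dataclasses

import numpy as np
import pytest

from oxyrheo.device import ChannelGeometry, DeviceNetwork, HydraulicResistor
from oxyrheo.synthetic import BloodModelParams, default_network, default_pressure_steps
from oxyrheo.viscometry import InversionSettings


@pytest.fixture(scope="session")
def network() -> DeviceNetwork:
    return default_network()


@pytest.fixture(scope="session")
def spec_constants_network() -> DeviceNetwork:
    """Network with bare constants (c1=2e15, c2=4e15, c3=1e16) and no geometries."""
    return DeviceNetwork(
        inlet_resistor=HydraulicResistor.from_constant("inlet_resistor", 2e15),
        bypass=HydraulicResistor.from_constant("bypass", 4e15),
        experimental=HydraulicResistor.from_constant(
            "experimental", 1e16, geometry=ChannelGeometry(15e-6, 15e-6, 17.8e-6, "square")
        ),
    )


@pytest.fixture(scope="session")
def sickle_model():
    return BloodModelParams().sickle_model()


@pytest.fixture(scope="session")
def healthy_model():
    return BloodModelParams().healthy_model()


@pytest.fixture(scope="session")
def noiseless_sickle_model(sickle_model):
    return dataclasses.replace(sickle_model, noise_cv=0.0)


@pytest.fixture(scope="session")
def settings() -> InversionSettings:
    return InversionSettings()


@pytest.fixture(scope="session")
def pressure_steps() -> np.ndarray:
    return default_pressure_steps()
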