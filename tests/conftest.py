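import logging

import numpy as np
import pytest

from hpcsi.acquisition import AcquisitionParams, default_resonances
from hpcsi.kinetics import VoxelKinetics
from hpcsi.phantom import default_phantom


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def resonances():
    return default_resonances()


@pytest.fixture(scope="session")
def brain_kinetics():
    return VoxelKinetics(kpl=0.029, pyr_delivery_amp=1.0, urea_delivery_amp=0.5)


@pytest.fixture()
def phantom():
    return default_phantom(kpl=0.029)


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    """Voxel-level fit warnings are expected in bulk runs; keep logs clean."""
    logging.getLogger("hpcsi.pipeline").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230925)
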