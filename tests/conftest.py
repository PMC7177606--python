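import numpy as np
import pytest

from saruq.doe import ElectrodeLayout, fibonacci_cap_layout
from saruq.forward import ForwardModelParams, TissueModel, VoxelGrid


@pytest.fixture(scope="session")
def tissue():
    return TissueModel.three_layer_child_900mhz()


@pytest.fixture(scope="session")
def tiny_grid():
    return VoxelGrid(n_per_axis=5, extent_mm=68.0)


@pytest.fixture(scope="session")
def two_electrode_layout():
    return fibonacci_cap_layout(L=2, radius_mm=74.7, delta=np.deg2rad(2.0))


@pytest.fixture
def simple_layout():
    """One electrode at mid-latitude, handy for hand-checked geometry."""
    return ElectrodeLayout(
        radius_mm=74.7,
        ids=np.array([1]),
        theta=np.array([1.0]),
        phi=np.array([2.0]),
        delta=0.05,
    )
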