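import numpy as np
import pytest

from cellflow.builder import build_cell
from cellflow.membrane import MembraneParams
from cellflow.mesh import make_sphere_mesh


@pytest.fixture(scope="session")
def small_mesh():
    """162-vertex icosphere, the standard desk-scale membrane."""
    return make_sphere_mesh(1.66, 0.5)


@pytest.fixture(scope="session")
def tiny_mesh():
    """42-vertex icosphere for finite-difference sweeps."""
    return make_sphere_mesh(0.85, 0.5)


@pytest.fixture(scope="session")
def small_cell():
    """3.3-um cell: 162 outer + 42 nucleus vertices, calibrated defaults."""
    return build_cell(3.3, 0.29)


@pytest.fixture(scope="session")
def sweep_cell():
    """6.6-um cell: 642 outer vertices, the standard sweep resolution."""
    return build_cell(6.6, 0.29)


def membrane_params_for(mesh, **overrides) -> MembraneParams:
    kw = dict(
        p=0.00141, l_max=3.0, l_0=0.5, k_b=65.0, k_a=10_000.0,
        k_vol=15_000.0, a_0=mesh.area(), v_0=mesh.volume(), gamma=4.0,
        kbt=0.1,
    )
    kw.update(overrides)
    return MembraneParams(**kw)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
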