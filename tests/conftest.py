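import numpy as np
import pytest

from ianload.fem import LoadCase, default_materials, solve_case
from ianload.geometry import ModelParams, build_model
from ianload.meshing import box_mesh, generate_mesh


@pytest.fixture(scope="session")
def coarse_params():
    """Default geometry at a coarse 1 mm grid (fast enough for unit tests;
    interface planes are snapped, so every region is still resolved)."""
    return ModelParams(global_element_size=1.0)


@pytest.fixture(scope="session")
def coarse_mesh(coarse_params):
    return generate_mesh(build_model(coarse_params), coarse_params)


@pytest.fixture(scope="session")
def coarse_fields(coarse_mesh):
    """Reference 200 N solve with the default material set."""
    return solve_case(coarse_mesh, default_materials(), LoadCase(200.0))


@pytest.fixture(scope="session")
def small_box():
    """2x2x2 mm single-material block, 48 tets (dense-oracle scale)."""
    return box_mesh(2.0, 2.0, 2.0, (2, 2, 2))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
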