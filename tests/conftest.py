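import numpy as np
import pytest

from cellindent.geometry import GeometryParams, build_domain
from cellindent.loading import build_bcs, default_materials


@pytest.fixture(scope="session")
def default_params():
    return GeometryParams()


@pytest.fixture(scope="session")
def coarse_mesh():
    """Coarsest full cell-on-gel mesh; shared across tests (read-only)."""
    return build_domain(resolution=1)


@pytest.fixture(scope="session")
def coarse_bcs(coarse_mesh):
    return build_bcs(coarse_mesh)


@pytest.fixture(scope="session")
def soft_materials():
    """The study's baseline materials (0.8 kPa cytoplasm)."""
    return default_materials(E_cyto=0.8)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240301)
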