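import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from medialknee.contact import (
    CartilageMaterial,
    KneeGeometry,
    build_mesh,
)


@pytest.fixture(scope="session")
def default_mesh():
    """Default plateau mesh, shared across tests (read-only)."""
    return build_mesh(KneeGeometry(), CartilageMaterial())


@pytest.fixture(scope="session")
def single_spring():
    """Degenerate 1-element mesh whose force-depth law has a closed form."""
    geometry = KneeGeometry(mesh_dims=(1, 1), element_spacing=1.0)
    return build_mesh(geometry, CartilageMaterial())


@pytest.fixture(scope="session")
def reference_load_n():
    """Cohort-mean peak medial force for a cohort-mean body mass, newtons."""
    return 2.68 * 69.31 * 9.81
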