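import numpy as np
import pytest

from capsidfit.geometry import build_dodecahedron, enumerate_species
from capsidfit.scattering import SpeciesGeometry, default_q_grid, sphere_form_factor


@pytest.fixture(scope="session")
def model():
    return build_dodecahedron()


@pytest.fixture(scope="session")
def table(model):
    return enumerate_species(model)


@pytest.fixture(scope="session")
def geometry(table):
    return SpeciesGeometry.from_table(table, radius=100.0)


@pytest.fixture(scope="session")
def form_factor():
    return sphere_form_factor(default_q_grid(), radius=30.0)
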