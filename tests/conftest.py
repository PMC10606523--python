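import numpy as np
import pytest
from hypothesis import settings as hsettings

from pkagrid import synthetic_data as synth
from pkagrid.dielectric_model import DielectricScene, grid_from_structure
from pkagrid.pb_solver import SolverSettings
from pkagrid.pka_engine import EngineSettings
from pkagrid.structure_io import assign_parse, find_titratable_sites, load_parameter_table

hsettings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
hsettings.load_profile("suite")


@pytest.fixture(scope="session")
def parameter_table():
    return load_parameter_table()


@pytest.fixture(scope="session")
def solvated_helix():
    """Short poly-Ala helix with one Glu near the top, fully in water."""
    return assign_parse(synth.make_helix_in_slab([("GLU", 8)], n_residues=10))


@pytest.fixture(scope="session")
def helix_sites(solvated_helix):
    return find_titratable_sites(solvated_helix)


@pytest.fixture(scope="session")
def helix_map(solvated_helix):
    grid = grid_from_structure(solvated_helix, spacing=1.0, margin=12.0)
    return DielectricScene(structure=solvated_helix, ionic_strength=0.1).rasterize(grid)


@pytest.fixture(scope="session")
def engine_settings():
    return EngineSettings(solver=SolverSettings(ionic_strength=0.1), fine_spacing=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
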