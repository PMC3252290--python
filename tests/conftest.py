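import numpy as np
import pytest

from nsiscreen import assign_kinetics, build_library
from nsiscreen.render import FieldGeometry, NoiseParams, render_field


@pytest.fixture(scope="session")
def library():
    return build_library(seed=42, n_compounds=240)


@pytest.fixture(scope="session")
def small_library():
    return build_library(seed=42, n_compounds=24)


@pytest.fixture(scope="session")
def truth(library):
    return assign_kinetics(library, ("line1", "line2", "line3"),
                           structure_link=0.7, seed=1)


@pytest.fixture(scope="session")
def noiseless():
    return NoiseParams(background=0.0, read_sd=0.0, photon_noise=False)


@pytest.fixture(scope="session")
def sparse_geometry():
    """Cells with fully disjoint bodies, for conservation checks."""
    return FieldGeometry(n_cells=10, touching_fraction=0.0, separation=2.2,
                         margin=24.0)


def render_noiseless_field(kin, seed=0, n_cells=10):
    geom = FieldGeometry(n_cells=n_cells, touching_fraction=0.0,
                         separation=2.2, margin=24.0)
    noise = NoiseParams(background=0.0, read_sd=0.0)
    return render_field(kin, geom, noise, None, seed=seed)


@pytest.fixture(scope="session")
def inout_kinetics(truth):
    """An enter-and-leave compound with diffuse localization."""
    return next(
        k for k in truth.values()
        if k.behavior_class == "in_and_out" and k.localization == "diffuse"
        and k.cell_line == "line1"
    )
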