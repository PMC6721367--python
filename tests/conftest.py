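"""Shared fixtures: phantoms and solved fields reused across test modules."""

import numpy as np
import pytest

import tnirsim as t


@pytest.fixture(scope="session")
def tables():
    return t.load_reference_tables()


@pytest.fixture(scope="session")
def default_phantom():
    """The default axisymmetric four-layer phantom (0.5 mm spacing)."""
    return t.build_phantom()


@pytest.fixture(scope="session")
def coarse_phantom():
    """A cheaper axisymmetric phantom for coupled/thermal tests."""
    return t.build_phantom(spacing=1e-3, lateral_extent=30e-3, total_depth=40e-3)


@pytest.fixture(scope="session")
def coarse_props_810(coarse_phantom):
    return t.assign_properties(coarse_phantom, 810)


@pytest.fixture(scope="session")
def coarse_field_810(coarse_phantom, coarse_props_810):
    return t.solve_diffusion(coarse_phantom, coarse_props_810)


@pytest.fixture(scope="session")
def coupled_run_810(coarse_phantom, coarse_props_810, coarse_field_810):
    """Coupled diffusion + bioheat run at 810 nm on the coarse phantom."""
    Qr = t.heat_source(coarse_props_810.mu_a, coarse_field_810)
    temps = t.solve_steady_bioheat(coarse_phantom, coarse_props_810, Qr)
    return coarse_field_810, temps


@pytest.fixture(scope="session")
def gm_slab():
    """Homogeneous gray-matter 1-D slab (deep, fine): analytic test bed."""
    return t.build_phantom(
        layers=[t.LayerSpec("gray_matter", None)],
        grid_kind="slab_1d",
        spacing=0.5e-3,
        total_depth=100e-3,
    )


def axis_distance(phantom, z_source):
    """3-D distance from the on-axis source to on-axis cell centers."""
    dz = np.abs(phantom.z_centers() - z_source)
    return np.sqrt((phantom.spacing / 2) ** 2 + dz**2)
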