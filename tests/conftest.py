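"""Shared fixtures: small geometries for unit tests, the simulation-layout
probe, and helpers for building measurement sets from pair lists."""

import numpy as np
import pytest

from platedot.forward import OpticalProperties
from platedot.mesh import build_slab_mesh
from platedot.probe import build_probe, enumerate_pairs
from platedot.calibrate import MeasurementSet


@pytest.fixture(scope="session")
def sim_probe():
    """The 3 x 4 mirrored simulation layout, centred on the slab face."""
    return build_probe(3, 4, 13.0, 14.0, 44.0).centered_on(65.0, 39.5)


@pytest.fixture(scope="session")
def full_probe():
    """The full 7 x 8 system layout."""
    return build_probe(7, 8, 13.0, 14.0, 44.0)


@pytest.fixture(scope="session")
def small_probe():
    """A 2 x 2 probe on a thin small slab, for fast FEM tests."""
    return build_probe(2, 2, 13.0, 14.0, 30.0).centered_on(30.0, 25.0)


@pytest.fixture(scope="session")
def small_mesh(small_probe):
    """Coarse homogeneous slab matching ``small_probe``."""
    src = small_probe.source_positions
    mesh = build_slab_mesh(
        (30.0, 60.0, 50.0),
        h=5.0,
        plate_depth=1.0,
        snap_yz=(np.unique(src[:, 1]), np.unique(src[:, 2])),
    )
    mesh.set_homogeneous(0.004, 1.0)
    return mesh


@pytest.fixture(scope="session")
def background_props():
    return OpticalProperties(mu_a=0.004, mu_s_prime=1.0)


def make_measurements(pairs, amplitudes, role="task", wavelength_nm=750.0):
    return MeasurementSet.from_pairs(
        pairs, np.asarray(amplitudes, float), wavelength_nm=wavelength_nm, role=role
    )


@pytest.fixture(scope="session")
def sim_pairs(sim_probe):
    return enumerate_pairs(sim_probe)
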