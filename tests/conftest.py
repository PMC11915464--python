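"""Shared fixtures: phantoms are cheap, the full cap build is expensive and
therefore session-scoped (several acceptance properties measure the same
built cap)."""

import numpy as np
import pytest

import capforge as cf
from capforge import pipeline
from capforge.phantoms import make_ellipsoid, make_sphere


@pytest.fixture(scope="session")
def sphere100():
    """R = 100 mm, density-5 icosphere phantom (landmark accuracy checks)."""
    return make_sphere(100.0, 5)


@pytest.fixture(scope="session")
def sphere100_landmarks(sphere100):
    return cf.compute_landmarks(sphere100.mesh, sphere100.fiducials, "10-10")


@pytest.fixture(scope="session")
def sphere_d4():
    """R = 100 mm, density-4 icosphere (cap-build demo size)."""
    return make_sphere(100.0, 4)


@pytest.fixture(scope="session")
def ellipsoid_phantom():
    return make_ellipsoid(100.0, 80.0, 90.0, density=5)


@pytest.fixture(scope="session")
def cap_build(sphere_d4):
    """Full default cap build on the density-4 sphere: coarsen 0.05,
    4 mm grommets, 2.5 mm wire, default margins, re-tessellated + repaired."""
    landmarks = cf.compute_landmarks(sphere_d4.mesh, sphere_d4.fiducials,
                                     "10-10")
    return pipeline.build_cap(sphere_d4.mesh, landmarks)


def analytic_row_distances(radius: float) -> dict:
    """Closed-form reference-curve distances on a sphere: sagittal from Iz,
    coronal from RPA (distances to the 15 standard validation labels)."""
    sag = {"Fpz": 0.1, "AFz": 0.2, "Fz": 0.3, "FCz": 0.4, "Cz": 0.5,
           "CPz": 0.6, "Pz": 0.7, "POz": 0.8, "Oz": 0.9}
    cor = {"C5": 0.2, "C3": 0.3, "C1": 0.4, "C2": 0.6, "C4": 0.7, "C6": 0.8}
    return {
        "sagittal": {k: (1 - t) * np.pi * radius for k, t in sag.items()},
        "coronal": {k: (1 - t) * np.pi * radius for k, t in cor.items()},
    }
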