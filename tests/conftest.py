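"""Shared fixtures: phantom meshes and analytic fields (module scope for speed)."""

import numpy as np
import pytest
from skimage import measure

from anewall import synthetic as syn
from anewall.core import BLOOD_ANALOGUE
from anewall.mesh import TriangleMesh

TUBE_RADIUS = 1.675  # mm, IA1-like parent artery radius
TUBE_LENGTH = 20.0
Q_REF = 4.38  # ml/s


@pytest.fixture(scope="session")
def tube():
    """(mesh, centerline) straight tube phantom."""
    return syn.make_tube_phantom(TUBE_RADIUS, TUBE_LENGTH)


@pytest.fixture(scope="session")
def sphere_on_tube():
    """(mesh, centerline) tube with a 5 mm sac, 3 mm neck."""
    return syn.make_sphere_on_tube(1.7, 5.0, 3.0)


@pytest.fixture(scope="session")
def poiseuille_05():
    """Steady Poiseuille field on the acquisition grid (0.5 mm voxels)."""
    grid = syn.GridSpec.for_tube(TUBE_RADIUS, TUBE_LENGTH, spacing=0.5)
    return syn.sample_poiseuille(grid, Q_REF, TUBE_RADIUS)


@pytest.fixture(scope="session")
def womersley_ica():
    """Pulsatile Womersley field of the built-in waveform, 0.5 mm voxels."""
    wf = syn.make_ica_waveform(Q_REF)
    grid = syn.GridSpec.for_tube(TUBE_RADIUS, TUBE_LENGTH, spacing=0.5)
    return syn.sample_womersley(grid, wf, TUBE_RADIUS)


@pytest.fixture(scope="session")
def ica_waveform():
    return syn.make_ica_waveform(Q_REF)


def marching_sphere(radius: float = 1.0, pitch: float = 0.08) -> TriangleMesh:
    """Watertight triangulated sphere from an implicit marching-cubes extract."""
    g = np.arange(-radius - 0.3, radius + 0.3 + pitch, pitch)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    f = np.sqrt(X**2 + Y**2 + Z**2) - radius
    v, faces, _, _ = measure.marching_cubes(f, 0.0, spacing=(pitch,) * 3)
    return TriangleMesh(v + g[0], faces.astype(np.int64))


@pytest.fixture(scope="session")
def unit_sphere_mesh():
    return marching_sphere()


@pytest.fixture(scope="session")
def mu_blood():
    return BLOOD_ANALOGUE.dynamic_viscosity
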