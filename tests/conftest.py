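import numpy as np
import pytest

from viscolb import boundaries, membrane
from viscolb.driver import LatticeRun, make_particle

#: stable rigid-limit moduli used by the desk-scale coupled fixtures
RIGID_LATTICE = membrane.RIGID_MODULI_LATTICE


@pytest.fixture(scope="session")
def sphere120():
    return membrane.generate_sphere_mesh(6.0, 120)


@pytest.fixture(scope="session")
def sphere480():
    return membrane.generate_sphere_mesh(12.0, 480)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240908)


def make_duct_run(ny=18, nz=18, nx=4, lam=0.8, accel=0.0, polymer=None,
                  particles=None):
    section = boundaries.duct_section(ny, nz)
    ws = boundaries.build_wallset(section)
    return LatticeRun((nx, ny, nz), section, ws, lambda_f=lam, accel=accel,
                      polymer=polymer, particles=particles or [])


def make_shear_run(u_wall, ny=18, nz=12, nx=4, lam=0.8, polymer=None,
                   particles=None):
    section, ws, gdot = boundaries.shear_box(u_wall, ny, nz)
    run = LatticeRun((nx, ny, nz), section, ws, lambda_f=lam, polymer=polymer,
                     particles=particles or [], periodic=(True, False, True))
    return run, gdot


def centered_particle(shape, diameter=6.0, n_faces=120, moduli=RIGID_LATTICE,
                      offset=(0.0, 0.0, 0.0)):
    nx, ny, nz = shape
    center = (nx / 2.0 + offset[0], (ny - 1) / 2.0 + offset[1],
              (nz - 1) / 2.0 + offset[2])
    return make_particle(diameter, n_faces, center, moduli)
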