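import numpy as np
import pytest

from aucbind.hydro import (
    BSA,
    InteractionParams,
    ParticleSpec,
    SolventModel,
)
from aucbind.lamm import CellGeometry, RotorProgram, default_scan_times


@pytest.fixture(scope="session")
def water():
    return SolventModel()


@pytest.fixture(scope="session")
def cell():
    return CellGeometry()


@pytest.fixture(scope="session")
def mus_m_particle():
    """Medium MUS-coated AuNP: 7.0 nm, 5.5 g/cm³."""
    return ParticleSpec(hydrodynamic_diameter=7.0e-9, density=5500.0,
                        label="MUS(m)")


@pytest.fixture(scope="session")
def bsa():
    return BSA


@pytest.fixture(scope="session")
def mua_params():
    """MUA-AuNP/BSA Hill parameters: K_D 5.4 uM, N_max 18, n 0.8."""
    return InteractionParams(k_d=5.4e-6, n_max=18.0, hill_n=0.8)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def make_rotor(s_slowest, rpm=10000.0, cell=CellGeometry(), n_scans=45):
    return RotorProgram(rpm, default_scan_times(s_slowest, rpm, cell, n_scans))
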