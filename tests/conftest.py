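import numpy as np
import pytest

import lh2exciton as lx


@pytest.fixture(scope="session")
def ideal_ring():
    """Ideal nonameric double ring (27 sites, HL site energies)."""
    return lx.build_ideal_ring()


@pytest.fixture(scope="session")
def ring18(ideal_ring):
    """The 18-site B850 subring of the ideal complex."""
    return ideal_ring.b850_subframe()


@pytest.fixture(scope="session")
def nn_records(ring18):
    """Nearest-neighbor point-dipole couplings of the ideal 18-ring."""
    return lx.couple_frame(ring18, method="point_dipole", cutoff=12.0)


@pytest.fixture(scope="session")
def ring18_states(ring18, nn_records):
    """Eigenstates of the ideal 18-ring NN Hamiltonian with its dipoles."""
    ham = lx.hamiltonian_from_frame(ring18, nn_records)
    states = lx.diagonalize(ham, ring18.dipoles)
    lx.assign_k(states)
    return states


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
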