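import numpy as np
import pytest

from rdmvqe.experiments import fixture_scf
from rdmvqe.hamiltonian import fold_frozen_core, jordan_wigner_hamiltonian
from rdmvqe.molecular_system import select_active_space
from rdmvqe.reference_ci import solve_casci


@pytest.fixture(scope="session")
def h2_scf():
    return fixture_scf("h2")


@pytest.fixture(scope="session")
def h3plus_scf():
    return fixture_scf("h3plus")


@pytest.fixture(scope="session")
def h4_scf():
    return fixture_scf("h4_chain")


@pytest.fixture(scope="session")
def h2_problem(h2_scf):
    """(scf, active, folded hamiltonian, qubit hamiltonian, casci) for H2."""
    active = select_active_space(h2_scf, 2, 2)
    ham = fold_frozen_core(h2_scf, active)
    qubit = jordan_wigner_hamiltonian(ham)
    ci = solve_casci(ham)
    return h2_scf, active, ham, qubit, ci


@pytest.fixture(scope="session")
def h4_problem(h4_scf):
    active = select_active_space(h4_scf, 4, 4)
    ham = fold_frozen_core(h4_scf, active)
    qubit = jordan_wigner_hamiltonian(ham)
    ci = solve_casci(ham)
    return h4_scf, active, ham, qubit, ci


@pytest.fixture(scope="session")
def ch5_scf():
    return fixture_scf("ch5_1.3")


def random_number_conserving_state(n_qubits, n_particles, rng, real=False):
    """Haar-ish random state supported on a fixed-particle-number sector.

    ``real=True`` restricts to real amplitudes (the family produced by the
    real-generator ansätze, for which the spatial spin-sum is real).
    """
    dim = 2 ** n_qubits
    idxs = [b for b in range(dim) if bin(b).count("1") == n_particles]
    amps = rng.normal(size=len(idxs)).astype(complex)
    if not real:
        amps = amps + 1j * rng.normal(size=len(idxs))
    amps /= np.linalg.norm(amps)
    psi = np.zeros(dim, dtype=complex)
    psi[idxs] = amps
    return psi


def dense_annihilation(n_qubits, p):
    """Ladder-operator matrix built directly by kron products (oracle)."""
    A = np.array([[0.0, 1.0], [0.0, 0.0]])
    Z = np.diag([1.0, -1.0])
    I = np.eye(2)
    out = np.array([[1.0]])
    for q in range(n_qubits):
        out = np.kron(out, Z if q < p else (A if q == p else I))
    return out
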