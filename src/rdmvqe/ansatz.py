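"""Noiseless statevector simulation of the k-UpCCGSD and GateFabric ansätze.

Every gate is exp(θK) with K the real antisymmetric matrix of a fermionic
excitation generator (single, or paired double); K³ = −K, so gates are
applied in closed form

    exp(θK)|v⟩ = |v⟩ + sinθ K|v⟩ + (1 − cosθ) K²|v⟩

and dU/dθ = K U, which makes adjoint-mode gradients exact to machine
precision.  Both ansätze conserve particle number and S_z by construction.

Fixed conventions (they define the circuit, so they are frozen here):

* k-UpCCGSD layer ordering: generalized singles over spatial pairs (p, q),
  p < q, lexicographic, alpha then beta within a pair; then paired doubles
  p̄p → q̄q over the same lexicographic pairs.  Each of the k layers has its
  own parameters.
* GateFabric: brick-wall of 4-qubit tiles over neighboring spatial orbital
  pairs; per tile a paired DoubleExcitation(θ) followed by an
  OrbitalRotation(φ); no fixed Π block, so θ = 0 prepares exactly the HF
  reference.  Even layers tile orbitals (0,1), (2,3), …; odd layers (1,2),
  (3,4), …
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.sparse

from .hamiltonian import PauliSum, jw_annihilation, jw_creation
from .molecular_system import ActiveSpace


# ------------------------------------------------------------- generators
@lru_cache(maxsize=None)
def _single_excitation_generator(n_qubits: int, p: int, q: int):
    """K = a_p†a_q − a_q†a_p as a sparse real matrix (p, q spin orbitals)."""
    op = (jw_creation(n_qubits, p) * jw_annihilation(n_qubits, q)
          - jw_creation(n_qubits, q) * jw_annihilation(n_qubits, p))
    m = op.prune().to_matrix()
    if np.abs(m.imag).max() > 1e-12:
        raise AssertionError("single-excitation generator must be real")
    return scipy.sparse.csr_matrix(m.real)


@lru_cache(maxsize=None)
def _paired_double_generator(n_qubits: int, p: int, q: int):
    """K for the paired double p̄p → q̄q (spatial p → spatial q)."""
    pa, pb, qa, qb = 2 * p, 2 * p + 1, 2 * q, 2 * q + 1
    exc = (jw_creation(n_qubits, qa) * jw_creation(n_qubits, qb)
           * jw_annihilation(n_qubits, pb) * jw_annihilation(n_qubits, pa))
    dag = (jw_creation(n_qubits, pa) * jw_creation(n_qubits, pb)
           * jw_annihilation(n_qubits, qb) * jw_annihilation(n_qubits, qa))
    m = (exc - dag).prune().to_matrix()
    if np.abs(m.imag).max() > 1e-12:
        raise AssertionError("paired-double generator must be real")
    return scipy.sparse.csr_matrix(m.real)


@dataclass(frozen=True)
class Gate:
    """One rotation exp(θK); ``param_index`` = −1 marks a fixed angle."""

    label: str
    generator: scipy.sparse.csr_matrix
    generator_sq: scipy.sparse.csr_matrix
    param_index: int
    fixed_angle: float = 0.0

    def angle(self, theta: np.ndarray) -> float:
        if self.param_index < 0:
            return self.fixed_angle
        return theta[self.param_index]

    def apply(self, theta: float, v: np.ndarray) -> np.ndarray:
        return (v + np.sin(theta) * (self.generator @ v)
                + (1.0 - np.cos(theta)) * (self.generator_sq @ v))

    def apply_dagger(self, theta: float, v: np.ndarray) -> np.ndarray:
        return self.apply(-theta, v)


def _make_gate(label: str, K: scipy.sparse.csr_matrix, idx: int,
               fixed_angle: float = 0.0) -> Gate:
    return Gate(label, K, (K @ K).tocsr(), idx, fixed_angle)


@dataclass
class AnsatzCircuit:
    kind: str
    n_qubits: int
    layers: int
    parameter_count: int
    gates: list[Gate]
    reference_index: int          # basis index of the HF bitstring
    n_electrons: int

    def reference_state(self) -> np.ndarray:
        psi = np.zeros(2 ** self.n_qubits, dtype=complex)
        psi[self.reference_index] = 1.0
        return psi

    def to_gate_json(self) -> str:
        return json.dumps([{"gate": g.label, "param": g.param_index}
                           for g in self.gates], indent=1)


# ---------------------------------------------------------------- builders
def hf_reference_state(active: ActiveSpace) -> np.ndarray:
    """|1…10…0⟩: the lowest n_active_electrons interleaved SOs occupied."""
    nq = active.n_qubits
    ne = active.n_active_electrons
    if ne > nq:
        raise ValueError("more electrons than spin-orbitals")
    psi = np.zeros(2 ** nq, dtype=complex)
    psi[_hf_index(nq, ne)] = 1.0
    return psi


def _hf_index(n_qubits: int, n_electrons: int) -> int:
    idx = 0
    for q in range(n_electrons):
        idx |= 1 << (n_qubits - 1 - q)
    return idx


def build_kupccgsd(active: ActiveSpace, k: int = 1) -> AnsatzCircuit:
    if k < 1:
        raise ValueError("k must be >= 1")
    nq = active.n_qubits
    n_orb = active.n_active_orbitals
    pairs = [(p, q) for p in range(n_orb) for q in range(p + 1, n_orb)]
    gates: list[Gate] = []
    idx = 0
    for _layer in range(k):
        for (p, q) in pairs:
            for spin, tag in ((0, "a"), (1, "b")):
                K = _single_excitation_generator(nq, 2 * p + spin,
                                                 2 * q + spin)
                gates.append(_make_gate(f"gs({p}{tag}->{q}{tag})", K, idx))
                idx += 1
        for (p, q) in pairs:
            K = _paired_double_generator(nq, p, q)
            gates.append(_make_gate(f"pd({p}{p}->{q}{q})", K, idx))
            idx += 1
    return AnsatzCircuit("kupccgsd", nq, k, idx, gates,
                         _hf_index(nq, active.n_active_electrons),
                         active.n_active_electrons)


def build_gatefabric(active: ActiveSpace, layers: int,
                     include_pi: bool = False) -> AnsatzCircuit:
    """Brick-wall GateFabric; ``include_pi`` prepends the fixed Π block
    (orbital rotation by π/2 in the exp(θK) convention, i.e. a full Givens
    swap of the tile's orbital pair) to every tile, in which case θ = 0 no
    longer prepares the bare HF reference."""
    nq = active.n_qubits
    if nq < 4 or nq % 2:
        raise ValueError("GateFabric needs an even number of qubits, >= 4")
    if layers < 1:
        raise ValueError("layers must be >= 1")
    n_orb = nq // 2
    gates: list[Gate] = []
    idx = 0
    for layer in range(layers):
        start = 0 if layer % 2 == 0 else 1
        tiles = list(range(start, n_orb - 1, 2))
        if not tiles:          # 2 spatial orbitals: every layer is one tile
            tiles = [0]
        for p in tiles:
            q = p + 1
            Ka = _single_excitation_generator(nq, 2 * p, 2 * q)
            Kb = _single_excitation_generator(nq, 2 * p + 1, 2 * q + 1)
            if include_pi:
                gates.append(_make_gate(f"L{layer}:pi_a({p},{q})", Ka, -1,
                                        np.pi / 2))
                gates.append(_make_gate(f"L{layer}:pi_b({p},{q})", Kb, -1,
                                        np.pi / 2))
            Kd = _paired_double_generator(nq, p, q)
            gates.append(_make_gate(f"L{layer}:dbl({p},{q})", Kd, idx))
            idx += 1
            # orbital rotation: same-angle alpha and beta Givens rotations
            gates.append(_make_gate(f"L{layer}:orb_a({p},{q})", Ka, idx))
            gates.append(_make_gate(f"L{layer}:orb_b({p},{q})", Kb, idx))
            idx += 1
    return AnsatzCircuit("gatefabric", nq, layers, idx, gates,
                         _hf_index(nq, active.n_active_electrons),
                         active.n_active_electrons)


# --------------------------------------------------------------- execution
def prepare_state(circuit: AnsatzCircuit, theta: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (circuit.parameter_count,):
        raise ValueError(
            f"expected {circuit.parameter_count} parameters, got {theta.shape}")
    psi = circuit.reference_state()
    for gate in circuit.gates:
        psi = gate.apply(gate.angle(theta), psi)
    return psi


def expectation_and_gradient(circuit: AnsatzCircuit, theta: np.ndarray,
                             observable: np.ndarray):
    """⟨ψ(θ)|O|ψ(θ)⟩ and its exact gradient by adjoint differentiation.

    ``observable`` is a dense Hermitian matrix.  Multiple gates may share a
    parameter (GateFabric orbital rotations); their contributions add.
    """
    theta = np.asarray(theta, dtype=float)
    psi = prepare_state(circuit, theta)
    lam = observable @ psi
    value = float(np.real(np.vdot(psi, lam)))
    grad = np.zeros(circuit.parameter_count)
    for gate in reversed(circuit.gates):
        t = gate.angle(theta)
        if gate.param_index >= 0:
            grad[gate.param_index] += 2.0 * np.real(
                np.vdot(lam, gate.generator @ psi))
        psi = gate.apply_dagger(t, psi)
        lam = gate.apply_dagger(t, lam)
    return value, grad


def energy_and_gradient(circuit: AnsatzCircuit, theta: np.ndarray,
                        hamiltonian) -> tuple[float, np.ndarray]:
    """E(θ) = ⟨Ψ(θ)|H|Ψ(θ)⟩ and ∇E for a :class:`PauliSum` or dense H."""
    H = (hamiltonian.to_matrix() if isinstance(hamiltonian, PauliSum)
         else np.asarray(hamiltonian))
    return expectation_and_gradient(circuit, theta, H)
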