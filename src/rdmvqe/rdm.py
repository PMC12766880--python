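"""Measuring, assembling, and embedding the one-particle RDM.

The active-space 1-RDM D_pq = ⟨Ψ|a_p†a_q|Ψ⟩ is recovered from Hermitian
Pauli observables only: diagonals from (I − ⟨Z_p⟩)/2, off-diagonal real and
imaginary parts from the (X_pX_q + Y_pY_q)/4 and (X_pY_q − Y_pX_q)/4
combinations (with JW Z-strings in between), and the lower triangle by
Hermitian conjugation.  The spin-summed spatial matrix is then embedded
into the Hartree–Fock density of the full molecule: frozen occupied MOs
keep occupation 2, the active block is replaced by the measured matrix, and
the result is transformed MO → AO.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .hamiltonian import jw_excitation_operator, pauli_expectation
from .molecular_system import ActiveSpace, SCFReference


@lru_cache(maxsize=None)
def _excitation_observables(n_qubits: int):
    obs = {}
    for p in range(n_qubits):
        for q in range(p, n_qubits):
            obs[(p, q)] = jw_excitation_operator(n_qubits, p, q)
    return obs


def measure_active_rdm(state: np.ndarray) -> np.ndarray:
    """Hermitian D over active spin-orbitals from Pauli expectations."""
    dim = len(state)
    n_qubits = int(round(np.log2(dim)))
    if 2 ** n_qubits != dim:
        raise ValueError("state length is not a power of two")
    if abs(np.linalg.norm(state) - 1.0) > 1e-8:
        raise ValueError("state is not normalized")
    obs = _excitation_observables(n_qubits)
    d = np.zeros((n_qubits, n_qubits), dtype=complex)
    for p in range(n_qubits):
        for q in range(p, n_qubits):
            real_op, imag_op = obs[(p, q)]
            re = pauli_expectation(state, real_op)
            im = pauli_expectation(state, imag_op) if len(imag_op) else 0.0
            d[p, q] = re + 1j * im
            if p != q:
                d[q, p] = d[p, q].conjugate()
    return d


def spin_sum(d: np.ndarray, imag_tol: float = 1e-8) -> np.ndarray:
    """Spatial D_pq = D[pα,qα] + D[pβ,qβ] (interleaved spin-orbitals).

    The αβ cross-blocks are never read.  A residual imaginary part above
    ``imag_tol`` signals a state outside the real-representable family both
    ansätze generate and raises.
    """
    nso = d.shape[0]
    if nso % 2:
        raise ValueError("spin-orbital RDM must have even dimension")
    n = nso // 2
    out = d[0::2, 0::2] + d[1::2, 1::2]
    resid = float(np.abs(out.imag).max()) if np.iscomplexobj(out) else 0.0
    if resid > imag_tol:
        raise ValueError(
            f"imaginary residue {resid:.2e} above tolerance {imag_tol:.0e}")
    return np.asarray(out.real if np.iscomplexobj(out) else out, dtype=float)


def embed_active_rdm(d_spatial: np.ndarray, scf: SCFReference,
                     active: ActiveSpace) -> np.ndarray:
    """Full-molecule AO density γ from an active-space spatial RDM.

    MO-basis assembly: 2 on the frozen-occupied diagonal, the measured
    block over the active window, zero elsewhere (no correlation is
    assigned to MOs outside the window); then γ = C D_MO Cᵀ.
    """
    n_act = active.n_active_orbitals
    if d_spatial.shape != (n_act, n_act):
        raise ValueError("active RDM dimension mismatch")
    d_mo = np.zeros((scf.n_mo, scf.n_mo))
    for i in active.frozen_occupied_indices:
        d_mo[i, i] = 2.0
    act = np.asarray(active.active_mo_indices)
    d_mo[np.ix_(act, act)] = d_spatial
    C = scf.mo_coefficients
    return C @ d_mo @ C.T


def hf_active_block(scf: SCFReference, active: ActiveSpace) -> np.ndarray:
    """The HF occupation pattern restricted to the active window."""
    nocc = scf.geometry.n_electrons // 2
    diag = [2.0 if p < nocc else 0.0 for p in active.active_mo_indices]
    return np.diag(diag)
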