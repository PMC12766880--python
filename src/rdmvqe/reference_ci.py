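"""Determinant-based CASCI: the internal reference for energies and 1-RDMs.

Determinants are pairs of occupation bitmasks (alpha, beta) over the active
spatial orbitals; bit ``p`` set means orbital ``p`` occupied.  The fermionic
ordering inside a determinant is the alpha block (ascending orbital) before
the beta block.  Matrix elements follow the Slater–Condon rules with
chemists' (pq|rs) integrals; FCI is CASCI with all orbitals active.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from .hamiltonian import ActiveSpaceHamiltonian


def _bits(mask: int) -> list[int]:
    out = []
    p = 0
    while mask:
        if mask & 1:
            out.append(p)
        mask >>= 1
        p += 1
    return out


def _popcount_between(mask: int, i: int, j: int) -> int:
    """Number of set bits strictly between positions i and j."""
    lo, hi = (i, j) if i < j else (j, i)
    seg = mask & (((1 << hi) - 1) ^ ((1 << (lo + 1)) - 1))
    return bin(seg).count("1")


def _single_sign(mask: int, i: int, a: int) -> float:
    """Phase of a_a† a_i acting on a determinant with occupation ``mask``."""
    return -1.0 if _popcount_between(mask, i, a) % 2 else 1.0


@dataclass(frozen=True)
class DeterminantBasis:
    """All (alpha, beta) occupation pairs with fixed N_alpha = N_beta."""

    n_orbitals: int
    n_alpha: int
    n_beta: int
    determinants: tuple[tuple[int, int], ...]

    @classmethod
    def build(cls, n_orbitals: int, n_electrons: int) -> "DeterminantBasis":
        if n_electrons % 2:
            raise ValueError("S_z = 0 sector requires an even electron count")
        na = nb = n_electrons // 2
        if na > n_orbitals:
            raise ValueError("more electrons than the active space can hold")
        strings = [sum(1 << p for p in occ)
                   for occ in combinations(range(n_orbitals), na)]
        strings.sort()
        dets = tuple((a, b) for a in strings for b in strings)
        return cls(n_orbitals, na, nb, dets)

    def __len__(self) -> int:
        return len(self.determinants)

    def index(self) -> dict[tuple[int, int], int]:
        return {d: i for i, d in enumerate(self.determinants)}


def _diagonal_element(ham, amask: int, bmask: int) -> float:
    h, g = ham.h_eff, ham.g
    occ_a, occ_b = _bits(amask), _bits(bmask)
    e = sum(h[p, p] for p in occ_a) + sum(h[p, p] for p in occ_b)
    for p, q in combinations(occ_a, 2):
        e += g[p, p, q, q] - g[p, q, q, p]
    for p, q in combinations(occ_b, 2):
        e += g[p, p, q, q] - g[p, q, q, p]
    for p in occ_a:
        for q in occ_b:
            e += g[p, p, q, q]
    return float(e)


def _single_element(ham, same_mask_other_spin, mask, i, a) -> float:
    """⟨D|H|D_{i→a}⟩ for a same-spin single excitation."""
    h, g = ham.h_eff, ham.g
    e = h[i, a]
    for j in _bits(mask & ~(1 << i)):
        e += g[i, a, j, j] - g[i, j, j, a]
    for j in _bits(same_mask_other_spin):
        e += g[i, a, j, j]
    return _single_sign(mask, i, a) * float(e)


def hamiltonian_matrix(ham: ActiveSpaceHamiltonian,
                       basis: DeterminantBasis) -> np.ndarray:
    """Dense CI Hamiltonian (electronic part only; e_core added by callers)."""
    dets = basis.determinants
    n = len(dets)
    g = ham.g
    H = np.zeros((n, n))
    for I in range(n):
        aI, bI = dets[I]
        H[I, I] = _diagonal_element(ham, aI, bI)
        for J in range(I + 1, n):
            aJ, bJ = dets[J]
            da, db = aI ^ aJ, bI ^ bJ
            na, nb = bin(da).count("1"), bin(db).count("1")
            if na + nb > 4:
                continue
            if na == 2 and nb == 0:
                i, a = _bits(da & aI)[0], _bits(da & aJ)[0]
                H[I, J] = _single_element(ham, bI, aI, i, a)
            elif na == 0 and nb == 2:
                i, a = _bits(db & bI)[0], _bits(db & bJ)[0]
                H[I, J] = _single_element(ham, aI, bI, i, a)
            elif na == 2 and nb == 2:
                i, a = _bits(da & aI)[0], _bits(da & aJ)[0]
                j, b = _bits(db & bI)[0], _bits(db & bJ)[0]
                sign = _single_sign(aI, i, a) * _single_sign(bI, j, b)
                H[I, J] = sign * g[i, a, j, b]
            elif na == 4 and nb == 0:
                i, j = _bits(da & aI)
                a, b = _bits(da & aJ)
                sign = _single_sign(aI, i, a) * _single_sign(
                    (aI ^ (1 << i)) | (1 << a), j, b)
                H[I, J] = sign * (g[i, a, j, b] - g[i, b, j, a])
            elif na == 0 and nb == 4:
                i, j = _bits(db & bI)
                a, b = _bits(db & bJ)
                sign = _single_sign(bI, i, a) * _single_sign(
                    (bI ^ (1 << i)) | (1 << a), j, b)
                H[I, J] = sign * (g[i, a, j, b] - g[i, b, j, a])
            H[J, I] = H[I, J]
    return H


@dataclass
class CIResult:
    energy: float                 # total = electronic + e_core
    ci_vector: np.ndarray
    basis: DeterminantBasis
    one_rdm: np.ndarray           # spatial, spin-summed


def solve_casci(ham: ActiveSpaceHamiltonian,
                n_electrons: int | None = None,
                dense_cutoff: int = 2000) -> CIResult:
    """Lowest eigenpair of the active-space CI problem (S_z = 0 sector)."""
    if n_electrons is None:
        n_electrons = ham.n_electrons
    basis = DeterminantBasis.build(ham.n_orbitals, n_electrons)
    H = hamiltonian_matrix(ham, basis)
    n = len(basis)
    if n <= dense_cutoff:
        w, v = np.linalg.eigh(H)
        e0, c0 = w[0], v[:, 0]
    else:
        w, v = scipy.sparse.linalg.eigsh(
            scipy.sparse.csr_matrix(H), k=1, which="SA", tol=1e-12)
        e0, c0 = w[0], v[:, 0]
    c0 = c0 / np.linalg.norm(c0)
    if c0[np.argmax(np.abs(c0))] < 0:
        c0 = -c0
    rdm = ci_one_rdm_from_vector(basis, c0)
    return CIResult(energy=float(e0 + ham.e_core), ci_vector=c0,
                    basis=basis, one_rdm=rdm)


def ci_one_rdm_from_vector(basis: DeterminantBasis,
                           c: np.ndarray) -> np.ndarray:
    """Spin-summed spatial 1-RDM D_pq = ⟨Ψ|Σ_σ a_pσ† a_qσ|Ψ⟩."""
    n = basis.n_orbitals
    D = np.zeros((n, n))
    idx = basis.index()
    for I, (a, b) in enumerate(basis.determinants):
        cI = c[I]
        if cI == 0.0:
            continue
        for p in _bits(a):
            D[p, p] += cI * cI
        for p in _bits(b):
            D[p, p] += cI * cI
        # single excitations q -> p applied to |I>, overlapped with <J|
        for spin, mask, other in ((0, a, b), (1, b, a)):
            for q in _bits(mask):
                for p in range(n):
                    if p == q or (mask >> p) & 1:
                        continue
                    new = (mask ^ (1 << q)) | (1 << p)
                    key = (new, other) if spin == 0 else (other, new)
                    J = idx.get(key)
                    if J is None:
                        continue
                    D[p, q] += c[J] * cI * _single_sign(mask, q, p)
    return D


def ci_one_rdm(result: CIResult) -> np.ndarray:
    return result.one_rdm


def ci_statevector(basis: DeterminantBasis, c: np.ndarray) -> np.ndarray:
    """CI vector as a JW statevector (interleaved SOs, qubit 0 = MSB).

    The determinant's fermionic ordering (alpha block then beta block) is
    permuted to ascending interleaved spin-orbital order; the resulting
    permutation parity multiplies each amplitude.
    """
    n = basis.n_orbitals
    nq = 2 * n
    psi = np.zeros(2 ** nq, dtype=complex)
    for cI, (a, b) in zip(c, basis.determinants):
        if cI == 0.0:
            continue
        sos = [2 * p for p in _bits(a)] + [2 * p + 1 for p in _bits(b)]
        # parity of the permutation sorting `sos` ascending
        inv = sum(1 for i in range(len(sos)) for j in range(i + 1, len(sos))
                  if sos[i] > sos[j])
        sign = -1.0 if inv % 2 else 1.0
        index = 0
        for so in sos:
            index |= 1 << (nq - 1 - so)
        psi[index] += sign * cI
    return psi
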