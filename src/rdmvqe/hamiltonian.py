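"""Active-space Hamiltonians and the Jordan–Wigner qubit mapping.

Conventions (global for the package):

* spin-orbitals are interleaved, SO ``2p`` is the alpha and ``2p+1`` the
  beta component of spatial MO ``p``;
* qubit 0 is the leftmost tensor factor, i.e. the most significant bit of
  the computational-basis index;
* two-electron integrals are chemists' ``(pq|rs)`` throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

_PAULI_PROD = {
    ("I", "I"): (1.0, "I"), ("I", "X"): (1.0, "X"),
    ("I", "Y"): (1.0, "Y"), ("I", "Z"): (1.0, "Z"),
    ("X", "I"): (1.0, "X"), ("X", "X"): (1.0, "I"),
    ("X", "Y"): (1j, "Z"), ("X", "Z"): (-1j, "Y"),
    ("Y", "I"): (1.0, "Y"), ("Y", "X"): (-1j, "Z"),
    ("Y", "Y"): (1.0, "I"), ("Y", "Z"): (1j, "X"),
    ("Z", "I"): (1.0, "Z"), ("Z", "X"): (1j, "Y"),
    ("Z", "Y"): (-1j, "X"), ("Z", "Z"): (1.0, "I"),
}

_PAULI_MAT = {
    "I": np.eye(2, dtype=complex),
    "X": np.array([[0, 1], [1, 0]], dtype=complex),
    "Y": np.array([[0, -1j], [1j, 0]], dtype=complex),
    "Z": np.array([[1, 0], [0, -1]], dtype=complex),
}


class PauliSum:
    """Weighted sum of Pauli strings, Σ_j α_j P_j.

    Strings are words over {I, X, Y, Z} with one letter per qubit (qubit 0
    first).  Coefficients are kept complex internally; a Hermitian operator
    has real coefficients, which :meth:`real_coefficients` enforces.
    """

    def __init__(self, n_qubits: int, terms: dict[str, complex] | None = None):
        self.n_qubits = n_qubits
        self.terms: dict[str, complex] = dict(terms or {})

    # -- construction helpers ----------------------------------------------
    @classmethod
    def identity(cls, n_qubits: int, coeff: complex = 1.0) -> "PauliSum":
        return cls(n_qubits, {"I" * n_qubits: coeff})

    @classmethod
    def single(cls, n_qubits: int, pauli: str, qubit: int,
               coeff: complex = 1.0) -> "PauliSum":
        word = ["I"] * n_qubits
        word[qubit] = pauli
        return cls(n_qubits, {"".join(word): coeff})

    def copy(self) -> "PauliSum":
        return PauliSum(self.n_qubits, self.terms)

    # -- algebra -----------------------------------------------------------
    def __add__(self, other: "PauliSum") -> "PauliSum":
        out = dict(self.terms)
        for word, c in other.terms.items():
            out[word] = out.get(word, 0.0) + c
        return PauliSum(self.n_qubits, out)

    def __sub__(self, other: "PauliSum") -> "PauliSum":
        return self + (other * -1.0)

    def __mul__(self, other):
        if np.isscalar(other):
            return PauliSum(self.n_qubits,
                            {w: c * other for w, c in self.terms.items()})
        out: dict[str, complex] = {}
        for w1, c1 in self.terms.items():
            for w2, c2 in other.terms.items():
                phase = c1 * c2
                word = []
                for p1, p2 in zip(w1, w2):
                    ph, p = _PAULI_PROD[(p1, p2)]
                    phase *= ph
                    word.append(p)
                key = "".join(word)
                out[key] = out.get(key, 0.0) + phase
        return PauliSum(self.n_qubits, out)

    __rmul__ = __mul__

    def prune(self, tol: float = 1e-12) -> "PauliSum":
        return PauliSum(self.n_qubits,
                        {w: c for w, c in self.terms.items() if abs(c) > tol})

    def real_coefficients(self, tol: float = 1e-10) -> "PauliSum":
        bad = max((abs(c.imag) for c in self.terms.values()), default=0.0)
        if bad > tol:
            raise ValueError(f"non-Hermitian operator: imag residue {bad:.2e}")
        return PauliSum(self.n_qubits,
                        {w: c.real for w, c in self.terms.items()})

    @property
    def constant(self) -> complex:
        return self.terms.get("I" * self.n_qubits, 0.0)

    # -- realization -------------------------------------------------------
    def to_matrix(self) -> np.ndarray:
        dim = 2 ** self.n_qubits
        out = np.zeros((dim, dim), dtype=complex)
        for word, c in self.terms.items():
            m = np.array([[1.0]], dtype=complex)
            for p in word:
                m = np.kron(m, _PAULI_MAT[p])
            out += c * m
        return out

    def __len__(self) -> int:
        return len(self.terms)

    def __repr__(self) -> str:
        return f"PauliSum(n_qubits={self.n_qubits}, n_terms={len(self.terms)})"


def apply_pauli_word(state: np.ndarray, word: str) -> np.ndarray:
    """P|ψ⟩ for one Pauli word on a dense statevector (qubit 0 = MSB)."""
    n = len(word)
    psi = np.asarray(state, dtype=complex).reshape((2,) * n)
    for q, p in enumerate(word):
        if p == "I":
            continue
        psi = np.moveaxis(psi, q, 0)
        if p == "X":
            psi = psi[::-1]
        elif p == "Y":
            psi = psi[::-1].copy()
            psi[0] *= -1j
            psi[1] *= 1j
        else:  # Z
            psi = psi.copy()
            psi[1] *= -1
        psi = np.moveaxis(psi, 0, q)
    return psi.reshape(-1)


def apply_pauli_sum(state: np.ndarray, op: PauliSum) -> np.ndarray:
    out = np.zeros(len(state), dtype=complex)
    for word, c in op.terms.items():
        out += c * apply_pauli_word(state, word)
    return out


def pauli_expectation(state: np.ndarray, op: PauliSum) -> float:
    """⟨ψ|O|ψ⟩ for Hermitian O; raises if a sizable imaginary part appears."""
    if len(state) != 2 ** op.n_qubits:
        raise ValueError("state / operator dimension mismatch")
    val = complex(np.vdot(state, apply_pauli_sum(state, op)))
    if abs(val.imag) > 1e-10 * max(1.0, abs(val.real)):
        raise ValueError(f"expectation has imaginary part {val.imag:.2e}")
    return val.real


# --------------------------------------------------------------- JW ladder
def jw_annihilation(n_qubits: int, p: int) -> PauliSum:
    """JW image of a_p: ½(X_p + iY_p) ⊗ Z_0…Z_{p-1}."""
    word_x = ["Z"] * p + ["X"] + ["I"] * (n_qubits - p - 1)
    word_y = ["Z"] * p + ["Y"] + ["I"] * (n_qubits - p - 1)
    return PauliSum(n_qubits, {"".join(word_x): 0.5, "".join(word_y): 0.5j})


def jw_creation(n_qubits: int, p: int) -> PauliSum:
    """JW image of a_p†: ½(X_p − iY_p) ⊗ Z_0…Z_{p-1}."""
    word_x = ["Z"] * p + ["X"] + ["I"] * (n_qubits - p - 1)
    word_y = ["Z"] * p + ["Y"] + ["I"] * (n_qubits - p - 1)
    return PauliSum(n_qubits, {"".join(word_x): 0.5, "".join(word_y): -0.5j})


def jw_excitation_operator(n_qubits: int, p: int, q: int):
    """Hermitian operator pair measuring Re[D_pq] and Im[D_pq], p ≤ q.

    For p = q the real part is the number operator (I − Z_p)/2 and the
    imaginary part is zero.  For p < q the real part is
    ½(a_p†a_q + a_q†a_p) = ¼(X_pX_q + Y_pY_q)·Z-string and the imaginary
    part ½i⁻¹(a_p†a_q − a_q†a_p) = ¼(X_pY_q − Y_pX_q)·Z-string.
    """
    if p > q:
        raise ValueError("requires p <= q")
    if p == q:
        real = (PauliSum.identity(n_qubits, 0.5)
                + PauliSum.single(n_qubits, "Z", p, -0.5))
        return real, PauliSum(n_qubits)
    upper = jw_creation(n_qubits, p) * jw_annihilation(n_qubits, q)
    lower = jw_creation(n_qubits, q) * jw_annihilation(n_qubits, p)
    real = ((upper + lower) * 0.5).prune().real_coefficients()
    imag = ((upper - lower) * (-0.5j)).prune().real_coefficients()
    return real, imag


# ------------------------------------------------------ active Hamiltonian
@dataclass
class ActiveSpaceHamiltonian:
    """Folded second-quantized Hamiltonian over active spatial MOs."""

    h_eff: np.ndarray   # (n_act, n_act), Hartree
    g: np.ndarray       # (pq|rs) over active MOs
    e_core: float       # nuclear repulsion + frozen-shell energy
    n_electrons: int    # active electrons

    @property
    def n_orbitals(self) -> int:
        return self.h_eff.shape[0]

    @property
    def n_qubits(self) -> int:
        return 2 * self.n_orbitals

    def validate(self, tol: float = 1e-10) -> None:
        if not np.allclose(self.h_eff, self.h_eff.T, atol=tol):
            raise ValueError("h_eff not symmetric")
        g = self.g
        for perm in [(1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)]:
            if not np.allclose(g, g.transpose(perm), atol=tol):
                raise ValueError("g lacks 8-fold permutational symmetry")

    def hf_energy(self) -> float:
        """⟨HF|H|D⟩ + e_core for the aufbau closed-shell determinant."""
        nocc = self.n_electrons // 2
        e = 2.0 * np.trace(self.h_eff[:nocc, :nocc]) + self.e_core
        for i in range(nocc):
            for j in range(nocc):
                e += 2.0 * self.g[i, i, j, j] - self.g[i, j, j, i]
        return float(e)


def fold_frozen_core(scf, active) -> ActiveSpaceHamiltonian:
    """Fold frozen doubly-occupied MOs into an active-space Hamiltonian.

    Inactive-Fock folding: h_eff_pq = h_pq + Σ_i [2(pq|ii) − (pi|iq)] and
    e_core = E_nuc + Σ_i 2 h_ii + Σ_ij [2(ii|jj) − (ij|ji)], sums over the
    frozen occupied MOs i, j.
    """
    act = list(active.active_mo_indices)
    frz = list(active.frozen_occupied_indices)
    if set(act) & set(frz):
        raise ValueError("active and frozen MO sets overlap")
    h_mo = scf.mo_one_electron()
    g_mo = scf.mo_eri()
    e_core = scf.nuclear_repulsion
    for i in frz:
        e_core += 2.0 * h_mo[i, i]
        for j in frz:
            e_core += 2.0 * g_mo[i, i, j, j] - g_mo[i, j, j, i]
    h_eff = h_mo[np.ix_(act, act)].copy()
    for a, p in enumerate(act):
        for b, q in enumerate(act):
            for i in frz:
                h_eff[a, b] += 2.0 * g_mo[p, q, i, i] - g_mo[p, i, i, q]
    g_act = g_mo[np.ix_(act, act, act, act)].copy()
    ham = ActiveSpaceHamiltonian(h_eff=h_eff, g=g_act, e_core=float(e_core),
                                 n_electrons=active.n_active_electrons)
    ham.validate()
    return ham


def spin_orbital_integrals(ham: ActiveSpaceHamiltonian):
    """Interleaved spin-orbital h and (PQ|RS) from spatial integrals."""
    n = ham.n_orbitals
    nso = 2 * n
    h = np.zeros((nso, nso))
    g = np.zeros((nso, nso, nso, nso))
    for P in range(nso):
        for Q in range(nso):
            if P % 2 == Q % 2:
                h[P, Q] = ham.h_eff[P // 2, Q // 2]
    for P in range(nso):
        for Q in range(nso):
            if P % 2 != Q % 2:
                continue
            for R in range(nso):
                for S in range(nso):
                    if R % 2 != S % 2:
                        continue
                    g[P, Q, R, S] = ham.g[P // 2, Q // 2, R // 2, S // 2]
    return h, g


def jordan_wigner_hamiltonian(ham: ActiveSpaceHamiltonian) -> PauliSum:
    """Qubit Hamiltonian Σ_j α_j P_j of the folded active-space problem."""
    nso = ham.n_qubits
    h, g = spin_orbital_integrals(ham)
    out = PauliSum.identity(nso, ham.e_core)
    cre = [jw_creation(nso, p) for p in range(nso)]
    ann = [jw_annihilation(nso, p) for p in range(nso)]
    for P in range(nso):
        for Q in range(nso):
            if h[P, Q] != 0.0:
                out = out + (cre[P] * ann[Q]) * h[P, Q]
    # ½ Σ (PQ|RS) a_P† a_R† a_S a_Q  (chemists' convention)
    for P in range(nso):
        for Q in range(nso):
            if P % 2 != Q % 2:
                continue
            for R in range(nso):
                for S in range(nso):
                    if R % 2 != S % 2:
                        continue
                    coeff = 0.5 * g[P, Q, R, S]
                    if coeff == 0.0:
                        continue
                    term = cre[P] * cre[R] * ann[S] * ann[Q]
                    out = out + term * coeff
    return out.prune().real_coefficients()


# ------------------------------------------------------------ FCIDUMP I/O
def write_fcidump(ham: ActiveSpaceHamiltonian, path, tol: float = 1e-16):
    """Standard FCIDUMP (namelist header, 8-fold-unique integral records)."""
    n = ham.n_orbitals
    with open(path, "w") as fh:
        fh.write(f"&FCI NORB={n}, NELEC={ham.n_electrons}, MS2=0,\n")
        fh.write("  ORBSYM=" + "1," * n + "\n  ISYM=1,\n&END\n")
        for p in range(n):
            for q in range(p + 1):
                pq = p * (p + 1) // 2 + q
                for r in range(p + 1):
                    for s in range(r + 1):
                        rs = r * (r + 1) // 2 + s
                        if rs > pq:
                            continue
                        v = ham.g[p, q, r, s]
                        if abs(v) > tol:
                            fh.write(f"{v:23.16e} {p+1:3d} {q+1:3d} "
                                     f"{r+1:3d} {s+1:3d}\n")
        for p in range(n):
            for q in range(p + 1):
                v = ham.h_eff[p, q]
                if abs(v) > tol:
                    fh.write(f"{v:23.16e} {p+1:3d} {q+1:3d}   0   0\n")
        fh.write(f"{ham.e_core:23.16e}   0   0   0   0\n")


def read_fcidump(path) -> ActiveSpaceHamiltonian:
    text = open(path).read()
    header, _, body = text.partition("&END")
    norb = int(re.search(r"NORB\s*=\s*(\d+)", header).group(1))
    nelec = int(re.search(r"NELEC\s*=\s*(\d+)", header).group(1))
    h = np.zeros((norb, norb))
    g = np.zeros((norb, norb, norb, norb))
    e_core = 0.0
    for line in body.strip().splitlines():
        parts = line.split()
        if len(parts) != 5:
            continue
        v = float(parts[0])
        p, q, r, s = (int(x) for x in parts[1:])
        if p == q == r == s == 0:
            e_core = v
        elif r == s == 0:
            h[p - 1, q - 1] = h[q - 1, p - 1] = v
        else:
            p, q, r, s = p - 1, q - 1, r - 1, s - 1
            for (a, b, c, d) in {(p, q, r, s), (q, p, r, s), (p, q, s, r),
                                 (q, p, s, r), (r, s, p, q), (s, r, p, q),
                                 (r, s, q, p), (s, r, q, p)}:
                g[a, b, c, d] = v
    return ActiveSpaceHamiltonian(h, g, e_core, nelec)
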