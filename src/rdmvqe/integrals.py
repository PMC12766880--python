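"""One- and two-electron integrals over contracted Gaussians.

McMurchie–Davidson scheme: Cartesian Gaussian products are expanded in
Hermite Gaussians (coefficients ``E``), Coulomb integrals use the Hermite
Coulomb recursion ``R`` built on the Boys function.  Adequate for s/p shells
of a minimal basis; everything is exact (no screening, no approximations).

All lengths are Bohr and all energies Hartree.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.special import gammainc, gamma


def boys(n: int, x: float) -> float:
    """Boys function F_n(x) = ∫₀¹ t^{2n} exp(-x t²) dt."""
    if x < 1e-12:
        return 1.0 / (2 * n + 1)
    return gamma(n + 0.5) * gammainc(n + 0.5, x) / (2.0 * x ** (n + 0.5))


def _boys_sequence(nmax: int, x: float) -> list[float]:
    """F_0..F_nmax by stable downward recursion from a single F_nmax."""
    out = [0.0] * (nmax + 1)
    out[nmax] = boys(nmax, x)
    if nmax:
        ex = math.exp(-x)
        for n in range(nmax, 0, -1):
            out[n - 1] = (2.0 * x * out[n] + ex) / (2 * n - 1)
    return out


@lru_cache(maxsize=200000)
def _E(i: int, j: int, t: int, Q: float, a: float, b: float) -> float:
    """Hermite expansion coefficient E_t^{ij} for a 1-D Gaussian pair."""
    p = a + b
    q = a * b / p
    if t < 0 or t > i + j:
        return 0.0
    if i == j == t == 0:
        return math.exp(-q * Q * Q)
    if j == 0:
        return (_E(i - 1, j, t - 1, Q, a, b) / (2 * p)
                - q * Q / a * _E(i - 1, j, t, Q, a, b)
                + (t + 1) * _E(i - 1, j, t + 1, Q, a, b))
    return (_E(i, j - 1, t - 1, Q, a, b) / (2 * p)
            + q * Q / b * _E(i, j - 1, t, Q, a, b)
            + (t + 1) * _E(i, j - 1, t + 1, Q, a, b))


def _R_table(Lmax: int, p: float, PC, dist2: float):
    """All Hermite Coulomb integrals R⁰_{tuv} with t+u+v <= Lmax.

    Returns a dict keyed by (t, u, v).  Built iteratively from one Boys
    sequence, filling auxiliary order n downward.
    """
    F = _boys_sequence(Lmax, p * dist2)
    X, Y, Z = PC
    R = {}
    for n in range(Lmax + 1):
        R[(n, 0, 0, 0)] = (-2.0 * p) ** n * F[n]
    for total in range(1, Lmax + 1):
        for t in range(total + 1):
            for u in range(total - t + 1):
                v = total - t - u
                for n in range(Lmax - total + 1):
                    if t > 0:
                        val = X * R[(n + 1, t - 1, u, v)]
                        if t > 1:
                            val += (t - 1) * R[(n + 1, t - 2, u, v)]
                    elif u > 0:
                        val = Y * R[(n + 1, t, u - 1, v)]
                        if u > 1:
                            val += (u - 1) * R[(n + 1, t, u - 2, v)]
                    else:
                        val = Z * R[(n + 1, t, u, v - 1)]
                        if v > 1:
                            val += (v - 1) * R[(n + 1, t, u, v - 2)]
                    R[(n, t, u, v)] = val
    return R


# ---------------------------------------------------------------- primitives
def primitive_overlap(a, lmn1, A, b, lmn2, B) -> float:
    p = a + b
    s = (np.pi / p) ** 1.5
    for ax in range(3):
        s *= _E(lmn1[ax], lmn2[ax], 0, A[ax] - B[ax], a, b)
    return s


def primitive_kinetic(a, lmn1, A, b, lmn2, B) -> float:
    l2, m2, n2 = lmn2

    def ov(dl, dm, dn):
        new = (l2 + dl, m2 + dm, n2 + dn)
        if min(new) < 0:
            return 0.0
        return primitive_overlap(a, lmn1, A, b, new, B)

    term0 = b * (2 * (l2 + m2 + n2) + 3) * ov(0, 0, 0)
    term1 = -2.0 * b * b * (ov(2, 0, 0) + ov(0, 2, 0) + ov(0, 0, 2))
    term2 = -0.5 * (l2 * (l2 - 1) * ov(-2, 0, 0)
                    + m2 * (m2 - 1) * ov(0, -2, 0)
                    + n2 * (n2 - 1) * ov(0, 0, -2))
    return term0 + term1 + term2


def primitive_nuclear(a, lmn1, A, b, lmn2, B, C) -> float:
    """⟨a| 1/|r-C| |b⟩ for primitives (positive magnitude; caller adds -Z)."""
    p = a + b
    P = (a * np.asarray(A) + b * np.asarray(B)) / p
    PC = P - np.asarray(C)
    dist2 = float(PC @ PC)
    Lmax = sum(lmn1) + sum(lmn2)
    R = _R_table(Lmax, p, (PC[0], PC[1], PC[2]), dist2)
    val = 0.0
    for t in range(lmn1[0] + lmn2[0] + 1):
        Et = _E(lmn1[0], lmn2[0], t, A[0] - B[0], a, b)
        for u in range(lmn1[1] + lmn2[1] + 1):
            Eu = _E(lmn1[1], lmn2[1], u, A[1] - B[1], a, b)
            for v in range(lmn1[2] + lmn2[2] + 1):
                Ev = _E(lmn1[2], lmn2[2], v, A[2] - B[2], a, b)
                val += Et * Eu * Ev * R[(0, t, u, v)]
    return 2.0 * np.pi / p * val


def primitive_eri(a, lmn1, A, b, lmn2, B, c, lmn3, C, d, lmn4, D) -> float:
    """(ab|cd) in chemists' notation for four primitives."""
    p = a + b
    q = c + d
    alpha = p * q / (p + q)
    Px = (a * A[0] + b * B[0]) / p
    Py = (a * A[1] + b * B[1]) / p
    Pz = (a * A[2] + b * B[2]) / p
    Qx = (c * C[0] + d * D[0]) / q
    Qy = (c * C[1] + d * D[1]) / q
    Qz = (c * C[2] + d * D[2]) / q
    PQ = (Px - Qx, Py - Qy, Pz - Qz)
    dist2 = PQ[0] * PQ[0] + PQ[1] * PQ[1] + PQ[2] * PQ[2]
    E1 = [[_E(lmn1[ax], lmn2[ax], t, A[ax] - B[ax], a, b)
           for t in range(lmn1[ax] + lmn2[ax] + 1)] for ax in range(3)]
    E2 = [[_E(lmn3[ax], lmn4[ax], t, C[ax] - D[ax], c, d)
           for t in range(lmn3[ax] + lmn4[ax] + 1)] for ax in range(3)]
    Lmax = sum(lmn1) + sum(lmn2) + sum(lmn3) + sum(lmn4)
    R = _R_table(Lmax, alpha, PQ, dist2)
    val = 0.0
    for t, Et in enumerate(E1[0]):
        for u, Eu in enumerate(E1[1]):
            for v, Ev in enumerate(E1[2]):
                w1 = Et * Eu * Ev
                if w1 == 0.0:
                    continue
                for tau, Ft in enumerate(E2[0]):
                    for nu, Fu in enumerate(E2[1]):
                        for phi, Fv in enumerate(E2[2]):
                            w2 = Ft * Fu * Fv
                            if w2 == 0.0:
                                continue
                            sign = -1.0 if (tau + nu + phi) % 2 else 1.0
                            val += w1 * w2 * sign * R[
                                (0, t + tau, u + nu, v + phi)]
    return val * 2.0 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))


def primitive_dipole(a, lmn1, A, b, lmn2, B, axis: int, origin) -> float:
    """⟨a| (r_axis - origin_axis) |b⟩ via angular-momentum raising on B."""
    raised = list(lmn2)
    raised[axis] += 1
    s_raised = primitive_overlap(a, lmn1, A, b, tuple(raised), B)
    s_plain = primitive_overlap(a, lmn1, A, b, lmn2, B)
    return s_raised + (B[axis] - origin[axis]) * s_plain


# --------------------------------------------------------------- contracted
def _contract2(f, ao1, ao2, *extra):
    val = 0.0
    for c1, a1 in zip(ao1.coefficients, ao1.exponents):
        for c2, a2 in zip(ao2.coefficients, ao2.exponents):
            val += c1 * c2 * f(a1, ao1.lmn, ao1.center,
                               a2, ao2.lmn, ao2.center, *extra)
    return val


def overlap_matrix(basis) -> np.ndarray:
    n = basis.n_ao
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            S[i, j] = S[j, i] = _contract2(
                primitive_overlap, basis.aos[i], basis.aos[j])
    return S


def kinetic_matrix(basis) -> np.ndarray:
    n = basis.n_ao
    T = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            T[i, j] = _contract2(primitive_kinetic, basis.aos[i], basis.aos[j])
    return 0.5 * (T + T.T)


def nuclear_attraction_matrix(basis, charges, centers) -> np.ndarray:
    """Σ_A (-Z_A) ⟨μ| 1/|r-R_A| |ν⟩."""
    n = basis.n_ao
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            v = 0.0
            for Z, C in zip(charges, centers):
                v -= Z * _contract2(primitive_nuclear,
                                    basis.aos[i], basis.aos[j], C)
            V[i, j] = V[j, i] = v
    return V


def point_potential_matrix(basis, point) -> np.ndarray:
    """⟨μ| 1/|r-c| |ν⟩ for an arbitrary point (ESP electronic term)."""
    n = basis.n_ao
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            V[i, j] = V[j, i] = _contract2(
                primitive_nuclear, basis.aos[i], basis.aos[j], np.asarray(point))
    return V


def dipole_matrices(basis, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Three (n_ao, n_ao) matrices of ⟨μ| r_k - o_k |ν⟩."""
    n = basis.n_ao
    origin = np.asarray(origin, float)
    D = np.zeros((3, n, n))
    for k in range(3):
        for i in range(n):
            for j in range(i, n):
                D[k, i, j] = D[k, j, i] = _contract2(
                    primitive_dipole, basis.aos[i], basis.aos[j], k, origin)
    return D


# Optional numba acceleration of the ERI tensor; the pure-python path below
# is the reference and is used whenever numba is unavailable.
try:
    from ._eri_kernel import eri_tensor_packed as _eri_tensor_packed
except Exception:  # pragma: no cover - numba present in supported envs
    _eri_tensor_packed = None


def _eri_tensor_python(basis) -> np.ndarray:
    n = basis.n_ao
    eri = np.zeros((n, n, n, n))
    for i in range(n):
        for j in range(i + 1):
            ij = i * (i + 1) // 2 + j
            for k in range(n):
                for l in range(k + 1):
                    kl = k * (k + 1) // 2 + l
                    if ij < kl:
                        continue
                    ao_i, ao_j = basis.aos[i], basis.aos[j]
                    ao_k, ao_l = basis.aos[k], basis.aos[l]
                    val = 0.0
                    for c1, a1 in zip(ao_i.coefficients, ao_i.exponents):
                        for c2, a2 in zip(ao_j.coefficients, ao_j.exponents):
                            for c3, a3 in zip(ao_k.coefficients, ao_k.exponents):
                                for c4, a4 in zip(ao_l.coefficients, ao_l.exponents):
                                    val += c1 * c2 * c3 * c4 * primitive_eri(
                                        a1, ao_i.lmn, ao_i.center,
                                        a2, ao_j.lmn, ao_j.center,
                                        a3, ao_k.lmn, ao_k.center,
                                        a4, ao_l.lmn, ao_l.center)
                    for (p, q, r, s) in {(i, j, k, l), (j, i, k, l),
                                         (i, j, l, k), (j, i, l, k),
                                         (k, l, i, j), (l, k, i, j),
                                         (k, l, j, i), (l, k, j, i)}:
                        eri[p, q, r, s] = val
    return eri


def eri_tensor(basis) -> np.ndarray:
    """Full (μν|λσ) tensor, chemists' convention, 8-fold symmetry exploited."""
    if _eri_tensor_packed is None:
        return _eri_tensor_python(basis)
    n = basis.n_ao
    nprim = max(len(ao.exponents) for ao in basis.aos)
    exps = np.zeros((n, nprim))
    coefs = np.zeros((n, nprim))
    centers = np.zeros((n, 3))
    lmn = np.zeros((n, 3), dtype=np.int64)
    counts = np.zeros(n, dtype=np.int64)
    for i, ao in enumerate(basis.aos):
        m = len(ao.exponents)
        counts[i] = m
        exps[i, :m] = ao.exponents
        coefs[i, :m] = ao.coefficients
        centers[i] = ao.center
        lmn[i] = ao.lmn
    return _eri_tensor_packed(exps, coefs, centers, lmn, counts)


def nuclear_repulsion(charges, centers) -> float:
    e = 0.0
    centers = np.asarray(centers, float)
    for i in range(len(charges)):
        for j in range(i + 1, len(charges)):
            e += charges[i] * charges[j] / np.linalg.norm(
                centers[i] - centers[j])
    return float(e)
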