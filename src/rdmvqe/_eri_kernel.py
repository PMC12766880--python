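"""Numba-compiled two-electron-integral kernel.

Same McMurchie–Davidson formulation as :mod:`rdmvqe.integrals`; only the
inner loops are compiled.  The pure-python implementation there remains the
reference and is cross-checked in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _boys_seq(nmax: int, x: float, out: np.ndarray) -> None:
    """F_0..F_nmax into ``out`` (stable for all x)."""
    if x < 1e-12:
        for n in range(nmax + 1):
            out[n] = 1.0 / (2 * n + 1)
        return
    if x > 35.0:
        # asymptotic F_0 then upward recursion (stable at large x)
        out[0] = 0.5 * math.sqrt(math.pi / x) * math.erf(math.sqrt(x))
        ex = math.exp(-x)
        for n in range(nmax):
            out[n + 1] = ((2 * n + 1) * out[n] - ex) / (2.0 * x)
        return
    # series for F_m at m = nmax, then downward recursion (stable at small x)
    m = nmax
    term = 1.0 / (2 * m + 1)
    s = term
    k = 1
    while term > 1e-17 * s:
        term *= 2.0 * x / (2 * m + 2 * k + 1)
        s += term
        k += 1
    ex = math.exp(-x)
    out[m] = ex * s
    for n in range(m, 0, -1):
        out[n - 1] = (2.0 * x * out[n] + ex) / (2 * n - 1)


@njit(cache=True)
def _e_table(la: int, lb: int, Q: float, a: float, b: float) -> np.ndarray:
    """Hermite coefficients E[i, j, t] for one Cartesian direction."""
    p = a + b
    q = a * b / p
    E = np.zeros((la + 1, lb + 1, la + lb + 2))
    E[0, 0, 0] = math.exp(-q * Q * Q)
    for i in range(la):
        for t in range(i + 2):
            val = 0.0
            if t > 0:
                val += E[i, 0, t - 1] / (2.0 * p)
            val -= q * Q / a * E[i, 0, t]
            val += (t + 1) * E[i, 0, t + 1]
            E[i + 1, 0, t] = val
    for i in range(la + 1):
        for j in range(lb):
            for t in range(i + j + 2):
                val = 0.0
                if t > 0:
                    val += E[i, j, t - 1] / (2.0 * p)
                val += q * Q / b * E[i, j, t]
                val += (t + 1) * E[i, j, t + 1]
                E[i, j + 1, t] = val
    return E


@njit(cache=True)
def _r_table(Lmax: int, p: float, X: float, Y: float, Z: float,
             dist2: float) -> np.ndarray:
    """Hermite Coulomb integrals R⁰_{tuv}; index [t, u, v]."""
    F = np.zeros(Lmax + 1)
    _boys_seq(Lmax, p * dist2, F)
    R = np.zeros((Lmax + 1, Lmax + 1, Lmax + 1, Lmax + 1))
    for n in range(Lmax + 1):
        R[n, 0, 0, 0] = (-2.0 * p) ** n * F[n]
    for total in range(1, Lmax + 1):
        for t in range(total + 1):
            for u in range(total - t + 1):
                v = total - t - u
                for n in range(Lmax - total + 1):
                    if t > 0:
                        val = X * R[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * R[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = Y * R[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * R[n + 1, t, u - 2, v]
                    else:
                        val = Z * R[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * R[n + 1, t, u, v - 2]
                    R[n, t, u, v] = val
    return R[0]


@njit(cache=True)
def _prim_eri(a, la, A, b, lb, B, c, lc, C, d, ld, D) -> float:
    p = a + b
    q = c + d
    alpha = p * q / (p + q)
    PQ = np.empty(3)
    for ax in range(3):
        PQ[ax] = (a * A[ax] + b * B[ax]) / p - (c * C[ax] + d * D[ax]) / q
    dist2 = PQ[0] ** 2 + PQ[1] ** 2 + PQ[2] ** 2
    E1x = _e_table(la[0], lb[0], A[0] - B[0], a, b)
    E1y = _e_table(la[1], lb[1], A[1] - B[1], a, b)
    E1z = _e_table(la[2], lb[2], A[2] - B[2], a, b)
    E2x = _e_table(lc[0], ld[0], C[0] - D[0], c, d)
    E2y = _e_table(lc[1], ld[1], C[1] - D[1], c, d)
    E2z = _e_table(lc[2], ld[2], C[2] - D[2], c, d)
    Lmax = (la[0] + la[1] + la[2] + lb[0] + lb[1] + lb[2]
            + lc[0] + lc[1] + lc[2] + ld[0] + ld[1] + ld[2])
    R = _r_table(Lmax, alpha, PQ[0], PQ[1], PQ[2], dist2)
    val = 0.0
    for t in range(la[0] + lb[0] + 1):
        for u in range(la[1] + lb[1] + 1):
            for v in range(la[2] + lb[2] + 1):
                w1 = (E1x[la[0], lb[0], t] * E1y[la[1], lb[1], u]
                      * E1z[la[2], lb[2], v])
                if w1 == 0.0:
                    continue
                for tau in range(lc[0] + ld[0] + 1):
                    for nu in range(lc[1] + ld[1] + 1):
                        for ph in range(lc[2] + ld[2] + 1):
                            w2 = (E2x[lc[0], ld[0], tau]
                                  * E2y[lc[1], ld[1], nu]
                                  * E2z[lc[2], ld[2], ph])
                            if w2 == 0.0:
                                continue
                            sign = -1.0 if (tau + nu + ph) % 2 else 1.0
                            val += w1 * w2 * sign * R[t + tau, u + nu, v + ph]
    return val * 2.0 * math.pi ** 2.5 / (p * q * math.sqrt(p + q))


@njit(cache=True)
def eri_tensor_packed(exps, coefs, centers, lmn, counts) -> np.ndarray:
    n = exps.shape[0]
    eri = np.zeros((n, n, n, n))
    for i in range(n):
        for j in range(i + 1):
            ij = i * (i + 1) // 2 + j
            for k in range(n):
                for l in range(k + 1):
                    kl = k * (k + 1) // 2 + l
                    if ij < kl:
                        continue
                    val = 0.0
                    for pi in range(counts[i]):
                        ci = coefs[i, pi]
                        for pj in range(counts[j]):
                            cj = coefs[j, pj]
                            for pk in range(counts[k]):
                                ck = coefs[k, pk]
                                for pl in range(counts[l]):
                                    cl = coefs[l, pl]
                                    val += ci * cj * ck * cl * _prim_eri(
                                        exps[i, pi], lmn[i], centers[i],
                                        exps[j, pj], lmn[j], centers[j],
                                        exps[k, pk], lmn[k], centers[k],
                                        exps[l, pl], lmn[l], centers[l])
                    eri[i, j, k, l] = val
                    eri[j, i, k, l] = val
                    eri[i, j, l, k] = val
                    eri[j, i, l, k] = val
                    eri[k, l, i, j] = val
                    eri[l, k, i, j] = val
                    eri[k, l, j, i] = val
                    eri[l, k, j, i] = val
    return eri
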