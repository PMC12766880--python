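"""Minimal Gaussian basis (STO-3G) and atomic-orbital evaluation.

Each atomic orbital is a contracted Cartesian Gaussian

    phi(r) = sum_k c_k N(a_k, l, m, n) (x-Ax)^l (y-Ay)^m (z-Az)^n exp(-a_k |r-A|^2)

with primitives normalized individually and the contraction renormalized so
that <phi|phi> = 1.  Only s and p shells are needed for H and C, but the
evaluation and normalization code is written for general Cartesian angular
momentum so second derivatives (density Hessians) come out of one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# STO-3G exponents / contraction coefficients (coefficients refer to
# normalized primitives).  Shells are (label, angmom, exponents, coeffs).
_STO3G = {
    "H": [
        ("1s", 0, [3.42525091, 0.62391373, 0.16885540],
         [0.15432897, 0.53532814, 0.44463454]),
    ],
    "C": [
        ("1s", 0, [71.6168370, 13.0450960, 3.5305122],
         [0.15432897, 0.53532814, 0.44463454]),
        ("2s", 0, [2.9412494, 0.6834831, 0.2222899],
         [-0.09996723, 0.39951283, 0.70011547]),
        ("2p", 1, [2.9412494, 0.6834831, 0.2222899],
         [0.15591627, 0.60768372, 0.39195739]),
    ],
}

_CART = {0: [(0, 0, 0)], 1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)]}


def _double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def primitive_norm(alpha: float, lmn: tuple[int, int, int]) -> float:
    l, m, n = lmn
    L = l + m + n
    num = (2.0 * alpha / np.pi) ** 0.75 * (4.0 * alpha) ** (L / 2.0)
    den = np.sqrt(float(_double_factorial(2 * l - 1)
                        * _double_factorial(2 * m - 1)
                        * _double_factorial(2 * n - 1)))
    return num / den


@dataclass
class ContractedGaussian:
    """One AO: a normalized contraction of Cartesian primitives."""

    center: np.ndarray          # Bohr
    lmn: tuple[int, int, int]
    exponents: np.ndarray
    coefficients: np.ndarray    # includes primitive norms after finalization
    atom_index: int
    label: str                  # e.g. "C 2px"

    def finalize(self) -> None:
        c = self.coefficients * np.array(
            [primitive_norm(a, self.lmn) for a in self.exponents])
        # renormalize the contracted function
        from .integrals import primitive_overlap
        s = 0.0
        for ca, aa in zip(c, self.exponents):
            for cb, ab in zip(c, self.exponents):
                s += ca * cb * primitive_overlap(
                    aa, self.lmn, self.center, ab, self.lmn, self.center)
        self.coefficients = c / np.sqrt(s)

    # ---- real-space evaluation -------------------------------------------
    def _poly_1d(self, t: np.ndarray, l: int, deriv: int) -> np.ndarray:
        """d^deriv/dt^deriv of t^l, elementwise (deriv in 0..2)."""
        if deriv == 0:
            return t ** l
        if deriv == 1:
            return l * t ** (l - 1) if l > 0 else np.zeros_like(t)
        if l > 1:
            return l * (l - 1) * t ** (l - 2)
        return np.zeros_like(t)

    def evaluate(self, points: np.ndarray, derivs: int = 0):
        """Value (and optionally gradient, Hessian) at ``points`` (n,3) Bohr.

        Returns ``val`` or ``(val, grad)`` or ``(val, grad, hess)`` where
        grad has shape (n,3) and hess (n,3,3).
        """
        pts = np.atleast_2d(points)
        d = pts - self.center
        r2 = np.einsum("ij,ij->i", d, d)
        n = pts.shape[0]
        val = np.zeros(n)
        grad = np.zeros((n, 3)) if derivs >= 1 else None
        hess = np.zeros((n, 3, 3)) if derivs >= 2 else None
        lmn = self.lmn
        for c, a in zip(self.coefficients, self.exponents):
            e = c * np.exp(-a * r2)
            # per-axis factor f_i(t) = t^l_i * exp part handled globally; the
            # exponential couples axes only through the radial prefactor, so
            # work with g_i(t) = t^{l_i} e^{-a t^2} per axis.
            f = []
            for ax in range(3):
                t = d[:, ax]
                l = lmn[ax]
                f0 = t ** l
                row = [f0]
                if derivs >= 1:
                    f1 = self._poly_1d(t, l, 1) - 2.0 * a * t ** (l + 1)
                    row.append(f1)
                if derivs >= 2:
                    f2 = (self._poly_1d(t, l, 2)
                          - 2.0 * a * (2 * l + 1) * t ** l
                          + 4.0 * a * a * t ** (l + 2))
                    row.append(f2)
                f.append(row)
            # recombine with the full 3-D exponential split per axis:
            # phi = c * prod_i t_i^{l_i} * exp(-a r^2); the per-axis "rows"
            # above already include exp derivatives via the t^{l+1} terms
            # because exp(-a r^2) factorizes as prod exp(-a t_i^2).
            g = c * np.exp(-a * r2)
            p0 = f[0][0] * f[1][0] * f[2][0]
            val += g * p0
            if derivs >= 1:
                for ax in range(3):
                    parts = [f[i][1] if i == ax else f[i][0] for i in range(3)]
                    grad[:, ax] += g * parts[0] * parts[1] * parts[2]
            if derivs >= 2:
                for ax in range(3):
                    for ay in range(ax, 3):
                        parts = []
                        for i in range(3):
                            k = (1 if i in (ax, ay) else 0)
                            if ax == ay and i == ax:
                                k = 2
                            parts.append(f[i][k])
                        h = g * parts[0] * parts[1] * parts[2]
                        hess[:, ax, ay] += h
                        if ax != ay:
                            hess[:, ay, ax] += h
        if derivs == 0:
            return val
        if derivs == 1:
            return val, grad
        return val, grad, hess


@dataclass
class BasisSet:
    """Ordered AO list for a molecule; the single basis here is STO-3G."""

    aos: list[ContractedGaussian] = field(default_factory=list)

    @property
    def n_ao(self) -> int:
        return len(self.aos)

    def ao_atom_indices(self) -> np.ndarray:
        return np.array([ao.atom_index for ao in self.aos])

    def evaluate(self, points: np.ndarray, derivs: int = 0):
        """Stacked AO values: (n_ao, n_pts) [, (n_ao, n_pts, 3), ...]."""
        outs = [ao.evaluate(points, derivs) for ao in self.aos]
        if derivs == 0:
            return np.array(outs)
        return tuple(np.array([o[i] for o in outs]) for i in range(derivs + 1))


def build_basis(geometry, name: str = "sto-3g") -> BasisSet:
    """Construct the AO basis for a :class:`Geometry` (positions in Bohr)."""
    if name.lower() not in ("sto-3g", "sto3g"):
        raise ValueError(f"unsupported basis: {name!r}")
    basis = BasisSet()
    for ia, atom in enumerate(geometry.atoms):
        if atom.symbol not in _STO3G:
            raise ValueError(f"no STO-3G parameters for element {atom.symbol}")
        center = geometry.positions_bohr[ia]
        for shell_label, ang, exps, coefs in _STO3G[atom.symbol]:
            for lmn in _CART[ang]:
                suffix = {(1, 0, 0): "x", (0, 1, 0): "y", (0, 0, 1): "z"}.get(lmn, "")
                ao = ContractedGaussian(
                    center=np.asarray(center, float),
                    lmn=lmn,
                    exponents=np.asarray(exps, float),
                    coefficients=np.asarray(coefs, float),
                    atom_index=ia,
                    label=f"{atom.symbol}{ia + 1} {shell_label}{suffix}",
                )
                ao.finalize()
                basis.aos.append(ao)
    return basis
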