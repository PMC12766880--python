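"""Observables derived from the AO one-particle density matrix γ.

Electron density ρ(r) = Σ_μν γ_μν φ_μ(r) φ_ν(r) with analytic first and
second derivatives; electrostatic potential V(r) (nuclear point charges
minus the density Coulomb integral, evaluated exactly through
nuclear-attraction-type integrals); dipole moment; Mulliken populations;
and QTAIM-style critical points of ρ found by Newton iteration and
classified by the Hessian signature (NCP: three negative eigenvalues,
BCP: two negative and one positive).  Gaussian cube export/import for grids.

Atomic units throughout (Bohr, Hartree); dipoles also reported in Debye.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import integrals
from .molecular_system import AU_TO_DEBYE, Geometry

log = logging.getLogger(__name__)


# ------------------------------------------------------------------ fields
@dataclass(frozen=True)
class GridSpec:
    origin: np.ndarray       # Bohr
    axes: np.ndarray         # (3, 3) step vectors, Bohr
    counts: tuple[int, int, int]

    def __post_init__(self):
        if min(self.counts) < 2:
            raise ValueError("need at least 2 points per axis")
        if abs(np.linalg.det(self.axes)) < 1e-12:
            raise ValueError("degenerate grid axes")

    @classmethod
    def around(cls, geometry: Geometry, padding: float = 4.0,
               step: float = 0.10) -> "GridSpec":
        """Bounding box of the molecule padded by ``padding`` Bohr."""
        pos = geometry.positions_bohr
        lo = pos.min(axis=0) - padding
        hi = pos.max(axis=0) + padding
        counts = tuple(int(np.ceil((hi[k] - lo[k]) / step)) + 1
                       for k in range(3))
        return cls(origin=lo, axes=np.eye(3) * step, counts=counts)

    def points(self) -> np.ndarray:
        nx, ny, nz = self.counts
        idx = np.stack(np.meshgrid(np.arange(nx), np.arange(ny),
                                   np.arange(nz), indexing="ij"), axis=-1)
        return (self.origin + idx.reshape(-1, 3) @ self.axes)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.axes)))


@dataclass
class ScalarField:
    grid: GridSpec
    values: np.ndarray   # shape == grid.counts

    def __post_init__(self):
        if self.values.shape != tuple(self.grid.counts):
            raise ValueError("field shape does not match grid counts")


# ----------------------------------------------------------------- density
def density_at(gamma: np.ndarray, basis, points: np.ndarray,
               derivs: int = 0):
    """ρ (and optionally ∇ρ, Hessian of ρ) at arbitrary points (Bohr)."""
    pts = np.atleast_2d(np.asarray(points, float))
    if derivs == 0:
        ao = basis.evaluate(pts, 0)                    # (nao, npts)
        return np.einsum("mp,mn,np->p", ao, gamma, ao, optimize=True)
    if derivs == 1:
        ao, dao = basis.evaluate(pts, 1)
        rho = np.einsum("mp,mn,np->p", ao, gamma, ao, optimize=True)
        grad = 2.0 * np.einsum("mp,mn,npk->pk", ao, gamma, dao,
                               optimize=True)
        return rho, grad
    ao, dao, d2ao = basis.evaluate(pts, 2)
    rho = np.einsum("mp,mn,np->p", ao, gamma, ao, optimize=True)
    grad = 2.0 * np.einsum("mp,mn,npk->pk", ao, gamma, dao, optimize=True)
    hess = (2.0 * np.einsum("mpk,mn,npl->pkl", dao, gamma, dao,
                            optimize=True)
            + 2.0 * np.einsum("mp,mn,npkl->pkl", ao, gamma, d2ao,
                              optimize=True))
    return rho, grad, hess


def density_field(gamma: np.ndarray, basis, grid: GridSpec,
                  chunk: int = 20000) -> ScalarField:
    pts = grid.points()
    vals = np.empty(len(pts))
    for i in range(0, len(pts), chunk):
        vals[i:i + chunk] = density_at(gamma, basis, pts[i:i + chunk])
    return ScalarField(grid, vals.reshape(grid.counts))


# --------------------------------------------------------------------- ESP
def esp_at(gamma: np.ndarray, basis, geometry: Geometry,
           points: np.ndarray, nucleus_tol: float = 1e-6) -> np.ndarray:
    """V(r) = Σ_A Z_A/|r−R_A| − Σ_μν γ_μν ⟨μ|1/|r−r'||ν⟩, in Hartree/e.

    Points within ``nucleus_tol`` Bohr of a nucleus are masked to NaN.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    centers = geometry.positions_bohr
    charges = geometry.charges
    out = np.empty(len(pts))
    for i, r in enumerate(pts):
        dists = np.linalg.norm(centers - r, axis=1)
        if dists.min() < nucleus_tol:
            log.warning("ESP point within %.1e Bohr of a nucleus; masked",
                        nucleus_tol)
            out[i] = np.nan
            continue
        v_nuc = float(np.sum(charges / dists))
        v_el = float(np.einsum(
            "mn,mn->", gamma, integrals.point_potential_matrix(basis, r)))
        out[i] = v_nuc - v_el
    return out


def esp_field(gamma: np.ndarray, basis, geometry: Geometry,
              grid: GridSpec) -> ScalarField:
    vals = esp_at(gamma, basis, geometry, grid.points())
    return ScalarField(grid, vals.reshape(grid.counts))


# ------------------------------------------------------------------ dipole
def dipole_moment(gamma: np.ndarray, scf, origin=(0.0, 0.0, 0.0)):
    """μ_k = −Σ_μν γ_μν (ν|r_k|μ) + Σ_A Z_A R_Ak about ``origin`` (Bohr).

    Returns (vector a.u., magnitude a.u., magnitude Debye).
    """
    origin = np.asarray(origin, float)
    geometry = scf.geometry
    mu = np.zeros(3)
    for k in range(3):
        ints = scf.dipole_integrals[k] - origin[k] * scf.overlap
        mu[k] = -np.einsum("mn,mn->", gamma, ints)
    mu += (geometry.charges[:, None]
           * (geometry.positions_bohr - origin)).sum(axis=0)
    mag = float(np.linalg.norm(mu))
    return mu, mag, mag * AU_TO_DEBYE


# ---------------------------------------------------------------- Mulliken
def mulliken(gamma: np.ndarray, overlap: np.ndarray, basis,
             geometry: Geometry):
    """Per-atom populations P_A = Σ_{μ∈A} (γS)_μμ and charges Z_A − P_A.

    Returns (populations, charges, per-AO populations with labels).
    """
    gs_diag = np.einsum("mn,nm->m", gamma, overlap)
    atom_idx = basis.ao_atom_indices()
    pops = np.zeros(len(geometry.atoms))
    for mu, a in enumerate(atom_idx):
        pops[a] += gs_diag[mu]
    charges = geometry.charges - pops
    per_ao = [(ao.label, float(gs_diag[mu]))
              for mu, ao in enumerate(basis.aos)]
    return pops, charges, per_ao


# --------------------------------------------------------- critical points
@dataclass
class CriticalPoint:
    position: np.ndarray        # Bohr
    cp_type: str                # "NCP", "BCP", or "other"
    rho: float
    laplacian: float
    hessian_eigenvalues: np.ndarray   # ascending
    attached_atoms: tuple[str, ...]


def _classify(eigs: np.ndarray) -> str:
    neg = int(np.sum(eigs < 0))
    if neg == 3:
        return "NCP"
    if neg == 2:
        return "BCP"
    return "other"


def _trace_bond_path(gamma, basis, cp_position, direction, nuclei,
                     step: float = 0.05, max_steps: int = 1000):
    """Steepest-ascent path from a BCP toward its attractor nucleus."""
    x = cp_position + 0.05 * direction
    for _ in range(max_steps):
        d = np.linalg.norm(nuclei - x, axis=1)
        if d.min() < 0.15:
            return int(np.argmin(d))
        _, grad = density_at(gamma, basis, x[None, :], 1)
        g = grad[0]
        gn = np.linalg.norm(g)
        if gn < 1e-14:
            break
        x = x + step * g / gn
    d = np.linalg.norm(nuclei - x, axis=1)
    return int(np.argmin(d))


def find_critical_points(gamma: np.ndarray, basis, geometry: Geometry,
                         pair_cutoff: float = 4.5,
                         grad_tol: float = 1e-10,
                         dedup_tol: float = 1e-4,
                         rho_min: float = 1e-4,
                         max_newton: int = 80) -> list[CriticalPoint]:
    """Newton searches for ∇ρ = 0 seeded at nuclei and bonded midpoints.

    Seeds: every nucleus, plus the midpoint of every atom pair closer than
    ``pair_cutoff`` Bohr.  Converged roots (‖∇ρ‖ < grad_tol) are merged
    within ``dedup_tol`` Bohr, discarded when ρ < ``rho_min`` (far-field
    artifacts), and classified by the Hessian signature.  BCPs are attached
    to the two nuclei their bond path (steepest ascent along the positive
    Hessian eigenvector) terminates at.
    """
    nuclei = geometry.positions_bohr
    seeds = [p.copy() for p in nuclei]
    n_at = len(nuclei)
    for i in range(n_at):
        for j in range(i + 1, n_at):
            if np.linalg.norm(nuclei[i] - nuclei[j]) < pair_cutoff:
                seeds.append(0.5 * (nuclei[i] + nuclei[j]))
    roots = []
    for seed in seeds:
        x = seed.copy()
        ok = False
        for _ in range(max_newton):
            rho, grad, hess = density_at(gamma, basis, x[None, :], 2)
            g = grad[0]
            if np.linalg.norm(g) < grad_tol:
                ok = True
                break
            try:
                step = np.linalg.solve(hess[0], -g)
            except np.linalg.LinAlgError:
                break
            norm = np.linalg.norm(step)
            if norm > 0.5:       # trust region: density varies on ~a0 scale
                step *= 0.5 / norm
            x = x + step
        if not ok:
            log.debug("CP search from %s did not converge", seed)
            continue
        if any(np.linalg.norm(x - r) < dedup_tol for r in roots):
            continue
        roots.append(x)
    cps = []
    for x in roots:
        rho, grad, hess = density_at(gamma, basis, x[None, :], 2)
        if rho[0] < rho_min:
            continue
        eigs, vecs = np.linalg.eigh(hess[0])
        kind = _classify(eigs)
        if kind == "NCP":
            i = int(np.argmin(np.linalg.norm(nuclei - x, axis=1)))
            attached = (f"{geometry.atoms[i].symbol}{i + 1}",)
        elif kind == "BCP":
            v = vecs[:, 2]   # eigenvector of the single positive curvature
            ends = sorted(
                _trace_bond_path(gamma, basis, x, s * v, nuclei)
                for s in (+1.0, -1.0))
            attached = tuple(
                f"{geometry.atoms[i].symbol}{i + 1}" for i in ends)
        else:
            order = np.argsort(np.linalg.norm(nuclei - x, axis=1))
            attached = tuple(
                f"{geometry.atoms[i].symbol}{i + 1}"
                for i in sorted(order[:2]))
        cps.append(CriticalPoint(
            position=x, cp_type=kind, rho=float(rho[0]),
            laplacian=float(np.trace(hess[0])),
            hessian_eigenvalues=eigs, attached_atoms=attached))
    cps.sort(key=lambda c: (c.cp_type, c.attached_atoms))
    return cps


# ----------------------------------------------------------------- cube IO
def write_cube(field: ScalarField, geometry: Geometry, path,
               comment: str = "electron density") -> None:
    """Standard Gaussian cube layout (Bohr, z-fastest, six values/line)."""
    g = field.grid
    with open(path, "w") as fh:
        fh.write(f"{comment}\n")
        fh.write("generated by rdmvqe\n")
        ox, oy, oz = g.origin
        fh.write(f"{len(geometry.atoms):5d}{ox:12.6f}{oy:12.6f}{oz:12.6f}\n")
        for k in range(3):
            ax = g.axes[k]
            fh.write(f"{g.counts[k]:5d}{ax[0]:12.6f}{ax[1]:12.6f}"
                     f"{ax[2]:12.6f}\n")
        for atom, pos in zip(geometry.atoms, geometry.positions_bohr):
            fh.write(f"{atom.Z:5d}{float(atom.Z):12.6f}"
                     f"{pos[0]:12.6f}{pos[1]:12.6f}{pos[2]:12.6f}\n")
        flat = field.values.reshape(g.counts)
        for ix in range(g.counts[0]):
            for iy in range(g.counts[1]):
                row = flat[ix, iy, :]
                for start in range(0, len(row), 6):
                    chunk = row[start:start + 6]
                    fh.write("".join(f"{v:14.6e}" for v in chunk) + "\n")


def read_cube(path):
    """Read a cube file back; returns (ScalarField, Geometry)."""
    from .molecular_system import geometry_from_arrays

    with open(path) as fh:
        fh.readline()
        fh.readline()
        parts = fh.readline().split()
        natoms = int(parts[0])
        origin = np.array([float(x) for x in parts[1:4]])
        counts = []
        axes = []
        for _ in range(3):
            parts = fh.readline().split()
            counts.append(int(parts[0]))
            axes.append([float(x) for x in parts[1:4]])
        symbols, positions = [], []
        inv_z = {1: "H", 6: "C", 7: "N", 8: "O"}
        for _ in range(natoms):
            parts = fh.readline().split()
            symbols.append(inv_z[int(parts[0])])
            positions.append([float(x) for x in parts[2:5]])
        data = np.array(fh.read().split(), dtype=float)
    grid = GridSpec(origin=origin, axes=np.array(axes),
                    counts=tuple(counts))
    field = ScalarField(grid, data.reshape(grid.counts))
    pos_ang = np.array(positions) / (1.0 / 0.529177210903)
    geom = geometry_from_arrays(symbols, pos_ang, 0, 1)
    return field, geom
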