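"""Molecular geometries, restricted Hartree–Fock, and active-space selection.

Positions are Angstrom at the user surface and Bohr internally; energies are
always Hartree.  The SCF/integral layer acts as the "integral provider": the
rest of the package only ever touches the :class:`SCFReference` container, so
the variational/CI machinery is independent of how the integrals were made.
"""

from __future__ import annotations

import importlib.resources
import io
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

from . import integrals
from .basis import BasisSet, build_basis

log = logging.getLogger(__name__)

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
AU_TO_DEBYE = 2.541746473

_ELEMENT_Z = {"H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7,
              "O": 8, "F": 9, "Ne": 10}

#: dissociation coordinates (Angstrom) of the packaged CH5+ geometries
CH5_R_VALUES = (1.3, 1.4, 1.6, 1.8, 2.1)


@dataclass(frozen=True)
class Atom:
    symbol: str
    Z: int
    position: np.ndarray  # Angstrom


@dataclass
class Geometry:
    """A molecule: atoms (Angstrom), total charge, and spin multiplicity."""

    atoms: list[Atom]
    total_charge: int = 0
    multiplicity: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        for atom in self.atoms:
            if atom.Z < 1:
                raise ValueError("nuclear charge must be >= 1")
            if not np.all(np.isfinite(atom.position)):
                raise ValueError("non-finite atomic position")
        if self.n_electrons <= 0:
            raise ValueError("electron count must be positive")

    @property
    def n_electrons(self) -> int:
        return sum(a.Z for a in self.atoms) - self.total_charge

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.Z for a in self.atoms], dtype=float)

    @property
    def positions_angstrom(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def positions_bohr(self) -> np.ndarray:
        return self.positions_angstrom * BOHR_PER_ANGSTROM


def geometry_from_arrays(symbols, positions_angstrom, charge=0,
                         multiplicity=1, label="") -> Geometry:
    atoms = [Atom(s, _ELEMENT_Z[s], np.asarray(p, float))
             for s, p in zip(symbols, positions_angstrom)]
    return Geometry(atoms, charge, multiplicity, label)


# ------------------------------------------------------------------- XYZ IO
def read_xyz(source, charge: int = 0, multiplicity: int = 1) -> Geometry:
    """Read a standard two-header-line XYZ file (element symbols, Angstrom).

    Charge and multiplicity are supplied by the caller, not parsed from the
    comment line.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        label = Path(source).stem
    else:
        text = source.read()
        label = ""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    natoms = int(lines[0].split()[0])
    symbols, coords = [], []
    for ln in lines[2:2 + natoms]:
        parts = ln.split()
        symbols.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return geometry_from_arrays(symbols, coords, charge, multiplicity, label)


def write_xyz(geometry: Geometry, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(geometry.atoms)}\n{comment}\n")
        for a in geometry.atoms:
            x, y, z = a.position
            fh.write(f"{a.symbol} {x:18.12f} {y:18.12f} {z:18.12f}\n")


# -------------------------------------------------------- packaged CH5+ set
def ch5_geometry(R: float) -> Geometry:
    """Packaged CH5+ geometry at dissociation coordinate ``R`` (Angstrom).

    R is the distance from the carbon to the center of mass of the leaving
    H2 pair (atoms H3/H4); 1.3 A is the equilibrium-region value.  The
    packaged structures are synthetic stand-ins: Cs-symmetric geometries
    relaxed at frozen-core CISD/STO-3G with this package's own CI code under
    the constraint that the C-(H3H4 c.o.m.) distance equals R.
    """
    for known in CH5_R_VALUES:
        if abs(R - known) < 1e-9:
            fname = f"ch5_synthetic_R{known:.1f}.xyz"
            data = importlib.resources.files("rdmvqe.data").joinpath(fname)
            geom = read_xyz(io.StringIO(data.read_text()),
                            charge=1, multiplicity=1)
            geom.label = f"ch5+_R{known:.1f}"
            return geom
    raise KeyError(
        f"no packaged CH5+ geometry at R={R}; available: {CH5_R_VALUES}")


def ch5_dissociation_coordinate(geometry: Geometry) -> float:
    """Recompute R: carbon to center of mass of the H3/H4 pair (Angstrom)."""
    pos = geometry.positions_angstrom
    com = 0.5 * (pos[2] + pos[3])  # equal masses
    return float(np.linalg.norm(pos[0] - com))


# ----------------------------------------------------------------- RHF/SCF
class SCFConvergenceError(RuntimeError):
    def __init__(self, trace):
        super().__init__(f"SCF failed to converge in {len(trace)} iterations")
        self.trace = trace


@dataclass
class SCFReference:
    """Converged restricted HF data plus every integral the pipeline needs."""

    geometry: Geometry
    basis: BasisSet
    mo_coefficients: np.ndarray       # C[nu, p]
    overlap: np.ndarray
    core_hamiltonian: np.ndarray
    eri: np.ndarray                   # (mu nu|la si), chemists' convention
    dipole_integrals: np.ndarray      # (3, n_ao, n_ao), about coord. origin
    orbital_energies: np.ndarray
    hf_energy: float
    hf_density_ao: np.ndarray         # gamma^HF (trace with S = N_elec)
    nuclear_repulsion: float

    @property
    def n_ao(self) -> int:
        return self.overlap.shape[0]

    @property
    def n_mo(self) -> int:
        return self.mo_coefficients.shape[1]

    def mo_one_electron(self) -> np.ndarray:
        C = self.mo_coefficients
        return C.T @ self.core_hamiltonian @ C

    def mo_eri(self) -> np.ndarray:
        C = self.mo_coefficients
        return np.einsum("ap,bq,abcd,cr,ds->pqrs",
                         C, C, self.eri, C, C, optimize=True)

    def save(self, path) -> None:
        np.savez(path,
                 symbols=np.array([a.symbol for a in self.geometry.atoms]),
                 positions=self.geometry.positions_angstrom,
                 charge=self.geometry.total_charge,
                 multiplicity=self.geometry.multiplicity,
                 mo_coefficients=self.mo_coefficients,
                 overlap=self.overlap,
                 core_hamiltonian=self.core_hamiltonian,
                 eri=self.eri,
                 dipole_integrals=self.dipole_integrals,
                 orbital_energies=self.orbital_energies,
                 hf_energy=self.hf_energy,
                 hf_density_ao=self.hf_density_ao,
                 nuclear_repulsion=self.nuclear_repulsion)

    @classmethod
    def load(cls, path) -> "SCFReference":
        z = np.load(path, allow_pickle=False)
        geom = geometry_from_arrays([str(s) for s in z["symbols"]],
                                    z["positions"], int(z["charge"]),
                                    int(z["multiplicity"]))
        return cls(geometry=geom, basis=build_basis(geom),
                   mo_coefficients=z["mo_coefficients"],
                   overlap=z["overlap"],
                   core_hamiltonian=z["core_hamiltonian"], eri=z["eri"],
                   dipole_integrals=z["dipole_integrals"],
                   orbital_energies=z["orbital_energies"],
                   hf_energy=float(z["hf_energy"]),
                   hf_density_ao=z["hf_density_ao"],
                   nuclear_repulsion=float(z["nuclear_repulsion"]))


def run_scf(geometry: Geometry, basis: str = "sto-3g",
            conv_tol: float = 1e-11, max_cycles: int = 200) -> SCFReference:
    """Restricted Hartree–Fock with DIIS for a closed-shell molecule."""
    if geometry.multiplicity != 1:
        raise ValueError("restricted HF requires multiplicity 1")
    if geometry.n_electrons % 2:
        raise ValueError("restricted HF requires an even electron count")
    bset = build_basis(geometry, basis)
    S = integrals.overlap_matrix(bset)
    T = integrals.kinetic_matrix(bset)
    V = integrals.nuclear_attraction_matrix(
        bset, geometry.charges, geometry.positions_bohr)
    hcore = T + V
    eri = integrals.eri_tensor(bset)
    enuc = integrals.nuclear_repulsion(geometry.charges,
                                       geometry.positions_bohr)
    nocc = geometry.n_electrons // 2

    def fock(dm):
        J = np.einsum("uvls,ls->uv", eri, dm, optimize=True)
        K = np.einsum("ulvs,ls->uv", eri, dm, optimize=True)
        return hcore + J - 0.5 * K

    def density(C):
        Cocc = C[:, :nocc]
        return 2.0 * Cocc @ Cocc.T

    eps, C = scipy.linalg.eigh(hcore, S)
    dm = density(C)
    e_old = 0.0
    trace = []
    diis_F, diis_err = [], []
    for it in range(max_cycles):
        F = fock(dm)
        err = F @ dm @ S - S @ dm @ F
        diis_F.append(F)
        diis_err.append(err.ravel())
        if len(diis_F) > 8:
            diis_F.pop(0)
            diis_err.pop(0)
        if len(diis_F) > 1:
            m = len(diis_F)
            B = -np.ones((m + 1, m + 1))
            B[m, m] = 0.0
            for i in range(m):
                for j in range(m):
                    B[i, j] = diis_err[i] @ diis_err[j]
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                w = np.linalg.solve(B, rhs)[:m]
                F = sum(wi * Fi for wi, Fi in zip(w, diis_F))
            except np.linalg.LinAlgError:
                pass
        eps, C = scipy.linalg.eigh(F, S)
        dm = density(C)
        e_elec = 0.5 * np.einsum("uv,uv->", dm, hcore + fock(dm))
        e_tot = e_elec + enuc
        trace.append(e_tot)
        if it > 0 and abs(e_tot - e_old) < conv_tol:
            break
        e_old = e_tot
    else:
        raise SCFConvergenceError(trace)

    dip = integrals.dipole_matrices(bset)
    return SCFReference(geometry=geometry, basis=bset, mo_coefficients=C,
                        overlap=S, core_hamiltonian=hcore, eri=eri,
                        dipole_integrals=dip, orbital_energies=eps,
                        hf_energy=float(e_tot), hf_density_ao=dm,
                        nuclear_repulsion=enuc)


# ------------------------------------------------------------- active space
@dataclass(frozen=True)
class ActiveSpace:
    n_active_electrons: int
    n_active_orbitals: int
    active_mo_indices: tuple[int, ...]
    frozen_occupied_indices: tuple[int, ...]

    @property
    def n_qubits(self) -> int:
        return 2 * self.n_active_orbitals

    def __post_init__(self):
        if set(self.active_mo_indices) & set(self.frozen_occupied_indices):
            raise ValueError("active and frozen MO sets overlap")
        if self.n_active_electrons > 2 * self.n_active_orbitals:
            raise ValueError("more active electrons than active spin-orbitals")


def select_active_space(scf: SCFReference, n_electrons: int,
                        n_orbitals: int,
                        active_indices=None) -> ActiveSpace:
    """Frontier-window active space on canonical RHF orbitals.

    The window holds the n_electrons/2 highest occupied and the remaining
    lowest virtual canonical MOs; all lower occupied MOs are frozen at
    double occupation.  ``active_indices`` overrides the window explicitly.
    """
    if n_electrons % 2:
        raise ValueError("active electron count must be even (closed shell)")
    nocc = scf.geometry.n_electrons // 2
    if active_indices is not None:
        active = tuple(int(i) for i in active_indices)
        if len(active) != n_orbitals:
            raise ValueError("active_indices length must equal n_orbitals")
        frozen = tuple(i for i in range(nocc) if i not in active)
    else:
        n_act_occ = n_electrons // 2
        if n_act_occ > nocc or nocc - n_act_occ + n_orbitals > scf.n_mo:
            raise ValueError("active window does not fit in the MO list")
        first = nocc - n_act_occ
        active = tuple(range(first, first + n_orbitals))
        frozen = tuple(range(first))
        eps = scf.orbital_energies
        if first > 0 and abs(eps[first] - eps[first - 1]) < 1e-8:
            warnings.warn("degenerate orbitals at the frozen/active edge")
        top = first + n_orbitals
        if top < scf.n_mo and abs(eps[top] - eps[top - 1]) < 1e-8:
            warnings.warn("degenerate orbitals at the active/virtual edge")
    space = ActiveSpace(n_electrons, n_orbitals, active, frozen)
    if 2 * len(frozen) + n_electrons != scf.geometry.n_electrons:
        raise ValueError("frozen/active bookkeeping does not add up")
    return space
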