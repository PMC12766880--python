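"""The three optimization loops: VQE, VQE*, and VQE-LD.

All variants are deterministic full-batch gradient descent with a fixed
learning rate (initial parameters zero, so the first state is the HF
reference).  They differ in what convergence means and in what drives the
update:

* ``vqe``       — update along −∇E; stop when |ΔE| < E_tol.  The 1-RDM drift
  ΔD is recorded every iteration but not enforced.
* ``vqe_star``  — same updates; stop only when |ΔE| < E_tol and ΔD < D_tol
  hold on the same iteration.
* ``vqe_ld``    — minimizes L(θ) = E(θ) + w_D·ΔD(θ) with
  w_D = f·‖G_E‖/‖G_D‖, the previous iteration's 1-RDM held constant inside
  ΔD; stops under the same dual criterion.

ΔD is the RMSD between consecutive spin-summed active-space 1-RDMs,
normalized by the matrix dimension N (number of active spatial orbitals):
ΔD = sqrt(Σ_pq |D_pq(n) − D_pq(n−1)|² / N²).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .ansatz import AnsatzCircuit, expectation_and_gradient, prepare_state
from .hamiltonian import PauliSum, jw_annihilation, jw_creation
from .rdm import measure_active_rdm, spin_sum

log = logging.getLogger(__name__)

VARIANTS = ("vqe", "vqe_star", "vqe_ld")


@dataclass(frozen=True)
class ConvergenceSettings:
    e_tol: float = 1e-6
    d_tol: float = 1e-6
    learning_rate: float = 0.4
    f: float = 0.05
    max_iterations: int = 5000
    variant: str = "vqe"
    rdm_basis: str = "spatial"   # "spatial" or "spin_orbital" ΔD normalization

    def __post_init__(self):
        if self.e_tol <= 0 or self.d_tol <= 0 or self.learning_rate <= 0:
            raise ValueError("tolerances and learning rate must be positive")
        if self.f < 0:
            raise ValueError("f must be non-negative")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class IterationRecord:
    n: int
    energy: float
    delta_e: float | None
    delta_d: float | None
    w_d: float
    grad_e_norm: float
    grad_d_norm: float
    loss: float
    theta: np.ndarray


@dataclass
class VQEResult:
    final_theta: np.ndarray
    final_energy: float
    final_active_rdm: np.ndarray      # spin-orbital, Hermitian
    final_spatial_rdm: np.ndarray
    trajectory: list[IterationRecord]
    converged: bool
    steps: int
    variant: str


# ----------------------------------------------------------- ΔD machinery
def delta_d(d_now: np.ndarray, d_prev: np.ndarray) -> float:
    """RMSD between consecutive 1-RDMs, normalized by the dimension."""
    if d_now.shape != d_prev.shape:
        raise ValueError("RDM shape mismatch")
    n = d_now.shape[0]
    diff = d_now - d_prev
    return float(np.sqrt(np.sum(np.abs(diff) ** 2) / n ** 2))


def weight_wd(grad_e: np.ndarray, grad_d: np.ndarray, f: float) -> float:
    """w_D = f·‖G_E‖/‖G_D‖; zero when G_D vanishes (first iteration)."""
    nd = float(np.linalg.norm(grad_d))
    if nd == 0.0:
        return 0.0
    return f * float(np.linalg.norm(grad_e)) / nd


@lru_cache(maxsize=None)
def _spatial_transition_matrices(n_qubits: int):
    """Dense matrices of E_pq = Σ_σ a_pσ†a_qσ over active spatial MOs."""
    n = n_qubits // 2
    out = {}
    for p in range(n):
        for q in range(n):
            op = (jw_creation(n_qubits, 2 * p) * jw_annihilation(n_qubits, 2 * q)
                  + jw_creation(n_qubits, 2 * p + 1)
                  * jw_annihilation(n_qubits, 2 * q + 1))
            out[(p, q)] = op.prune().to_matrix()
    return out


def _measure_spatial(state: np.ndarray) -> np.ndarray:
    return spin_sum(measure_active_rdm(state))


def loss_and_gradient(circuit: AnsatzCircuit, theta: np.ndarray,
                      h_dense: np.ndarray, d_prev: np.ndarray | None,
                      f: float):
    """L, ∇L, and every diagnostic of one VQE-LD evaluation.

    ``d_prev`` (spatial RDM of the previous iteration) is a constant
    reference; the ΔD → 0 point is non-differentiable and its safeguarded
    subgradient is G_D = 0.

    Returns (loss, grad_loss, energy, delta_d, w_d, grad_e, grad_d, d_now).
    """
    energy, grad_e = expectation_and_gradient(circuit, theta, h_dense)
    state = prepare_state(circuit, theta)
    d_now = _measure_spatial(state)
    if d_prev is None:
        return (energy, grad_e, energy, None, 0.0, grad_e,
                np.zeros_like(grad_e), d_now)
    dd = delta_d(d_now, d_prev)
    if dd < 1e-14:
        grad_d = np.zeros_like(grad_e)
    else:
        n = d_now.shape[0]
        resid = d_now - d_prev
        mats = _spatial_transition_matrices(circuit.n_qubits)
        A = np.zeros_like(mats[(0, 0)])
        for p in range(n):
            for q in range(n):
                if resid[p, q] != 0.0:
                    A = A + np.conj(resid[p, q]) * mats[(p, q)]
        A = 0.5 * (A + A.conj().T)   # Hermitize against rounding
        _, grad_a = expectation_and_gradient(circuit, theta, A)
        grad_d = grad_a / (dd * d_now.shape[0] ** 2)
    wd = weight_wd(grad_e, grad_d, f)
    loss = energy + wd * dd
    grad_loss = grad_e + wd * grad_d
    return loss, grad_loss, energy, dd, wd, grad_e, grad_d, d_now


# -------------------------------------------------------------- main loop
def run(variant: str, circuit: AnsatzCircuit, hamiltonian,
        settings: ConvergenceSettings | None = None,
        theta0: np.ndarray | None = None) -> VQEResult:
    """Run one VQE variant to convergence (θ₀ = 0 unless overridden)."""
    if settings is None:
        settings = ConvergenceSettings(variant=variant)
    elif settings.variant != variant:
        settings = ConvergenceSettings(
            e_tol=settings.e_tol, d_tol=settings.d_tol,
            learning_rate=settings.learning_rate, f=settings.f,
            max_iterations=settings.max_iterations, variant=variant,
            rdm_basis=settings.rdm_basis)
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    h_dense = (hamiltonian.to_matrix() if isinstance(hamiltonian, PauliSum)
               else np.asarray(hamiltonian))
    theta = (np.zeros(circuit.parameter_count) if theta0 is None
             else np.array(theta0, dtype=float))

    use_spatial = settings.rdm_basis == "spatial"

    def measure(state):
        d_so = measure_active_rdm(state)
        return spin_sum(d_so) if use_spatial else d_so

    trajectory: list[IterationRecord] = []
    d_prev = None
    e_prev = None
    converged = False
    for n in range(settings.max_iterations + 1):
        if variant == "vqe_ld":
            (loss, grad_cost, energy, dd, wd,
             grad_e, grad_d, d_now) = loss_and_gradient(
                circuit, theta, h_dense, d_prev, settings.f)
            if not use_spatial:
                raise NotImplementedError(
                    "VQE-LD drives ΔD through the spatial RDM")
        else:
            energy, grad_e = expectation_and_gradient(circuit, theta, h_dense)
            d_now = measure(prepare_state(circuit, theta))
            dd = None if d_prev is None else delta_d(d_now, d_prev)
            wd = 0.0
            grad_d = np.zeros_like(grad_e)
            grad_cost = grad_e
            loss = energy
        de = None if e_prev is None else abs(energy - e_prev)

        trajectory.append(IterationRecord(
            n=n, energy=energy, delta_e=de, delta_d=dd, w_d=wd,
            grad_e_norm=float(np.linalg.norm(grad_e)),
            grad_d_norm=float(np.linalg.norm(grad_d)),
            loss=loss, theta=theta.copy()))
        log.debug("iter %d E=%.12f dE=%s dD=%s", n, energy, de, dd)

        if de is not None:
            if variant == "vqe":
                converged = de < settings.e_tol
            else:
                converged = (de < settings.e_tol
                             and dd is not None and dd < settings.d_tol)
            if converged:
                break
        theta = theta - settings.learning_rate * grad_cost
        d_prev = d_now
        e_prev = energy

    final_state = prepare_state(circuit, theta)
    d_so = measure_active_rdm(final_state)
    result = VQEResult(
        final_theta=theta, final_energy=trajectory[-1].energy,
        final_active_rdm=d_so, final_spatial_rdm=spin_sum(d_so),
        trajectory=trajectory, converged=converged,
        steps=trajectory[-1].n, variant=variant)
    log.info("%s: E=%.10f converged=%s steps=%d", variant,
             result.final_energy, converged, result.steps)
    return result
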