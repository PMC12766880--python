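"""Frozen-core folding, Jordan–Wigner mapping, and FCIDUMP round trips."""

import numpy as np
import pytest

from rdmvqe.hamiltonian import (ActiveSpaceHamiltonian, PauliSum,
                                fold_frozen_core, jordan_wigner_hamiltonian,
                                jw_annihilation, jw_creation,
                                jw_excitation_operator, pauli_expectation,
                                read_fcidump, write_fcidump)
from rdmvqe.molecular_system import ActiveSpace, select_active_space
from rdmvqe.reference_ci import solve_casci

from conftest import dense_annihilation


class TestPauliAlgebra:
    def test_product_phases(self):
        x = PauliSum.single(1, "X", 0)
        y = PauliSum.single(1, "Y", 0)
        z = PauliSum.single(1, "Z", 0)
        assert (x * y).terms == {"Z": 1j}
        assert (y * x).terms == {"Z": -1j}
        assert (x * x).terms == {"I": 1.0}
        assert np.allclose((x * y * z).to_matrix(), 1j * np.eye(2))

    def test_matrix_of_word_uses_qubit0_as_msb(self):
        zi = PauliSum(2, {"ZI": 1.0}).to_matrix()
        assert np.allclose(np.diag(zi), [1, 1, -1, -1])

    def test_expectations(self):
        zz = PauliSum(2, {"ZZ": 1.0})
        e00 = np.zeros(4, complex)
        e00[0] = 1.0
        assert pauli_expectation(e00, zz) == pytest.approx(1.0)
        plus = np.ones(2, complex) / np.sqrt(2)
        assert pauli_expectation(plus, PauliSum(1, {"X": 1.0})) == \
            pytest.approx(1.0)

    def test_random_expectation_matches_dense(self):
        rng = np.random.default_rng(11)
        n = 4
        words = ["IXYZ", "ZZII", "XXYY", "IIII", "YZXI"]
        op = PauliSum(n, {w: rng.normal() for w in words})
        psi = rng.normal(size=16) + 1j * rng.normal(size=16)
        psi /= np.linalg.norm(psi)
        dense = psi.conj() @ (op.to_matrix() @ psi)
        assert pauli_expectation(psi, op) == pytest.approx(dense.real,
                                                           abs=1e-12)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            pauli_expectation(np.ones(4) / 2.0, PauliSum(1, {"Z": 1.0}))


class TestJWLadder:
    @pytest.mark.parametrize("n", [2, 3])
    def test_anticommutation_relations(self, n):
        for p in range(n):
            for q in range(n):
                ap = jw_annihilation(n, p).to_matrix()
                aqd = jw_creation(n, q).to_matrix()
                acomm = ap @ aqd + aqd @ ap
                expected = np.eye(2 ** n) if p == q else 0.0
                assert np.abs(acomm - expected).max() < 1e-12

    def test_single_orbital_number_operator(self):
        """One spin-orbital with energy ε maps to ε(I − Z)/2."""
        ham = ActiveSpaceHamiltonian(
            h_eff=np.array([[0.7]]), g=np.zeros((1, 1, 1, 1)),
            e_core=0.0, n_electrons=0)
        # restrict to one spin-orbital by hand
        op = jw_creation(1, 0) * jw_annihilation(1, 0) * 0.7
        op = op.prune().real_coefficients()
        assert op.terms == pytest.approx({"I": 0.35, "Z": -0.35})
        del ham

    def test_excitation_observable_forms(self):
        real, imag = jw_excitation_operator(2, 0, 0)
        assert real.terms == pytest.approx({"II": 0.5, "ZI": -0.5})
        assert len(imag) == 0
        real01, imag01 = jw_excitation_operator(2, 0, 1)
        assert real01.terms == pytest.approx({"XX": 0.25, "YY": 0.25})
        assert imag01.terms == pytest.approx({"XY": 0.25, "YX": -0.25})

    def test_excitation_requires_ordered_indices(self):
        with pytest.raises(ValueError):
            jw_excitation_operator(2, 1, 0)

    def test_excitation_expectations_match_ladder_oracle(self):
        rng = np.random.default_rng(3)
        n = 3
        psi = rng.normal(size=8) + 1j * rng.normal(size=8)
        psi /= np.linalg.norm(psi)
        for p in range(n):
            for q in range(p, n):
                re_op, im_op = jw_excitation_operator(n, p, q)
                apd = dense_annihilation(n, p).T
                aq = dense_annihilation(n, q)
                exact = psi.conj() @ (apd @ aq @ psi)
                re = pauli_expectation(psi, re_op)
                im = pauli_expectation(psi, im_op) if len(im_op) else 0.0
                assert re + 1j * im == pytest.approx(exact, abs=1e-12)


class TestFolding:
    def test_no_frozen_orbitals_is_identity(self, h2_scf):
        act = select_active_space(h2_scf, 2, 2)
        ham = fold_frozen_core(h2_scf, act)
        assert np.allclose(ham.h_eff, h2_scf.mo_one_electron(), atol=1e-12)
        assert ham.e_core == pytest.approx(h2_scf.nuclear_repulsion)

    def test_hf_energy_recovered_from_folded_hamiltonian(self, ch5_scf):
        """⟨HF|H_eff|HF⟩ + e_core equals the full-molecule RHF energy."""
        for ne, no in [(2, 2), (4, 4), (6, 5)]:
            act = select_active_space(ch5_scf, ne, no)
            ham = fold_frozen_core(ch5_scf, act)
            assert ham.hf_energy() == pytest.approx(ch5_scf.hf_energy,
                                                    abs=1e-8)

    def test_core_energy_independent_of_frozen_ordering(self, ch5_scf):
        act = select_active_space(ch5_scf, 4, 4)
        shuffled = ActiveSpace(4, 4, act.active_mo_indices, (2, 0, 1))
        h1 = fold_frozen_core(ch5_scf, act)
        h2 = fold_frozen_core(ch5_scf, shuffled)
        assert h1.e_core == pytest.approx(h2.e_core, abs=1e-12)
        assert np.allclose(h1.h_eff, h2.h_eff, atol=1e-12)

    def test_folded_casci_matches_parent_energy(self, ch5_scf):
        """CASCI on the folded (4,4) problem is bounded by the parent HF
        energy and reproduces it when the active block stays at HF."""
        act = select_active_space(ch5_scf, 4, 4)
        ham = fold_frozen_core(ch5_scf, act)
        ci = solve_casci(ham)
        assert ci.energy < ch5_scf.hf_energy
        assert ci.energy > ch5_scf.hf_energy - 0.2


class TestJWHamiltonian:
    def test_coefficients_real(self, h2_problem):
        _, _, _, qubit, _ = h2_problem
        assert all(isinstance(c, float) or abs(np.imag(c)) < 1e-12
                   for c in qubit.terms.values())

    def test_dense_spectrum_matches_casci(self, h2_problem):
        _, _, ham, qubit, ci = h2_problem
        w = np.linalg.eigvalsh(qubit.to_matrix())
        assert w[0] == pytest.approx(ci.energy, abs=1e-10)

    def test_number_operator_commutes(self, h2_problem):
        _, _, _, qubit, _ = h2_problem
        n = qubit.n_qubits
        N = PauliSum(n)
        for p in range(n):
            N = N + PauliSum.identity(n, 0.5) + PauliSum.single(n, "Z", p,
                                                                -0.5)
        H = qubit.to_matrix()
        Nm = N.to_matrix()
        assert np.abs(H @ Nm - Nm @ H).max() < 1e-10

    def test_h4_dense_spectrum_matches_casci(self, h4_problem):
        _, _, ham, qubit, ci = h4_problem
        M = qubit.to_matrix()
        assert np.abs(M - M.conj().T).max() < 1e-10
        w = np.linalg.eigvalsh(M)
        assert w[0] == pytest.approx(ci.energy, abs=1e-9)


class TestFCIDUMP:
    def test_roundtrip_bit_identical(self, tmp_path, h4_problem):
        _, _, ham, _, _ = h4_problem
        path = tmp_path / "h4.fcidump"
        write_fcidump(ham, path)
        loaded = read_fcidump(path)
        assert loaded.n_electrons == ham.n_electrons
        # full 8-fold reconstruction from the unique records
        assert np.abs(loaded.h_eff - ham.h_eff).max() < 1e-14
        assert np.abs(loaded.g - ham.g).max() < 1e-14
        assert loaded.e_core == pytest.approx(ham.e_core, abs=1e-14)
        ci0 = solve_casci(ham)
        ci1 = solve_casci(loaded)
        assert ci1.energy == pytest.approx(ci0.energy, abs=1e-10)
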