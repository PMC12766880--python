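"""ΔD, w_D, the augmented loss, and the three optimization loops."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rdmvqe.ansatz import build_kupccgsd, prepare_state
from rdmvqe.optimizers import (ConvergenceSettings, delta_d,
                               loss_and_gradient, run, weight_wd)
from rdmvqe.rdm import measure_active_rdm, spin_sum


class TestDeltaD:
    def test_identical_matrices(self):
        d = np.random.default_rng(0).normal(size=(4, 4))
        assert delta_d(d, d) == 0.0

    def test_uniform_offset_equals_offset(self):
        d = np.zeros((3, 3))
        assert delta_d(d + 0.25, d) == pytest.approx(0.25, abs=1e-15)

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=(4, 4))
        a = 0.5 * (a + a.T)
        b = rng.normal(size=(4, 4))
        b = 0.5 * (b + b.T)
        acc = 0.0
        for p in range(4):
            for q in range(4):
                acc += abs(a[p, q] - b[p, q]) ** 2
        assert delta_d(a, b) == pytest.approx(np.sqrt(acc / 16), abs=1e-14)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            delta_d(np.zeros((2, 2)), np.zeros((3, 3)))

    @given(st.integers(2, 5), st.integers(0, 10 ** 6))
    @settings(max_examples=25, deadline=None)
    def test_nonnegative_and_symmetric_in_arguments(self, n, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, n, n))
        assert delta_d(a, b) >= 0.0
        assert delta_d(a, b) == pytest.approx(delta_d(b, a), abs=1e-15)


class TestWeightWd:
    def test_ratio_arithmetic(self):
        ge = np.array([2.0, 0.0])
        gd = np.array([0.0, 4.0])
        assert weight_wd(ge, gd, 0.05) == pytest.approx(0.025)

    def test_zero_density_gradient_gives_zero(self):
        assert weight_wd(np.ones(3), np.zeros(3), 0.5) == 0.0

    def test_f_zero_gives_zero(self):
        assert weight_wd(np.ones(3), np.ones(3), 0.0) == 0.0


class TestLossAndGradient:
    def test_fd_check_of_loss_gradient(self, h2_problem):
        _, active, _, qubit, _ = h2_problem
        circ = build_kupccgsd(active, k=1)
        H = qubit.to_matrix()
        rng = np.random.default_rng(31)
        th0 = rng.normal(size=3) * 0.4
        d_prev = spin_sum(measure_active_rdm(prepare_state(circ, th0)))
        th = th0 + 0.15   # ensure ΔD is well away from the singular point
        f = 0.3
        loss, grad, *_ = loss_and_gradient(circ, th, H, d_prev, f)
        # w_D is a frozen scale inside one iteration: differentiate
        # E + w_D·ΔD at fixed w_D, matching the update rule ∇L = G_E + w_D·G_D
        wd = loss_and_gradient(circ, th, H, d_prev, f)[4]
        h = 1e-6
        for i in range(3):
            e = np.eye(3)[i] * h

            def fixed_wd_loss(t):
                out = loss_and_gradient(circ, t, H, d_prev, f)
                return out[2] + wd * out[3]

            fd = (fixed_wd_loss(th + e) - fixed_wd_loss(th - e)) / (2 * h)
            assert grad[i] == pytest.approx(fd, abs=1e-6)

    def test_zero_f_reduces_to_energy(self, h2_problem):
        _, active, _, qubit, _ = h2_problem
        circ = build_kupccgsd(active, k=1)
        H = qubit.to_matrix()
        th = np.array([0.1, -0.2, 0.3])
        d_prev = np.diag([2.0, 0.0])
        loss, grad, energy, dd, wd, ge, gd, _ = loss_and_gradient(
            circ, th, H, d_prev, 0.0)
        assert wd == 0.0
        assert loss == energy
        assert np.array_equal(grad, ge)

    def test_delta_d_at_reference_point_is_safeguarded(self, h2_problem):
        _, active, _, qubit, _ = h2_problem
        circ = build_kupccgsd(active, k=1)
        H = qubit.to_matrix()
        th = np.array([0.2, 0.1, -0.3])
        d_prev = spin_sum(measure_active_rdm(prepare_state(circ, th)))
        loss, grad, energy, dd, wd, ge, gd, _ = loss_and_gradient(
            circ, th, H, d_prev, 0.5)
        assert dd < 1e-14
        assert np.array_equal(gd, np.zeros_like(ge))


class TestRunLoops:
    @pytest.mark.parametrize("variant", ["vqe", "vqe_star", "vqe_ld"])
    def test_h2_converges_to_casci(self, h2_problem, variant):
        _, active, _, qubit, ci = h2_problem
        circ = build_kupccgsd(active, k=1)
        res = run(variant, circ, qubit)
        assert res.converged
        assert res.final_energy == pytest.approx(ci.energy, abs=1e-6)
        assert res.final_energy >= ci.energy - 1e-9

    def test_first_iteration_is_hf_energy(self, h4_problem):
        _, active, ham, qubit, _ = h4_problem
        circ = build_kupccgsd(active, k=1)
        res = run("vqe", circ, qubit)
        assert res.trajectory[0].energy == pytest.approx(ham.hf_energy(),
                                                         abs=1e-10)

    def test_dual_exit_criterion_enforced(self, h4_problem):
        _, active, _, qubit, _ = h4_problem
        circ = build_kupccgsd(active, k=1)
        for variant in ("vqe_star", "vqe_ld"):
            res = run(variant, circ, qubit)
            last = res.trajectory[-1]
            assert res.converged
            assert last.delta_e < 1e-6
            assert last.delta_d < 1e-6

    def test_vqe_ld_with_f_zero_reproduces_vqe_trajectory_bitwise(
            self, h2_problem):
        _, active, _, qubit, _ = h2_problem
        circ = build_kupccgsd(active, k=1)
        plain = run("vqe", circ, qubit,
                    ConvergenceSettings(variant="vqe", max_iterations=40,
                                        e_tol=1e-30))
        ld = run("vqe_ld", circ, qubit,
                 ConvergenceSettings(variant="vqe_ld", f=0.0,
                                     max_iterations=40, e_tol=1e-30))
        for r1, r2 in zip(plain.trajectory, ld.trajectory):
            assert np.array_equal(r1.theta, r2.theta)
            assert r1.energy == r2.energy

    def test_determinism_bitwise(self, h2_problem):
        _, active, _, qubit, _ = h2_problem
        circ = build_kupccgsd(active, k=1)
        a = run("vqe_ld", circ, qubit)
        b = run("vqe_ld", circ, qubit)
        assert a.final_energy == b.final_energy
        assert np.array_equal(a.final_theta, b.final_theta)
        assert [r.energy for r in a.trajectory] == \
            [r.energy for r in b.trajectory]

    def test_max_iterations_flags_nonconvergence(self, h2_problem):
        _, active, _, qubit, _ = h2_problem
        circ = build_kupccgsd(active, k=1)
        res = run("vqe", circ, qubit,
                  ConvergenceSettings(variant="vqe", e_tol=1e-30,
                                      max_iterations=5))
        assert not res.converged
        assert res.steps == 5

    def test_energy_monotone_under_plain_descent(self, h4_problem):
        _, active, _, qubit, _ = h4_problem
        circ = build_kupccgsd(active, k=1)
        res = run("vqe", circ, qubit)
        energies = [r.energy for r in res.trajectory]
        increases = [b - a for a, b in zip(energies, energies[1:]) if b > a]
        assert not any(inc > 1e-9 for inc in increases)

    def test_natural_occupations_bounded_along_run(self, h4_problem):
        _, active, _, qubit, _ = h4_problem
        circ = build_kupccgsd(active, k=1)
        res = run("vqe_star", circ, qubit)
        eigs = np.linalg.eigvalsh(res.final_spatial_rdm)
        assert eigs.min() > -1e-9 and eigs.max() < 2 + 1e-9

    def test_unknown_variant_rejected(self, h2_problem):
        _, active, _, qubit, _ = h2_problem
        circ = build_kupccgsd(active, k=1)
        with pytest.raises(ValueError):
            run("adam", circ, qubit)
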