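"""Density, ESP, dipole, Mulliken, critical points, and cube I/O."""

import numpy as np
import pytest

from rdmvqe.basis import build_basis
from rdmvqe.molecular_system import (BOHR_PER_ANGSTROM, geometry_from_arrays,
                                     select_active_space)
from rdmvqe import properties as props
from rdmvqe.rdm import embed_active_rdm, hf_active_block


@pytest.fixture(scope="module")
def h_atom():
    geom = geometry_from_arrays(["H"], [[0, 0, 0]], 0, 2)
    basis = build_basis(geom)
    return geom, basis


@pytest.fixture(scope="module")
def h2_density(h2_scf):
    act = select_active_space(h2_scf, 2, 2)
    gamma = embed_active_rdm(hf_active_block(h2_scf, act), h2_scf, act)
    return h2_scf, gamma


class TestDensity:
    def test_single_s_orbital_density_normalizes(self, h_atom):
        """γ = [[1]] on one AO: ρ integrates to 1 and peaks at the center."""
        geom, basis = h_atom
        grid = props.GridSpec.around(geom, padding=6.0, step=0.1)
        field = props.density_field(np.array([[1.0]]), basis, grid)
        assert field.values.sum() * grid.voxel_volume == pytest.approx(
            1.0, abs=1e-3)
        center = props.density_at(np.array([[1.0]]), basis,
                                  np.zeros((1, 3)))[0]
        off = props.density_at(np.array([[1.0]]), basis,
                               np.array([[1.0, 0, 0]]))[0]
        assert center > off > 0

    def test_contracted_s_value_matches_direct_sum(self, h_atom):
        """ρ(r) for one AO equals |φ(r)|² from the raw contraction."""
        geom, basis = h_atom
        ao = basis.aos[0]
        r = np.array([[0.3, -0.2, 0.5]])
        phi = sum(c * np.exp(-a * np.sum(r[0] ** 2))
                  for c, a in zip(ao.coefficients, ao.exponents))
        rho = props.density_at(np.array([[1.0]]), basis, r)[0]
        assert rho == pytest.approx(phi ** 2, rel=1e-12)

    def test_h2_density_integrates_to_two(self, h2_density):
        scf, gamma = h2_density
        grid = props.GridSpec.around(scf.geometry, padding=5.0, step=0.1)
        field = props.density_field(gamma, scf.basis, grid)
        assert field.values.sum() * grid.voxel_volume == pytest.approx(
            2.0, abs=0.02)

    def test_grid_refinement_improves_normalization(self, h2_density):
        """Quadrature error decreases with step until box truncation
        dominates; at the production step (0.1) it is far below truncation."""
        scf, gamma = h2_density
        errs = []
        for step in (1.2, 0.8, 0.4, 0.1):
            grid = props.GridSpec.around(scf.geometry, padding=6.0,
                                         step=step)
            field = props.density_field(gamma, scf.basis, grid)
            errs.append(abs(field.values.sum() * grid.voxel_volume - 2.0))
        assert errs[0] > errs[1] > errs[2] > errs[3]
        assert errs[3] < 1e-4

    def test_analytic_gradient_and_hessian_match_finite_difference(
            self, h2_density):
        scf, gamma = h2_density
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(10, 3))
        rho, grad, hess = props.density_at(gamma, scf.basis, pts, 2)
        h = 1e-5
        for k in range(3):
            e = np.zeros(3)
            e[k] = h
            fp = props.density_at(gamma, scf.basis, pts + e)
            fm = props.density_at(gamma, scf.basis, pts - e)
            assert np.abs((fp - fm) / (2 * h) - grad[:, k]).max() < 1e-7
            _, gp = props.density_at(gamma, scf.basis, pts + e, 1)
            _, gm = props.density_at(gamma, scf.basis, pts - e, 1)
            assert np.abs((gp - gm) / (2 * h) - hess[:, k, :]).max() < 1e-6

    def test_density_nonnegative(self, h2_density):
        scf, gamma = h2_density
        rng = np.random.default_rng(3)
        rho = props.density_at(gamma, scf.basis, rng.normal(size=(200, 3)))
        assert rho.min() > -1e-12


class TestESP:
    def test_nuclear_only_potential_is_coulombic(self, h_atom):
        geom, basis = h_atom
        r = 3.0  # Bohr
        v = props.esp_at(np.zeros((1, 1)), basis, geom, [[r, 0.0, 0.0]])
        assert v[0] == pytest.approx(1.0 / r, abs=1e-12)

    def test_far_field_monopole_limit(self, h3plus_scf):
        """H3+ at 50 a0 looks like a +1 point charge."""
        gamma = h3plus_scf.hf_density_ao
        v = props.esp_at(gamma, h3plus_scf.basis, h3plus_scf.geometry,
                         [[100.0, 0.0, 0.0]])
        assert v[0] == pytest.approx(1.0 / 100.0, rel=0.01)

    def test_electronic_term_matches_quadrature(self, h_atom):
        """Exact ⟨μ|1/|r−c||ν⟩ contraction vs brute-force grid quadrature."""
        geom, basis = h_atom
        gamma = np.array([[1.0]])
        c = np.array([2.5, 0.0, 0.0])
        grid = props.GridSpec.around(geom, padding=7.0, step=0.08)
        pts = grid.points()
        rho = props.density_at(gamma, basis, pts)
        dist = np.linalg.norm(pts - c, axis=1)
        quad = np.sum(rho / dist) * grid.voxel_volume
        exact = props.esp_at(gamma, basis, geom, [c])[0]
        # exact = V_nuc - V_el; V_nuc = 1/2.5 here
        v_el = 1.0 / 2.5 - exact
        assert v_el == pytest.approx(quad, abs=1e-3)

    def test_near_nucleus_masked(self, h_atom):
        geom, basis = h_atom
        v = props.esp_at(np.array([[1.0]]), basis, geom, [[0.0, 0.0, 1e-9]])
        assert np.isnan(v[0])


class TestDipole:
    def test_neutral_symmetric_h2_has_zero_dipole(self, h2_density):
        scf, gamma = h2_density
        mu, mag, debye = props.dipole_moment(gamma, scf)
        assert mag < 1e-10

    def test_origin_shift_identity_for_charged_species(self, h3plus_scf):
        """For net charge Q, μ(o + s) = μ(o) − Q·s exactly."""
        gamma = h3plus_scf.hf_density_ao
        shift = np.array([0.3, -0.7, 0.2])
        mu0, _, _ = props.dipole_moment(gamma, h3plus_scf)
        mu1, _, _ = props.dipole_moment(gamma, h3plus_scf, origin=shift)
        q = h3plus_scf.geometry.total_charge
        assert np.abs(mu1 - (mu0 - q * shift)).max() < 1e-10

    def test_neutral_dipole_origin_independent(self, h2_density):
        scf, gamma = h2_density
        mu0, _, _ = props.dipole_moment(gamma, scf)
        mu1, _, _ = props.dipole_moment(gamma, scf,
                                        origin=[1.0, 2.0, -3.0])
        assert np.abs(mu0 - mu1).max() < 1e-10

    def test_debye_conversion(self, h3plus_scf):
        _, mag, debye = props.dipole_moment(h3plus_scf.hf_density_ao,
                                            h3plus_scf)
        assert debye == pytest.approx(mag * 2.541746473, rel=1e-12)


class TestMulliken:
    def test_h2_charges_vanish_by_symmetry(self, h2_density):
        scf, gamma = h2_density
        _, charges, _ = props.mulliken(gamma, scf.overlap, scf.basis,
                                       scf.geometry)
        assert np.abs(charges).max() < 1e-10

    def test_population_sum_is_trace_identity(self, ch5_scf):
        pops, charges, per_ao = props.mulliken(
            ch5_scf.hf_density_ao, ch5_scf.overlap, ch5_scf.basis,
            ch5_scf.geometry)
        tr = np.trace(ch5_scf.hf_density_ao @ ch5_scf.overlap)
        assert pops.sum() == pytest.approx(tr, abs=1e-10)
        assert charges.sum() == pytest.approx(1.0, abs=1e-8)
        assert sum(p for _, p in per_ao) == pytest.approx(tr, abs=1e-10)


class TestCriticalPoints:
    def test_single_atom_has_one_ncp_at_nucleus(self, h_atom):
        geom, basis = h_atom
        cps = props.find_critical_points(np.array([[2.0]]), basis, geom)
        assert len(cps) == 1
        cp = cps[0]
        assert cp.cp_type == "NCP"
        assert np.linalg.norm(cp.position) < 1e-6
        assert np.all(cp.hessian_eigenvalues < 0)

    def test_h2_bcp_at_midpoint_with_correct_signature(self, h2_density):
        scf, gamma = h2_density
        cps = props.find_critical_points(gamma, scf.basis, scf.geometry)
        bcps = [c for c in cps if c.cp_type == "BCP"]
        ncps = [c for c in cps if c.cp_type == "NCP"]
        assert len(bcps) == 1 and len(ncps) == 2
        mid = scf.geometry.positions_bohr.mean(axis=0)
        assert np.linalg.norm(bcps[0].position - mid) < 1e-6
        eigs = bcps[0].hessian_eigenvalues
        assert (eigs < 0).sum() == 2 and (eigs > 0).sum() == 1

    def test_gradient_zero_at_every_reported_cp(self, h2_density):
        scf, gamma = h2_density
        for cp in props.find_critical_points(gamma, scf.basis,
                                             scf.geometry):
            _, grad = props.density_at(gamma, scf.basis,
                                       cp.position[None, :], 1)
            assert np.linalg.norm(grad) < 1e-8


class TestCubeIO:
    def test_roundtrip(self, tmp_path, h2_density):
        scf, gamma = h2_density
        grid = props.GridSpec.around(scf.geometry, padding=2.0, step=0.5)
        field = props.density_field(gamma, scf.basis, grid)
        path = tmp_path / "h2.cube"
        props.write_cube(field, scf.geometry, path)
        back, geom = props.read_cube(path)
        rel = np.abs(back.values - field.values) / (
            np.abs(field.values) + 1e-300)
        mask = np.abs(field.values) > 1e-12
        assert rel[mask].max() < 1e-6
        assert back.grid.counts == field.grid.counts

    def test_layout_matches_handwritten_reference(self, tmp_path):
        """2x2x2 grid of known values against the format written by hand."""
        geom = geometry_from_arrays(["H"], [[0, 0, 0]], 0, 2)
        grid = props.GridSpec(origin=np.zeros(3), axes=np.eye(3) * 0.5,
                              counts=(2, 2, 2))
        vals = np.arange(8, dtype=float).reshape(2, 2, 2)
        path = tmp_path / "ref.cube"
        props.write_cube(props.ScalarField(grid, vals), geom, path,
                         comment="reference")
        lines = path.read_text().splitlines()
        assert lines[0] == "reference"
        assert lines[2].split()[0] == "1"            # one atom
        assert [ln.split()[0] for ln in lines[3:6]] == ["2", "2", "2"]
        atom_line = lines[6].split()
        assert atom_line[0] == "1"                   # Z, positive convention
        # z-fastest ordering: first data row is values [0, 1]
        row0 = [float(x) for x in lines[7].split()]
        assert row0 == [0.0, 1.0]

    def test_rejects_mismatched_shapes(self):
        grid = props.GridSpec(origin=np.zeros(3), axes=np.eye(3) * 0.5,
                              counts=(2, 2, 2))
        with pytest.raises(ValueError):
            props.ScalarField(grid, np.zeros((2, 2, 3)))
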