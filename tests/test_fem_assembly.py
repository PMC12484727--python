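"""Element matrices, global assembly, Dirichlet elimination."""

import numpy as np
import pytest
import scipy.linalg as sla

from brainmodes import (
    LabeledMesh,
    MaterialSet,
    apply_dirichlet,
    assemble,
    element_mass,
    element_stiffness,
)
from brainmodes.assembly import AssemblyError
from brainmodes.materials import Material

UNIT_TET = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])


def stiffness_quadrature_oracle(coords, E, nu):
    """Independent K_e: nodal shape functions from a Vandermonde solve,
    strain-displacement rows assembled per DOF, integrated by quadrature
    (4-point Gauss; the integrand is constant so this is exact)."""
    A = np.hstack([np.ones((4, 1)), coords])  # N_a(x) = c0 + c.x
    C = np.linalg.inv(A)  # columns: coefficients of each shape function
    grads = C[1:, :].T  # (4, 3), row a = grad N_a
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = mu * np.eye(3)
    B = np.zeros((6, 12))
    for a in range(4):
        gx, gy, gz = grads[a]
        B[0, 3 * a] = gx
        B[1, 3 * a + 1] = gy
        B[2, 3 * a + 2] = gz
        B[3, 3 * a] = gy
        B[3, 3 * a + 1] = gx
        B[4, 3 * a + 1] = gz
        B[4, 3 * a + 2] = gy
        B[5, 3 * a] = gz
        B[5, 3 * a + 2] = gx
    vol = abs(np.linalg.det(coords[1:] - coords[0])) / 6.0
    # 4-point quadrature with equal weights over the constant integrand
    return sum(0.25 * vol * (B.T @ D @ B) for _ in range(4))


class TestElementStiffness:
    def test_translation_null_space(self):
        K = element_stiffness(UNIT_TET, E=1.0, nu=0.3)
        for d in range(3):
            u = np.zeros(12)
            u[d::3] = 1.0
            assert np.abs(K @ u).max() < 1e-12

    def test_rotation_null_space(self):
        K = element_stiffness(UNIT_TET, E=1.0, nu=0.3)
        centroid = UNIT_TET.mean(axis=0)
        for axis in np.eye(3):
            u = np.cross(axis, UNIT_TET - centroid).reshape(-1)
            assert np.abs(K @ u).max() < 1e-12

    def test_matches_quadrature_oracle(self):
        K = element_stiffness(UNIT_TET, E=1.0, nu=0.0)
        K_oracle = stiffness_quadrature_oracle(UNIT_TET, E=1.0, nu=0.0)
        assert np.allclose(K, K_oracle, atol=1e-13)

    def test_oracle_agreement_on_general_tet(self, rng):
        coords = UNIT_TET + 0.3 * rng.standard_normal((4, 3))
        if np.linalg.det(coords[1:] - coords[0]) < 0:
            coords[[2, 3]] = coords[[3, 2]]
        K = element_stiffness(coords, E=2.5, nu=0.3)
        K_oracle = stiffness_quadrature_oracle(coords, E=2.5, nu=0.3)
        assert np.allclose(K, K_oracle, rtol=1e-10, atol=1e-12)

    def test_degenerate_tet_raises(self):
        flat = UNIT_TET.copy()
        flat[3] = [1.0, 1.0, 0.0]  # coplanar
        with pytest.raises(AssemblyError, match="degenerate"):
            element_stiffness(flat, E=1.0, nu=0.3)


class TestElementMass:
    def test_mass_conservation_per_direction(self):
        M = element_mass(UNIT_TET, rho=2.0)
        vol = 1.0 / 6.0
        for d in range(3):
            u = np.zeros(12)
            u[d::3] = 1.0
            assert u @ M @ u == pytest.approx(2.0 * vol, rel=1e-12)

    def test_positive_definite(self):
        M = element_mass(UNIT_TET, rho=1.0)
        assert np.linalg.eigvalsh(M).min() > 0

    def test_unit_tet_diagonal_closed_form(self):
        M = element_mass(UNIT_TET, rho=1.0)
        assert np.allclose(np.diag(M), 1.0 / 60.0)

    def test_lumped_mass_is_diagonal_and_conserves(self):
        M = element_mass(UNIT_TET, rho=3.0, lumped=True)
        assert np.allclose(M, np.diag(np.diag(M)))
        assert np.diag(M).sum() == pytest.approx(3 * 3.0 / 6.0, rel=1e-12)


def two_tet_mesh():
    nodes = np.array(
        [[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]])
    tets = np.array([[0, 1, 2, 3], [1, 4, 2, 3]])
    return LabeledMesh(nodes=nodes, tets=tets,
                       region_labels=np.array(["WM", "GM"]))


class TestAssemble:
    def test_total_mass_conserved(self, coarse_phantom):
        mats = MaterialSet.csf_sweep(0.299)
        system = assemble(coarse_phantom, mats)
        expected = sum(
            mats[r].rho * coarse_phantom.region_volume(r)
            for r in coarse_phantom.regions)
        ones = np.zeros(system.n_free)
        ones[0::3] = 1.0
        assert ones @ system.M @ ones == pytest.approx(expected, rel=1e-10)

    def test_uniform_translation_in_null_space(self, coarse_phantom):
        system = assemble(coarse_phantom, MaterialSet.csf_sweep(0.299))
        u = np.zeros(system.n_free)
        u[1::3] = 1.0
        scale = np.abs(system.K.data).max()
        assert np.abs(system.K @ u).max() < 1e-9 * scale

    def test_hand_scattered_two_tet_oracle(self):
        mesh = two_tet_mesh()
        mats = MaterialSet({
            "WM": Material(E=1.0, rho=1e-9, nu=0.3),
            "GM": Material(E=2.0, rho=2e-9, nu=0.25),
        })
        system = assemble(mesh, mats)
        K_ref = np.zeros((15, 15))
        M_ref = np.zeros((15, 15))
        for tet, label in zip(mesh.tets, mesh.region_labels):
            m = mats[label]
            Ke = element_stiffness(mesh.nodes[tet], m.E, m.nu)
            Me = element_mass(mesh.nodes[tet], m.rho)
            dofs = (3 * tet[:, None] + np.arange(3)).reshape(-1)
            for a, ga in enumerate(dofs):
                for b, gb in enumerate(dofs):
                    K_ref[ga, gb] += Ke[a, b]
                    M_ref[ga, gb] += Me[a, b]
        assert np.allclose(system.K.toarray(), K_ref, atol=1e-14)
        assert np.allclose(system.M.toarray(), M_ref, atol=1e-22)

    def test_missing_material_names_region(self, coarse_phantom):
        with pytest.raises(AssemblyError, match="SKULL"):
            assemble(coarse_phantom, MaterialSet.complexity_heterogeneous())

    def test_symmetry(self, fixed_bar_system):
        K, M = fixed_bar_system.K, fixed_bar_system.M
        assert abs((K - K.T)).max() <= 1e-10 * np.abs(K.data).max()
        assert abs((M - M.T)).max() <= 1e-10 * np.abs(M.data).max()


class TestDirichlet:
    def test_fix_everything_signals_fully_constrained(self, small_bar, bar_material):
        system = assemble(small_bar, bar_material)
        small_bar.node_sets["all"] = np.arange(small_bar.n_nodes)
        reduced = apply_dirichlet(system, small_bar, "all")
        assert reduced.n_free == 0 and reduced.fully_constrained

    def test_fix_one_node_bookkeeping(self, small_bar, bar_material):
        system = assemble(small_bar, bar_material)
        small_bar.node_sets["one"] = np.array([0])
        reduced = apply_dirichlet(system, small_bar, "one")
        assert reduced.n_free == 3 * (small_bar.n_nodes - 1)
        assert (reduced.dof_map[:3] == -1).all()

    def test_reduced_stiffness_positive_definite(self, fixed_bar_system):
        w = sla.eigvalsh(fixed_bar_system.K.toarray())
        assert w.min() > 0

    def test_mass_positive_definite(self, fixed_bar_system):
        w = sla.eigvalsh(fixed_bar_system.M.toarray())
        assert w.min() > 0

    def test_empty_node_set_raises(self, small_bar, bar_material):
        system = assemble(small_bar, bar_material)
        small_bar.node_sets["empty"] = np.array([], dtype=int)
        with pytest.raises(AssemblyError, match="empty"):
            apply_dirichlet(system, small_bar, "empty")

    def test_unknown_node_set_raises(self, small_bar, bar_material):
        system = assemble(small_bar, bar_material)
        with pytest.raises(KeyError):
            apply_dirichlet(system, small_bar, "nope")


class TestMaterialScaling:
    def test_stiffness_scales_exactly_with_E(self, small_bar, bar_material):
        K1 = assemble(small_bar, bar_material).K
        K3 = assemble(small_bar, bar_material.scaled(3.0)).K
        assert np.allclose(K3.toarray(), 3.0 * K1.toarray(), rtol=1e-13)

    def test_single_region_stiffening_is_psd(self):
        # raising one region's E adds a positive semi-definite increment,
        # so no eigenfrequency can decrease (Courant-Fischer)
        mesh = two_tet_mesh()
        base = MaterialSet({
            "WM": Material(E=1.0, rho=1e-9, nu=0.3),
            "GM": Material(E=1.0, rho=1e-9, nu=0.3),
        })
        stiffer = MaterialSet({
            "WM": Material(E=1.0, rho=1e-9, nu=0.3),
            "GM": Material(E=4.0, rho=1e-9, nu=0.3),
        })
        dK = (assemble(mesh, stiffer).K - assemble(mesh, base).K).toarray()
        w = np.linalg.eigvalsh(0.5 * (dK + dK.T))
        assert w.min() > -1e-10 * max(abs(w).max(), 1.0)

    def test_material_validation(self):
        with pytest.raises(ValueError):
            Material(E=-1.0, rho=1e-9, nu=0.3)
        with pytest.raises(ValueError):
            Material(E=1.0, rho=1e-9, nu=0.5)
        with pytest.raises(ValueError):
            Material(E=1.0, rho=0.0, nu=0.3)

    def test_nu_cap(self):
        mats = MaterialSet.csf_sweep(0.299).with_nu_cap(0.49)
        assert mats["CSF"].nu == 0.49
        assert mats["SKULL"].nu == 0.22
        assert MaterialSet.csf_sweep(0.299).with_nu_cap(None)["CSF"].nu == 0.4999
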