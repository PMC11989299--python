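"""Solver verification: element oracle, assembly, loads, constraints,
patch test, dense brute-force equivalence, equilibrium, linearity."""

import numpy as np
import pytest

from ianload.fem import (LoadCase, Material, SolverError, adaptive_converge,
                         apply_dirichlet, apply_load, assemble,
                         default_materials, element_stiffness, fixed_dof_mask,
                         hooke_matrix, solve, solve_case)
from ianload.geometry import ModelParams, Region
from ianload.meshing import NerveInterface, TetMesh, box_mesh

UNIT_TET = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])


def _single_tet_mesh(coords=UNIT_TET):
    return TetMesh(nodes=np.asarray(coords, float),
                   tets=np.array([[0, 1, 2, 3]], dtype=np.int32),
                   region=np.array([int(Region.TRABECULAR)], dtype=np.int16),
                   facets={}, nerve_interface=NerveInterface(
                       np.empty((0, 3), np.int64), np.empty(0, np.int64),
                       np.empty(0, np.int64)))


def _dense_reference_K(mesh, E, nu):
    """Independent brute-force assembly: per-element loops, explicit
    shape-function algebra, dense accumulation."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D += np.diag([2 * mu] * 3 + [mu] * 3)
    n_dof = 3 * len(mesh.nodes)
    K = np.zeros((n_dof, n_dof))
    for tet in mesh.tets:
        X = np.c_[np.ones(4), mesh.nodes[tet]]
        C = np.linalg.inv(X)          # rows: coeffs (a, bx, by, bz) per node
        vol = abs(np.linalg.det(X)) / 6.0
        B = np.zeros((6, 12))
        for i in range(4):
            bx, by, bz = C[1, i], C[2, i], C[3, i]
            B[:, 3 * i:3 * i + 3] = [[bx, 0, 0], [0, by, 0], [0, 0, bz],
                                     [by, bx, 0], [0, bz, by], [bz, 0, bx]]
        Ke = vol * B.T @ D @ B
        dof = np.repeat(3 * tet, 3) + np.tile([0, 1, 2], 4)
        K[np.ix_(dof, dof)] += Ke
    return K


class TestElementStiffness:
    def test_rigid_modes_are_exact_null_space(self, rng):
        coords = UNIT_TET + rng.normal(0, 0.2, (4, 3))
        Ke = element_stiffness(coords, E=5000.0, nu=0.3)
        assert np.allclose(Ke, Ke.T)
        for t in np.eye(3):  # rigid translations
            v = np.tile(t, 4)
            assert np.abs(Ke @ v).max() < 1e-8 * np.abs(Ke).max()
        w = np.linalg.eigvalsh(Ke)
        assert (np.abs(w[:6]) < 1e-8 * w[-1]).all()   # 6 zero-energy modes
        assert (w[6:] > 0).all()

    def test_matches_symbolic_integration_on_unit_tet(self):
        sympy = pytest.importorskip("sympy")
        x, y, z = sympy.symbols("x y z")
        N = [1 - x - y - z, x, y, z]
        B = sympy.zeros(6, 12)
        for i, Ni in enumerate(N):
            bx, by, bz = (sympy.diff(Ni, v) for v in (x, y, z))
            B[0, 3 * i], B[1, 3 * i + 1], B[2, 3 * i + 2] = bx, by, bz
            B[3, 3 * i], B[3, 3 * i + 1] = by, bx
            B[4, 3 * i + 1], B[4, 3 * i + 2] = bz, by
            B[5, 3 * i], B[5, 3 * i + 2] = bz, bx
        D = sympy.diag(1, 1, 1, sympy.Rational(1, 2),
                       sympy.Rational(1, 2), sympy.Rational(1, 2))  # E=1, nu=0
        integrand = B.T * D * B
        Ke_sym = sympy.integrate(
            sympy.integrate(sympy.integrate(integrand, (z, 0, 1 - x - y)),
                            (y, 0, 1 - x)), (x, 0, 1))
        Ke = element_stiffness(UNIT_TET, E=1.0, nu=0.0)
        assert np.allclose(Ke, np.array(Ke_sym, dtype=float), atol=1e-12)

    def test_stiffness_scales_linearly_with_length(self):
        K1 = element_stiffness(UNIT_TET, E=1000.0, nu=0.25)
        K2 = element_stiffness(2.0 * UNIT_TET, E=1000.0, nu=0.25)
        assert np.allclose(K2, 2.0 * K1)

    def test_degenerate_tet_rejected(self):
        flat = UNIT_TET.copy()
        flat[3] = [0.5, 0.5, 0.0]  # coplanar
        with pytest.raises(ValueError, match="degenerate|inverted"):
            element_stiffness(flat, E=1000.0, nu=0.3)
        with pytest.raises(ValueError):
            element_stiffness(UNIT_TET, E=1000.0, nu=0.6)


class TestAssembly:
    def test_single_tet_assembly_identity(self):
        mesh = _single_tet_mesh()
        mats = {Region.TRABECULAR: Material(4500.0, 0.3)}
        K = assemble(mesh, mats).toarray()
        assert np.allclose(K, element_stiffness(UNIT_TET, 4500.0, 0.3))

    def test_matches_dense_brute_force(self, small_box):
        E, nu = 4500.0, 0.3
        K = assemble(small_box, {Region.TRABECULAR: Material(E, nu)})
        K_ref = _dense_reference_K(small_box, E, nu)
        assert np.allclose(K.toarray(), K_ref, atol=1e-9 * np.abs(K_ref).max())

    def test_exactly_symmetric(self, small_box):
        K = assemble(small_box, {Region.TRABECULAR: Material(4500.0, 0.3)})
        assert (K - K.T).nnz == 0 or abs(K - K.T).max() == 0

    def test_missing_material_reported(self, small_box):
        with pytest.raises(ValueError, match="TRABECULAR"):
            assemble(small_box, {Region.NERVE: Material(1.3, 0.4)})


class TestLoadsAndConstraints:
    def test_resultant_equals_total_load(self, coarse_mesh):
        f = apply_load(coarse_mesh, LoadCase(200.0))
        assert f.reshape(-1, 3)[:, 2].sum() == pytest.approx(200.0, rel=1e-12)
        assert np.allclose(f.reshape(-1, 3)[:, :2], 0)

    def test_zero_load_gives_zero_vector(self, coarse_mesh):
        assert not apply_load(coarse_mesh, LoadCase(0.0)).any()

    def test_resultant_invariant_under_facet_refinement(self):
        f1 = apply_load(box_mesh(2, 2, 2, (2, 2, 2)), LoadCase(200.0))
        f2 = apply_load(box_mesh(2, 2, 2, (4, 4, 2)), LoadCase(200.0))
        assert f1.reshape(-1, 3)[:, 2].sum() == pytest.approx(
            f2.reshape(-1, 3)[:, 2].sum(), rel=1e-12)

    def test_missing_load_tag(self):
        mesh = _single_tet_mesh()
        with pytest.raises(ValueError, match="BOLUS_TOP"):
            apply_load(mesh, LoadCase(200.0))

    def test_no_constraints_is_singular(self, small_box):
        K = assemble(small_box, {Region.TRABECULAR: Material(4500.0, 0.3)})
        with pytest.raises(SolverError, match="singular|constraints"):
            apply_dirichlet(K, np.zeros(K.shape[0], dtype=bool))

    def test_fully_fixed_tet_has_zero_displacement(self):
        mesh = _single_tet_mesh()
        mats = {Region.TRABECULAR: Material(4500.0, 0.3)}
        K = assemble(mesh, mats)
        system = apply_dirichlet(K, np.ones(12, dtype=bool))
        f = np.zeros(12)
        f[2::3] = 1.0  # arbitrary load, all nodes fixed
        fields = solve(system, f, mesh, mats)
        assert not fields.u.any()


class TestSolve:
    def test_uniaxial_patch_state_reproduced(self, small_box):
        """Rollers on the bottom, uniform pressure on top: sigma_zz = -p,
        shortening pL/E; constant-strain tets reproduce it exactly."""
        E, nu, F = 4500.0, 0.3, 200.0
        mats = {Region.TRABECULAR: Material(E, nu)}
        K = assemble(small_box, mats)
        mask = fixed_dof_mask(small_box, {"BLOCK_BOTTOM": "z"})
        # 3-2-1 pins consistent with the homogeneous state (nodes on the
        # symmetry axes of the lateral expansion)
        axis = np.nonzero((np.abs(small_box.nodes[:, 0]) < 1e-12)
                          & (np.abs(small_box.nodes[:, 1]) < 1e-12))[0]
        mask[3 * axis[0]:3 * axis[0] + 2] = True
        on_x = np.nonzero((np.abs(small_box.nodes[:, 1]) < 1e-12)
                          & (small_box.nodes[:, 0] > 0.5))[0]
        mask[3 * on_x[0] + 1] = True
        fields = solve(apply_dirichlet(K, mask), apply_load(small_box, LoadCase(F)),
                       small_box, mats)
        p = F / 4.0  # top face area 2x2
        assert np.allclose(fields.stress[:, 2], -p, rtol=1e-8)
        assert np.allclose(fields.stress[:, [0, 1, 3, 4, 5]], 0, atol=1e-8 * p)
        tip = np.abs(fields.u[small_box.facet_nodes("BOLUS_TOP"), 2]
                     - p * 2.0 / E)
        assert tip.max() < 0.01 * p * 2.0 / E

    def test_sparse_matches_dense_brute_force_solution(self, small_box):
        E, nu = 4500.0, 0.3
        mats = {Region.TRABECULAR: Material(E, nu)}
        load = LoadCase(200.0, fixed={"BLOCK_BOTTOM": "xyz"})
        fields = solve_case(small_box, mats, load)
        # independent dense path
        K_ref = _dense_reference_K(small_box, E, nu)
        f = apply_load(small_box, load)
        fixed = np.zeros(len(f), dtype=bool)
        for n in small_box.facet_nodes("BLOCK_BOTTOM"):
            fixed[3 * n:3 * n + 3] = True
        free = ~fixed
        u_ref = np.zeros(len(f))
        u_ref[free] = np.linalg.solve(K_ref[np.ix_(free, free)], f[free])
        err = np.linalg.norm(fields.u.ravel() - u_ref) / np.linalg.norm(u_ref)
        assert err < 1e-10

    def test_zero_load_zero_displacement(self, small_box):
        fields = solve_case(small_box, {Region.TRABECULAR: Material(4500.0, 0.3)},
                            LoadCase(0.0, fixed={"BLOCK_BOTTOM": "xyz"}))
        assert not fields.u.any()

    def test_equilibrium_on_production_case(self, coarse_fields):
        total = coarse_fields.reaction_total()
        assert np.linalg.norm(total + [0, 0, 200.0]) / 200.0 < 1e-6
        assert coarse_fields.residual < 1e-8

    def test_linearity_in_load(self, coarse_mesh, coarse_fields):
        doubled = solve_case(coarse_mesh, default_materials(), LoadCase(400.0))
        assert np.allclose(doubled.u, 2 * coarse_fields.u, rtol=1e-9, atol=1e-15)
        assert np.allclose(doubled.stress, 2 * coarse_fields.stress,
                           rtol=1e-9, atol=1e-12)

    def test_mirror_symmetric_solution(self, coarse_mesh, coarse_fields):
        # geometry/load/supports are mirror-symmetric about y=0; the Kuhn
        # tet split is not, so fields match only to discretisation level
        key = {tuple(p): i for i, p in enumerate(np.round(coarse_mesh.nodes, 9))}
        mirrored = np.round(coarse_mesh.nodes * np.array([1, -1, 1]), 9)
        idx = np.array([key[tuple(p)] for p in mirrored])
        u = coarse_fields.u
        u_mir = u[idx] * np.array([1, -1, 1])
        rel = np.linalg.norm(u - u_mir) / np.linalg.norm(u)
        assert rel < 0.05


@pytest.fixture(scope="module")
def adaptive_result():
    params = ModelParams(symmetry="quarter", axial_window=2.0,
                         refine_margin=0.3, refined_element_size=0.3)
    return adaptive_converge(params, default_materials(), LoadCase(200.0),
                             max_meshes=3)


class TestAdaptiveConvergence:
    def test_trace_and_stopping_rule(self, adaptive_result):
        r = adaptive_result
        assert len(r.trace) >= 2
        if r.converged:
            assert all(d < 0.10 for d in r.trace[-1]["rel_change"].values())

    def test_mesh_grows_monotonically(self, adaptive_result):
        sizes = [t["n_tets"] for t in adaptive_result.trace]
        assert sizes == sorted(sizes) and sizes[0] < sizes[-1]

    def test_unconverged_flag_when_cap_hits(self):
        params = ModelParams(symmetry="quarter", axial_window=2.0,
                             refine_margin=0.3, refined_element_size=0.45)
        r = adaptive_converge(params, default_materials(), LoadCase(200.0),
                              rel_tol=1e-9, max_meshes=2)
        assert not r.converged  # 1e-9 relative change is unattainable
        assert len(r.trace) == 2
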