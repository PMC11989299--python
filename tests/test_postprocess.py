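"""Derived fields: von Mises, equivalent strain, deformation, nerve pressure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ianload import postprocess as post
from ianload.fem import LoadCase, Material, apply_dirichlet, apply_load, \
    assemble, fixed_dof_mask, solve
from ianload.geometry import Region


def _rotation(angles):
    ax, ay, az = angles
    cx, sx, cy, sy, cz, sz = (np.cos(ax), np.sin(ax), np.cos(ay),
                              np.sin(ay), np.cos(az), np.sin(az))
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _tensor_to_voigt(t, engineering_shear):
    s = 2.0 if engineering_shear else 1.0
    return np.array([t[0, 0], t[1, 1], t[2, 2],
                     s * t[0, 1], s * t[1, 2], s * t[0, 2]])


class TestVonMises:
    @pytest.mark.parametrize("voigt,expected", [
        ([-5, -5, -5, 0, 0, 0], 0.0),          # hydrostatic: deviator null
        ([-4, 0, 0, 0, 0, 0], 4.0),            # uniaxial
        ([0, 0, 0, 1, 0, 0], np.sqrt(3.0)),    # pure shear
    ])
    def test_closed_forms(self, voigt, expected):
        assert post.von_mises(np.array(voigt, float)) == pytest.approx(expected)

    @given(st.lists(st.floats(-10, 10), min_size=6, max_size=6),
           st.lists(st.floats(0, np.pi), min_size=3, max_size=3))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_frame_invariance(self, voigt, angles):
        v = np.array(voigt)
        R = _rotation(angles)
        t = post._voigt_to_tensor(v, shear_half=False)
        rotated = _tensor_to_voigt(R @ t @ R.T, engineering_shear=False)
        assert post.von_mises(rotated) == pytest.approx(
            post.von_mises(v), rel=1e-9, abs=1e-9)


class TestEquivalentStrain:
    def test_zero_and_hydrostatic_vanish(self):
        assert post.equivalent_strain(np.zeros(6), 0.3) == 0.0
        hydro = np.array([1e-3, 1e-3, 1e-3, 0, 0, 0])
        assert post.equivalent_strain(hydro, 0.3) == pytest.approx(0.0, abs=1e-15)

    def test_uniaxial_with_zero_poisson(self):
        e = 2.5e-3
        voigt = np.array([e, 0, 0, 0, 0, 0])
        assert post.equivalent_strain(voigt, 0.0) == pytest.approx(e)

    @given(st.lists(st.floats(-1e-2, 1e-2), min_size=6, max_size=6),
           st.lists(st.floats(0, np.pi), min_size=3, max_size=3))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_frame_invariance(self, voigt, angles):
        v = np.array(voigt)
        R = _rotation(angles)
        t = post._voigt_to_tensor(v, shear_half=True)
        rotated = _tensor_to_voigt(R @ t @ R.T, engineering_shear=True)
        assert post.equivalent_strain(rotated, 0.3) == pytest.approx(
            post.equivalent_strain(v, 0.3), rel=1e-9, abs=1e-12)


class TestTraction:
    def test_uniform_compression_projects_to_pressure(self):
        p = 3.7
        stress = np.array([0, 0, -p, 0, 0, 0], float)
        n = np.array([0, 0, 1.0])
        assert -post.normal_traction(stress, n) == pytest.approx(p)

    @given(st.lists(st.floats(-10, 10), min_size=6, max_size=6),
           st.lists(st.floats(0.1, 1.0), min_size=3, max_size=3))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bounded_by_largest_principal_stress(self, voigt, direction):
        v = np.array(voigt)
        n = np.array(direction)
        n /= np.linalg.norm(n)
        t = post._voigt_to_tensor(v, shear_half=False)
        bound = np.abs(np.linalg.eigvalsh(t)).max()
        assert abs(post.normal_traction(v, n)) <= bound * (1 + 1e-9)


class TestTotalDeformation:
    def test_norm_of_displacement(self, coarse_fields):
        td = post.total_deformation(coarse_fields.u)
        assert (td >= 0).all()
        assert td.max() == pytest.approx(
            np.linalg.norm(coarse_fields.u, axis=1).max())
        assert post.total_deformation(np.zeros((5, 3))).tolist() == [0] * 5

    def test_maximum_in_loaded_column_above_the_bone(self, coarse_mesh,
                                                     coarse_fields):
        # the stack and crest carry the load path; the peak displacement
        # sits in the loaded column, not at the fixed boundary
        td = post.total_deformation(coarse_fields.u)
        node = coarse_mesh.nodes[np.argmax(td)]
        assert np.hypot(node[0], node[1]) <= coarse_mesh.params.implant_radius + 0.5


class TestNervePressure:
    @pytest.mark.filterwarnings("ignore:.*tensile.*:UserWarning")
    def test_summary_structure_and_location(self, coarse_mesh, coarse_fields):
        s = post.nerve_interface_pressure(coarse_fields, coarse_mesh)
        # headline = max of the recovered (nodally averaged) field
        assert s.max_pressure_mpa >= s.nodal_pressures[s.nodal_pressures > 0].max() - 1e-15
        assert s.max_pressure_mpa <= s.pressures.max() + 1e-15  # averaging never exceeds raw max
        assert len(s.pressures) == len(coarse_mesh.nerve_interface)
        # the maximum sits on the (staircase) nerve surface, whose nodes
        # lie within a grid step of the nominal nerve cylinder
        p = coarse_mesh.params
        y, z = s.max_location[1], s.max_location[2]
        r = np.hypot(y, z - p.canal_axis_depth)
        assert r <= p.nerve_radius + p.global_element_size + 1e-6

    @pytest.mark.filterwarnings("ignore:.*tensile.*:UserWarning")
    def test_matches_independent_traction_chain(self, coarse_mesh,
                                                coarse_fields, rng):
        """Recompute facet pressures from scratch: affine displacement fit
        per tet, tensor Hooke law, explicit normal projection."""
        s = post.nerve_interface_pressure(coarse_fields, coarse_mesh)
        iface = coarse_mesh.nerve_interface
        mats = coarse_fields.materials
        picks = rng.choice(len(iface), size=10, replace=False)
        for i in picks:
            e_out = mats[int(coarse_mesh.region[iface.outer_tet[i]])].E
            e_in = mats[int(coarse_mesh.region[iface.nerve_tet[i]])].E
            tet_id = iface.outer_tet[i] if e_out <= e_in else iface.nerve_tet[i]
            tet = coarse_mesh.tets[tet_id]
            X = np.c_[np.ones(4), coarse_mesh.nodes[tet]]
            grad = np.linalg.solve(X, coarse_fields.u[tet])[1:]  # du_j/dx_i
            eps = 0.5 * (grad + grad.T)
            mat = mats[int(coarse_mesh.region[tet_id])]
            lam = mat.E * mat.nu / ((1 + mat.nu) * (1 - 2 * mat.nu))
            mu = mat.E / (2 * (1 + mat.nu))
            sigma = lam * np.trace(eps) * np.eye(3) + 2 * mu * eps
            tri = coarse_mesh.nodes[iface.tris[i]]
            n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
            n /= np.linalg.norm(n)
            nerve_c = coarse_mesh.nodes[coarse_mesh.tets[iface.nerve_tet[i]]].mean(0)
            if n @ (tri.mean(0) - nerve_c) < 0:
                n = -n
            assert s.pressures[i] == pytest.approx(-n @ sigma @ n, rel=1e-9,
                                                   abs=1e-12)

    @pytest.mark.filterwarnings("ignore:.*tensile.*:UserWarning")
    def test_linearity_with_load(self, coarse_mesh, coarse_fields):
        from ianload.fem import solve_case, default_materials
        s1 = post.nerve_interface_pressure(coarse_fields, coarse_mesh)
        f2 = solve_case(coarse_mesh, default_materials(), LoadCase(400.0))
        s2 = post.nerve_interface_pressure(f2, coarse_mesh)
        assert np.allclose(s2.pressures, 2 * s1.pressures, rtol=1e-9, atol=1e-14)

    def test_tensile_surface_warns(self, small_box):
        """A block pulled upward puts the tagged interface in tension."""
        mats = {Region.TRABECULAR: Material(4500.0, 0.3)}
        K = assemble(small_box, mats)
        mask = fixed_dof_mask(small_box, {"BLOCK_BOTTOM": "xyz"})
        f = -apply_load(small_box, LoadCase(200.0))  # traction, not pressure
        fields = solve(apply_dirichlet(K, mask), f, small_box, mats)
        # fabricate an interface from interior faces of the box mesh
        from ianload.meshing import NerveInterface, _face_table
        fs, owner, group, counts = _face_table(small_box.tets)
        interior = counts[group] == 2
        tris = fs[interior][0::2][:20]
        t1 = owner[interior][0::2][:20]
        t2 = owner[interior][1::2][:20]
        small_box.nerve_interface = NerveInterface(tris, t1, t2)
        with pytest.warns(UserWarning, match="tensile"):
            post.nerve_interface_pressure(fields, small_box)
        small_box.nerve_interface = NerveInterface(
            np.empty((0, 3), np.int64), np.empty(0, np.int64),
            np.empty(0, np.int64))
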