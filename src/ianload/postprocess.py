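"""Derived field quantities: deformation, von Mises stress, equivalent
elastic strain, and the nerve-interface pressure readout.

Sign convention: compressive normal traction on the nerve is reported
positive (the conduction-block threshold literature refers to
compression); tensile facet values are retained in the distribution but
excluded from the headline maximum unless requested.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .meshing import TetMesh, _tri_areas

__all__ = ["von_mises", "equivalent_strain", "total_deformation",
           "normal_traction", "nerve_interface_pressure", "PressureSummary"]


def _voigt_to_tensor(v: np.ndarray, shear_half: bool) -> np.ndarray:
    """(...,6) Voigt (xx,yy,zz,xy,yz,zx) -> (...,3,3) symmetric tensors.

    ``shear_half`` divides the off-diagonals by 2 (engineering-shear
    strain convention)."""
    v = np.asarray(v, dtype=float)
    t = np.zeros(v.shape[:-1] + (3, 3))
    t[..., 0, 0] = v[..., 0]
    t[..., 1, 1] = v[..., 1]
    t[..., 2, 2] = v[..., 2]
    s = 0.5 if shear_half else 1.0
    t[..., 0, 1] = t[..., 1, 0] = s * v[..., 3]
    t[..., 1, 2] = t[..., 2, 1] = s * v[..., 4]
    t[..., 0, 2] = t[..., 2, 0] = s * v[..., 5]
    return t


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Equivalent (von Mises) stress from Voigt stresses (...,6), MPa.

    sqrt(1/2 [(s11-s22)^2 + (s22-s33)^2 + (s33-s11)^2] + 3(t12^2+t23^2+t31^2))
    """
    s = np.asarray(stress, dtype=float)
    sx, sy, sz, txy, tyz, tzx = (s[..., i] for i in range(6))
    return np.sqrt(0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
                   + 3.0 * (txy ** 2 + tyz ** 2 + tzx ** 2))


def equivalent_strain(strain: np.ndarray, nu) -> np.ndarray:
    """Equivalent elastic strain (effective-Poisson convention).

    eps_eq = 1/(1+nu) * sqrt(1/2 [(e1-e2)^2 + (e2-e3)^2 + (e3-e1)^2])
    with principal strains e_i and nu the element material's elastic
    Poisson ratio (the convention commercial FE packages use for the
    elastic-strain display, so magnitudes are directly comparable).
    Strains are Voigt with engineering shear.
    """
    t = _voigt_to_tensor(strain, shear_half=True)
    e = np.linalg.eigvalsh(t)
    e1, e2, e3 = e[..., 0], e[..., 1], e[..., 2]
    base = np.sqrt(0.5 * ((e1 - e2) ** 2 + (e2 - e3) ** 2 + (e3 - e1) ** 2))
    return base / (1.0 + np.asarray(nu, dtype=float))


def total_deformation(u: np.ndarray) -> np.ndarray:
    """Euclidean norm of each nodal displacement vector (mm)."""
    return np.linalg.norm(np.asarray(u, dtype=float), axis=-1)


def normal_traction(stress: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """n . sigma . n for Voigt stresses (...,6) and unit normals (...,3)."""
    t = _voigt_to_tensor(stress, shear_half=False)
    n = np.asarray(normal, dtype=float)
    return np.einsum("...i,...ij,...j->...", n, t, n)


@dataclass
class PressureSummary:
    """Nerve-surface pressure distribution and its maximum.

    Pressures in MPa, compression positive.  ``max_pressure_mpa`` is the
    maximum of the *recovered* (area-weighted nodally averaged) pressure
    field — the quantity a contour plot displays; raw per-facet values
    are elementwise-constant and oscillate on the staircase surface,
    recovery is the standard smoothing for constant-strain elements.
    It is 0 if the whole surface is tensile (unless ``include_tension``
    was requested).  ``pressures`` keeps the raw facet distribution.
    """

    max_pressure_mpa: float
    max_location: np.ndarray
    pressures: np.ndarray
    centroids: np.ndarray
    areas: np.ndarray
    tensile_fraction: float
    node_ids: np.ndarray = None
    nodal_pressures: np.ndarray = None

    @property
    def max_pressure_mmhg(self) -> float:
        from .calibration import mpa_to_mmhg
        return mpa_to_mmhg(self.max_pressure_mpa)


def nerve_interface_pressure(fields, mesh: TetMesh,
                             include_tension: bool = False,
                             tensile_warn_fraction: float = 0.05
                             ) -> PressureSummary:
    """Compressive normal traction on the nerve surface.

    Traction is continuous across the bonded interface, so either
    adjacent element may supply it; numerically the *compliant* side is
    the reliable one (its stress is modulus-scaled from continuous
    displacements, whereas the stiff side multiplies tiny strain
    differences by a modulus orders of magnitude larger).  Each facet is
    therefore evaluated from the canal-side element (soft tissue, the
    normal case) or from the nerve-side element at staircase corners
    where bone abuts the nerve directly, projected on the outward
    (nerve-to-bone) normal: p = -n . sigma . n, compression positive.
    """
    iface = mesh.nerve_interface
    if iface is None or len(iface) == 0:
        raise ValueError("mesh has no tagged nerve-surface facets")

    tri_pts = mesh.nodes[iface.tris]
    centroids = tri_pts.mean(axis=1)
    normals = np.cross(tri_pts[:, 1] - tri_pts[:, 0], tri_pts[:, 2] - tri_pts[:, 0])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    # orient outward from the nerve side
    nerve_cent = mesh.nodes[mesh.tets[iface.nerve_tet]].mean(axis=1)
    flip = np.einsum("ij,ij->i", normals, centroids - nerve_cent) < 0
    normals[flip] *= -1.0

    e_outer = np.array([fields.materials[int(r)].E
                        for r in mesh.region[iface.outer_tet]])
    e_nerve = np.array([fields.materials[int(r)].E
                        for r in mesh.region[iface.nerve_tet]])
    eval_tet = np.where(e_outer <= e_nerve, iface.outer_tet, iface.nerve_tet)
    sigma = fields.stress[eval_tet]
    p = -normal_traction(sigma, normals)

    areas = _tri_areas(mesh.nodes, iface.tris)
    tensile_fraction = float(np.mean(p < 0))
    if tensile_fraction > tensile_warn_fraction:
        warnings.warn(
            f"{100 * tensile_fraction:.1f}% of nerve-surface facets carry "
            "tensile normal traction; interpret the pressure map with care",
            stacklevel=2)

    # nodal recovery: area-weighted average of facet values at each
    # interface node (what a contour display shows for CST fields)
    num = np.zeros(mesh.n_nodes)
    den = np.zeros(mesh.n_nodes)
    for corner in range(3):
        np.add.at(num, iface.tris[:, corner], p * areas)
        np.add.at(den, iface.tris[:, corner], areas)
    node_ids = np.nonzero(den > 0)[0]
    nodal = num[node_ids] / den[node_ids]

    if include_tension:
        idx = int(np.argmax(np.abs(nodal)))
        pmax = float(nodal[idx])
    else:
        comp = nodal > 0
        if comp.any():
            idx = int(np.argmax(np.where(comp, nodal, -np.inf)))
            pmax = float(nodal[idx])
        else:
            idx = int(np.argmax(nodal))
            pmax = 0.0
    return PressureSummary(max_pressure_mpa=pmax,
                           max_location=mesh.nodes[node_ids[idx]].copy(),
                           pressures=p, centroids=centroids, areas=areas,
                           tensile_fraction=tensile_fraction,
                           node_ids=node_ids, nodal_pressures=nodal)
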