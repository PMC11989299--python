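"""Region-labelled tetrahedral meshing of the parametric assembly.

Strategy: a tensor-product grid over the square cross-section
[-R, R]^2 x [stack_top, block_length] with grid planes *snapped to every
material interface* (implant radius, canal/nerve tangent planes, layer
boundaries), then a square-to-disk radial map

    (x, y) = (u, v) * max(|u|, |v|) / sqrt(u^2 + v^2)

which carries the square ring max(|u|,|v|) = c exactly onto the circle
of radius c.  Because the implant radius and the block radius are grid
lines, both lateral surfaces become true inscribed-polygon cylinders;
the horizontal canal and nerve cylinders are voxel-approximated in the
transverse plane (with tangent planes snapped, so they are never lost
at coarse resolution).  Each hexahedral cell is split into six
tetrahedra by the Kuhn (main-diagonal) decomposition, which is
conforming across cells by construction.

The mesh is a pure function of the parameters: identical parameters
give a byte-identical mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import hashlib
import math

import numpy as np

from .geometry import (
    Geometry, GeometryError, ModelParams, Region, build_model,
    BOLUS_TOP, BLOCK_BOTTOM, BLOCK_LATERAL, NERVE_ENDS, NERVE_SURFACE,
)

__all__ = ["TetMesh", "MeshReport", "generate_mesh", "validate_mesh",
           "refine_near", "box_mesh", "SYMMETRY_X", "SYMMETRY_Y"]

#: Roller-condition tags on the mirror cut planes of reduced models.
SYMMETRY_X = "SYMMETRY_X"   # plane x = 0: clamp u_x
SYMMETRY_Y = "SYMMETRY_Y"   # plane y = 0: clamp u_y

#: Hard cap on tetrahedra; meshing refuses (memory guard) beyond this.
MAX_TETS = 2_500_000

_SQRT2 = math.sqrt(2.0)

# Kuhn decomposition: six tets share the main diagonal c0-c7 of each hex.
# Local corner index = di + 2*dj + 4*dk; one tet per axis permutation.
_KUHN = np.array([
    [0, 1, 3, 7],   # x, y, z
    [0, 1, 5, 7],   # x, z, y
    [0, 2, 3, 7],   # y, x, z
    [0, 2, 6, 7],   # y, z, x
    [0, 4, 5, 7],   # z, x, y
    [0, 4, 6, 7],   # z, y, x
], dtype=np.int64)


@dataclass
class TetMesh:
    """Conforming labelled tetrahedral mesh.

    nodes   : (N, 3) float64, mm; z down the implant axis.
    tets    : (M, 4) int32 node indices, positively oriented.
    region  : (M,) int16 :class:`~ianload.geometry.Region` codes.
    facets  : tag -> (K, 3) node-index triangles (boundary tags).
    nerve_interface : triangles of the nerve surface with the adjacent
        tet on each side (outer = bone/canal side used for the pressure
        readout).
    """

    nodes: np.ndarray
    tets: np.ndarray
    region: np.ndarray
    facets: dict[str, np.ndarray]
    nerve_interface: "NerveInterface"
    params: ModelParams | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        return _tet_volumes(self.nodes, self.tets)

    def region_volumes(self) -> dict[int, float]:
        vols = self.tet_volumes()
        return {int(r): float(vols[self.region == r].sum())
                for r in np.unique(self.region)}

    def facet_area(self, tag: str) -> float:
        tris = self.facets.get(tag)
        if tris is None or len(tris) == 0:
            return 0.0
        return float(_tri_areas(self.nodes, tris).sum())

    def facet_nodes(self, tag: str) -> np.ndarray:
        tris = self.facets.get(tag)
        if tris is None:
            return np.empty(0, dtype=np.int64)
        return np.unique(tris)

    def edges_of(self, region: int | None = None) -> np.ndarray:
        """Unique edge lengths, optionally restricted to one region."""
        tets = self.tets if region is None else self.tets[self.region == region]
        pairs = tets[:, [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]]].reshape(-1, 2)
        pairs = np.unique(np.sort(pairs, axis=1), axis=0)
        d = self.nodes[pairs[:, 0]] - self.nodes[pairs[:, 1]]
        return np.linalg.norm(d, axis=1)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.nodes.tobytes())
        h.update(self.tets.astype(np.int64).tobytes())
        h.update(self.region.astype(np.int64).tobytes())
        for tag in sorted(self.facets):
            h.update(tag.encode())
            h.update(self.facets[tag].astype(np.int64).tobytes())
        return h.hexdigest()


@dataclass
class NerveInterface:
    """Nerve-surface triangles with two-sided tet adjacency."""

    tris: np.ndarray        # (K, 3) node ids
    nerve_tet: np.ndarray   # (K,) tet on the nerve side
    outer_tet: np.ndarray   # (K,) tet on the bone/canal side

    def __len__(self) -> int:
        return len(self.tris)


def _tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = nodes[tets]
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def _tri_areas(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = nodes[tris]
    return 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)


def _interval_lines(lo: float, hi: float, snaps, size_of) -> np.ndarray:
    """Grid lines on [lo, hi] through every snap, spacing <= size_of(mid)."""
    pts = [lo, hi] + [s for s in snaps if lo + 1e-9 < s < hi - 1e-9]
    pts = np.array(sorted(pts))
    keep = np.concatenate([[True], np.diff(pts) > 1e-9])
    pts = pts[keep]
    lines = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        size = size_of(0.5 * (a + b))
        n = max(1, int(math.ceil((b - a) / size - 1e-9)))
        lines.extend(np.linspace(a, b, n + 1)[1:])
    return np.asarray(lines)


def _band_size_fn(global_size: float, band_size: float | None,
                  bands: list[tuple[float, float]]):
    if band_size is None:
        return lambda m: global_size
    h = min(global_size, band_size / _SQRT2)

    def size_of(mid: float) -> float:
        for a, b in bands:
            if a <= mid <= b:
                return h
        return global_size

    return size_of


def generate_mesh(geometry: Geometry, params: ModelParams | None = None,
                  band_element_size: float | None = None) -> TetMesh:
    """Mesh the assembly; deterministic for fixed parameters.

    ``band_element_size`` activates graded refinement (median-edge
    target, mm) in bands around the canal/implant-apex region; ``None``
    keeps the uniform ``global_element_size`` grid.
    """
    p = params or geometry.params
    R = p.block_radius
    zc = p.canal_axis_depth
    L = p.block_length

    # --- grid lines ------------------------------------------------------
    x_snaps = [-p.implant_radius, 0.0, p.implant_radius]
    y_snaps = sorted({-p.implant_radius, -p.canal_radius, -p.nerve_radius, 0.0,
                      p.nerve_radius, p.canal_radius, p.implant_radius})
    z_snaps = [p.stack_top,
               -(p.crown_height + p.composite_height), -p.crown_height, 0.0,
               p.cortical_thickness, p.implant_length,
               p.implant_length + p.apex_to_canal_distance,
               zc - p.nerve_radius, zc, zc + p.nerve_radius,
               min(zc + p.canal_radius, L), L]
    if p.thread_depth > 0:
        # ridge rings and groove transitions become exact grid surfaces
        core = p.implant_radius - p.thread_depth
        x_snaps += [-core, core]
        y_snaps = sorted(set(y_snaps) | {-core, core})
        half = p.thread_pitch / 2
        k = 1
        while k * half < p.implant_length - 1e-9:
            z_snaps.append(k * half)
            k += 1

    m = p.refine_margin
    if p.axial_window is not None:
        x_band = [(-p.axial_window, p.axial_window)]
    else:
        x_band = [(-R, R)]
    y_band = [(-(p.canal_radius + m), p.canal_radius + m)]
    z_band = [(max(0.0, p.implant_length - m), min(L, zc + p.canal_radius + m))]

    g = p.global_element_size
    x_lo = 0.0 if p.symmetry == "quarter" else -R
    y_lo = 0.0 if p.symmetry in ("half", "quarter") else -R
    x_lines = _interval_lines(x_lo, R, x_snaps, _band_size_fn(g, band_element_size, x_band))
    y_lines = _interval_lines(y_lo, R, y_snaps, _band_size_fn(g, band_element_size, y_band))
    z_lines = _interval_lines(p.stack_top, L, z_snaps,
                              _band_size_fn(g, band_element_size, z_band))

    nx, ny, nz = len(x_lines), len(y_lines), len(z_lines)
    n_cells = (nx - 1) * (ny - 1) * (nz - 1)
    if 6 * n_cells > MAX_TETS:
        raise GeometryError(
            f"requested resolution would produce ~{6 * n_cells} tets "
            f"(> {MAX_TETS}); coarsen the element sizes")

    # --- cell classification (pre-map square coordinates) ----------------
    xc = 0.5 * (x_lines[:-1] + x_lines[1:])
    yc = 0.5 * (y_lines[:-1] + y_lines[1:])
    zcell = 0.5 * (z_lines[:-1] + z_lines[1:])
    U, V, Z = np.meshgrid(xc, yc, zcell, indexing="ij")
    U, V, Z = U.ravel(), V.ravel(), Z.ravel()
    Mring = np.maximum(np.abs(U), np.abs(V))
    rho = np.hypot(U, V)
    scale = np.where(rho > 0, Mring / np.where(rho > 0, rho, 1.0), 1.0)
    Ymap = V * scale  # physical y of the cell centre

    region = np.full(U.shape, -1, dtype=np.int16)
    below = Z >= 0
    canal_r2 = (Z - zc) ** 2 + Ymap ** 2
    region[below & (canal_r2 <= p.nerve_radius ** 2)] = Region.NERVE
    sel = below & (region == -1) & (canal_r2 <= p.canal_radius ** 2)
    region[sel] = Region.CANAL
    sel = below & (region == -1) & (Mring <= p.implant_radius) & (Z <= p.implant_length)
    if p.thread_depth > 0:
        sel &= ~(p.in_groove(Z) & (Mring > p.implant_radius - p.thread_depth))
    region[sel] = Region.IMPLANT
    cort = below & (region == -1) & (Z <= p.cortical_thickness)
    if p.lateral_cortical:
        cort |= below & (region == -1) & (Mring >= R - p.cortical_thickness)
    region[cort] = Region.CORTICAL
    region[below & (region == -1)] = Region.TRABECULAR
    stack = ~below & (Mring <= p.implant_radius)
    region[stack & (Z >= -p.crown_height)] = Region.CROWN
    region[stack & (Z < -p.crown_height)
           & (Z >= -(p.crown_height + p.composite_height))] = Region.COMPOSITE
    region[stack & (Z < -(p.crown_height + p.composite_height))] = Region.BOLUS

    keep = region >= 0
    cell_region = region[keep]

    # --- node numbering for kept cells -----------------------------------
    ii, jj, kk = np.unravel_index(np.nonzero(keep)[0], (nx - 1, ny - 1, nz - 1))

    def gid(i, j, k):
        return (k.astype(np.int64) * ny + j) * nx + i

    corners = np.empty((len(ii), 8), dtype=np.int64)
    for b in range(8):
        di, dj, dk = b & 1, (b >> 1) & 1, (b >> 2) & 1
        corners[:, b] = gid(ii + di, jj + dj, kk + dk)

    used, inv = np.unique(corners, return_inverse=True)
    corners_local = inv.reshape(corners.shape).astype(np.int32)

    gk, rem = np.divmod(used, np.int64(nx * ny))
    gj, gi = np.divmod(rem, np.int64(nx))
    u = x_lines[gi]
    v = y_lines[gj]
    z = z_lines[gk]
    mring = np.maximum(np.abs(u), np.abs(v))
    rho_n = np.hypot(u, v)
    s = np.where(rho_n > 0, mring / np.where(rho_n > 0, rho_n, 1.0), 1.0)
    nodes = np.column_stack([u * s, v * s, z])
    on_outer = np.isclose(mring, R, atol=1e-9)

    # --- Kuhn subdivision -------------------------------------------------
    tets = corners_local[:, _KUHN].reshape(-1, 4)
    tet_region = np.repeat(cell_region, 6)
    vols = _tet_volumes(nodes, tets)
    flip = vols < 0
    if np.any(flip):
        t = tets[flip]
        t[:, [2, 3]] = t[:, [3, 2]]
        tets[flip] = t

    mesh = TetMesh(nodes=nodes, tets=tets.astype(np.int32),
                   region=tet_region.astype(np.int16),
                   facets={}, nerve_interface=None, params=p)
    _tag_facets(mesh, p, on_outer)
    return mesh


def _face_table(tets: np.ndarray):
    """All faces (sorted node triples), owner tet ids, grouping."""
    f = tets[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3)
    owner = np.repeat(np.arange(len(tets), dtype=np.int64), 4)
    fs = np.sort(f, axis=1)
    order = np.lexsort((fs[:, 2], fs[:, 1], fs[:, 0]))
    fs, owner = fs[order], owner[order]
    new = np.ones(len(fs), dtype=bool)
    new[1:] = np.any(fs[1:] != fs[:-1], axis=1)
    group = np.cumsum(new) - 1
    counts = np.bincount(group)
    return fs, owner, group, counts


def _tag_facets(mesh: TetMesh, p: ModelParams, on_outer: np.ndarray) -> None:
    fs, owner, group, counts = _face_table(mesh.tets)
    cnt = counts[group]
    z = mesh.nodes[:, 2]
    tol = 1e-9

    boundary = cnt == 1
    bf, bo = fs[boundary], owner[boundary]
    zf = z[bf]
    top = np.all(np.abs(zf - p.stack_top) < tol, axis=1)
    bottom = np.all(np.abs(zf - p.block_length) < tol, axis=1)
    lateral = np.all(on_outer[bf], axis=1)
    breg = mesh.region[bo]

    facets = {
        BOLUS_TOP: bf[top],
        BLOCK_BOTTOM: bf[bottom & np.isin(breg, [Region.CORTICAL, Region.TRABECULAR])],
        BLOCK_LATERAL: bf[lateral & np.isin(breg, [Region.CORTICAL, Region.TRABECULAR])],
        NERVE_ENDS: bf[lateral & (breg == Region.NERVE)],
    }
    if p.symmetry == "quarter":
        xz = np.all(np.abs(mesh.nodes[:, 0][bf]) < tol, axis=1)
        facets[SYMMETRY_X] = bf[xz]
    if p.symmetry in ("half", "quarter"):
        yz = np.all(np.abs(mesh.nodes[:, 1][bf]) < tol, axis=1)
        facets[SYMMETRY_Y] = bf[yz]

    # nerve surface: interior faces with exactly one nerve-side tet
    interior = cnt == 2
    fi, oi, gi = fs[interior], owner[interior], group[interior]
    # pairs are adjacent after the lexsort
    t1, t2 = oi[0::2], oi[1::2]
    tri = fi[0::2]
    r1, r2 = mesh.region[t1], mesh.region[t2]
    is_n1 = (r1 == Region.NERVE) & (r2 != Region.NERVE)
    is_n2 = (r2 == Region.NERVE) & (r1 != Region.NERVE)
    nerve_tet = np.concatenate([t1[is_n1], t2[is_n2]])
    outer_tet = np.concatenate([t2[is_n1], t1[is_n2]])
    tris = np.concatenate([tri[is_n1], tri[is_n2]])
    facets[NERVE_SURFACE] = tris
    mesh.facets = facets
    mesh.nerve_interface = NerveInterface(tris=tris, nerve_tet=nerve_tet,
                                          outer_tet=outer_tet)


@dataclass
class MeshReport:
    """Outcome of :func:`validate_mesh` (report-only, never raises)."""

    ok: bool
    checks: dict[str, bool]
    metrics: dict[str, float]
    messages: list[str] = field(default_factory=list)


def validate_mesh(mesh: TetMesh, volume_rtol: float | None = None) -> MeshReport:
    """Orientation, conformity, tag coverage and quality diagnostics.

    ``volume_rtol`` bounds the volume/area agreement with the analytic
    solid; by default it is 2% at the reference 0.5 mm resolution and
    scales quadratically with grid size (the inscribed-polygon area
    deficit of a circle of radius r meshed at spacing h is ~(h/r)^2/6).
    """
    if volume_rtol is None:
        h = mesh.params.global_element_size if mesh.params else 0.5
        volume_rtol = 0.02 * max(1.0, (h / 0.5) ** 2)
    checks: dict[str, bool] = {}
    metrics: dict[str, float] = {}
    messages: list[str] = []

    vols = mesh.tet_volumes()
    metrics["min_volume"] = float(vols.min()) if len(vols) else 0.0
    bad = np.nonzero(vols <= 0)[0]
    checks["positively_oriented"] = len(bad) == 0
    if len(bad):
        messages.append(f"non-positive tets: {bad[:10].tolist()}"
                        + ("..." if len(bad) > 10 else ""))

    _, _, _, counts = _face_table(mesh.tets)
    checks["conforming"] = bool(np.all(counts <= 2))
    if not checks["conforming"]:
        messages.append("faces shared by more than two tets")

    present = set(np.unique(mesh.region).tolist())
    if mesh.params is not None:
        expected = {int(r) for r in Region}
        checks["all_regions_present"] = expected <= present
        missing = expected - present
        if missing:
            messages.append(f"missing regions: {sorted(Region(r).name for r in missing)}")

        geom = build_model(mesh.params)
        analytic = geom.total_volume()
        total = float(vols.sum())
        metrics["total_volume"] = total
        metrics["analytic_volume"] = analytic
        checks["volume_match"] = abs(total - analytic) <= volume_rtol * analytic

        a_top = mesh.facet_area(BOLUS_TOP)
        a_exp = (math.pi * mesh.params.implant_radius ** 2
                 / mesh.params.symmetry_factor)
        metrics["bolus_top_area"] = a_top
        checks["bolus_top_area"] = abs(a_top - a_exp) <= volume_rtol * a_exp

    # shape quality: mean-ratio metric, 1 for the regular tet
    edges = mesh.tets[:, [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]]]
    d = mesh.nodes[edges[..., 0]] - mesh.nodes[edges[..., 1]]
    l2 = np.sum(d * d, axis=2).sum(axis=1)
    with np.errstate(invalid="ignore"):
        q = 12.0 * np.cbrt(9.0 * np.maximum(vols, 0.0) ** 2) / l2
    metrics["min_quality"] = float(q.min()) if len(q) else 0.0
    checks["quality_floor"] = metrics["min_quality"] > 1e-3

    ok = all(checks.values())
    return MeshReport(ok=ok, checks=checks, metrics=metrics, messages=messages)


def refine_near(params: ModelParams, tags, target_size: float,
                axial_window: float | None = None) -> TetMesh:
    """Regenerate the mesh with elements near the named regions at or
    below ``target_size`` (median-edge bound, mm).

    ``tags`` names the regions of interest (nerve/canal/bone); the
    refined band covers the canal neighbourhood that contains them.
    ``axial_window`` optionally limits the refined band along the canal
    axis (used by the adaptive solver to focus under the implant).
    """
    if target_size <= 0:
        raise GeometryError("target_size must be > 0")
    p = params.with_(axial_window=axial_window)
    geom = build_model(p)
    return generate_mesh(geom, p, band_element_size=target_size)


def box_mesh(lx: float, ly: float, lz: float, n: tuple[int, int, int],
             region: int = Region.TRABECULAR) -> TetMesh:
    """Single-material rectangular block, for solver verification.

    Facet tags reuse the production names: BOLUS_TOP (z=0 face, where
    load is applied), BLOCK_BOTTOM (z=lz), BLOCK_LATERAL (sides).
    """
    nx, ny, nz = n
    x = np.linspace(-lx / 2, lx / 2, nx + 1)
    y = np.linspace(-ly / 2, ly / 2, ny + 1)
    z = np.linspace(0.0, lz, nz + 1)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def gid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    cells = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                cells.append([gid(i + (b & 1), j + ((b >> 1) & 1), k + ((b >> 2) & 1))
                              for b in range(8)])
    corners = np.asarray(cells, dtype=np.int64)
    tets = corners[:, _KUHN].reshape(-1, 4)
    vols = _tet_volumes(nodes, tets)
    flip = vols < 0
    t = tets[flip]
    t[:, [2, 3]] = t[:, [3, 2]]
    tets[flip] = t

    mesh = TetMesh(nodes=nodes, tets=tets.astype(np.int32),
                   region=np.full(len(tets), region, dtype=np.int16),
                   facets={}, nerve_interface=NerveInterface(
                       np.empty((0, 3), np.int64), np.empty(0, np.int64),
                       np.empty(0, np.int64)),
                   params=None)
    fs, owner, group, counts = _face_table(mesh.tets)
    boundary = counts[group] == 1
    bf = fs[boundary]
    zf = nodes[bf][:, :, 2]
    tol = 1e-12
    top = np.all(np.abs(zf - 0.0) < tol, axis=1)
    bottom = np.all(np.abs(zf - lz) < tol, axis=1)
    mesh.facets = {
        BOLUS_TOP: bf[top],
        BLOCK_BOTTOM: bf[bottom],
        BLOCK_LATERAL: bf[~top & ~bottom],
    }
    return mesh
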