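# Methods

## Problem

A 4 mm ("ultra-short") dental implant in the atrophic posterior
mandible can sit within fractions of a millimetre of the mandibular
canal.  Occlusal loading then transmits pressure through the residual
bone to the inferior alveolar nerve (IAN); sustained compression of
100–200 mmHg (0.013–0.026 MPa) is the band in which nerve conduction
can block.  The package quantifies the maximum compressive normal
traction on the nerve surface as a function of (i) the implant-apex to
canal distance *d* and (ii) trabecular bone stiffness, and classifies
each configuration as safe (p < 0.026 MPa, strict) or not.

## Bone-stiffness calibration

Trabecular stiffness is derived from CT attenuation (Hounsfield units)
through the standard densitometric chain: radiographic density
ρ_QCT = −0.016404 + 0.00085164·HU, ash density
ρ_ASH = 0.079 + 0.877·ρ_QCT, apparent density ρ_APP = ρ_ASH/0.6
(all g/cm³), and E = 4730·ρ_APP^1.56 MPa, equivalently
E = 10494·ρ_ASH^1.56 (the 1/0.6 ratio folded into the coefficient;
4730·(1/0.6)^1.56 = 10494 to the nearest integer, so the two routes
agree to < 0.1 %).  HU below the ρ_QCT zero-crossing (~19.3) are
rejected as invalid CT input rather than clamped.

All chained evaluations keep full double precision; rounding (3 d.p.
densities, 1 d.p. GPa moduli) and the truncating mmHg→MPa display
(0.0266644 → 0.026) are presentation-layer only.  Note a reference
quirk the package reproduces deliberately *by not reproducing it*: the
published 14-grade table prints round moduli (4.5/7.5/8.5/9.5 GPa) at
HU = 700/1000/1100/1175 where the forward chain gives 4.6/7.6/8.7/9.6
GPa — those grades were evidently chosen as round stiffness targets
with approximate back-solved HU.  The forward chain is authoritative
here; the discrepancy is bounded by 0.2 GPa and covered in the tests.

## Geometry and its defaults

Units are N–mm–MPa; the origin is the block-top centre, z points down
the implant axis, x along the canal.  Defaults (all configurable):

| parameter | default | note |
|---|---|---|
| bone block | Ø 8 × 8 mm cylinder | simplified cortical+trabecular block |
| cortical layer | 1.0 mm crestal | thickness unreported in references; 1 mm is typical for the atrophic posterior mandible; optional lateral sheath |
| implant | Ø 4 × 4 mm, smooth | thread geometry is proprietary; bulk stiffness carries the load path; parametric ridges available |
| crown / composite / bolus | 6 / 1 / 2 mm, Ø 4 mm | only the transmitted 200 N resultant matters in a linear model |
| canal / nerve | Ø 2.5 / Ø 2.0 mm | anatomical ranges; canal runs horizontally, its roof *d* below the implant apex; the thin annulus is soft tissue (region CANAL) |
| d | 1.5 / 0.5 / 0.1 mm study grid | any d > 0; d = 0 (contact) rejected |

Materials (Young's modulus, Poisson ratio): bolus 3400 MPa/0.10,
zirconia crown 200000/0.30, composite 13800/0.30, Ti-6Al-4V implant
113000/0.35, cortical bone 13700/0.30, trabecular bone 4500/0.30
(swept 0.2–10.5 GPa via the calibration grades), nerve and canal
tissue 1.3/0.40.  All interfaces are bonded (shared nodes): contact
mechanics would contradict the linear static analysis.

## Meshing

No unstructured tet mesher is bundled; the mesh is a structured
tensor-product grid with three properties that make it adequate for
this geometry:

1. **interface snapping** — grid planes are placed at every material
   interface (layer boundaries, implant radius, canal/nerve tangent
   planes), so no region is lost at coarse resolution;
2. **square-to-disk mapping** — (x,y) ↦ (x,y)·max(|x|,|y|)/‖(x,y)‖
   maps the square ring max(|x|,|y|) = c onto the circle of radius c;
   with grid lines at the implant and block radii both lateral
   surfaces become true inscribed-polygon cylinders (area/volume error
   ~(h/r)²/6, ≈ 0.6 % at the 0.5 mm reference resolution);
3. **Kuhn 6-tet subdivision** — every hex splits around the same main
   diagonal, which is conforming across cells by construction.

The horizontal canal and nerve cylinders are voxel-approximated in the
transverse plane (snapped tangent planes, staircase arc).  Meshing is
a pure function of the parameters — identical input gives a
byte-identical mesh.  `validate_mesh` checks orientation, conformity,
region presence, analytic-volume and tag-area agreement (tolerance
scaled by (h/0.5)²) and a mean-ratio shape-quality floor.

Refinement targets are *median-edge* bounds: refined bands use grid
spacing target/√2 because Kuhn tets carry √2-length face diagonals.
The refined band covers the canal neighbourhood (y within the canal
radius + margin, z from the implant apex to below the canal), with an
optional axial window to focus under the implant where the pressure
maximum sits.

Because geometry, load and supports have two mirror planes (x = 0 and
y = 0), `symmetry="half"`/`"quarter"` meshes the reduced domain with
roller conditions on the cut planes and a proportionally reduced load;
production sweeps use the quarter model (4× fewer unknowns at equal
resolution; agreement with the full model is within discretisation
error, verified in the tests).

## FE solver

Standard small-strain isotropic elasticity with 4-node constant-strain
tetrahedra: K_e = V·BᵀDB assembled sparsely; uniform pressure on the
bolus top as consistent nodal loads (resultant exact to machine
precision); Dirichlet constraints by row/column elimination (exact,
conditioning preserved) on the block bottom, the lateral bone surface
and the nerve end cross-sections.  Fixing only the nerve *ends* (not
its whole surface) preserves a meaningful bone→nerve load path; a
config flag allows the alternative.  The reduced SPD system is
factorised with SuperLU in symmetric mode (MMD-ordered; scipy ships no
sparse Cholesky), with a diagonally preconditioned CG fallback;
relative residuals ≤ 1e−8 are enforced, and global equilibrium
(applied + reactions) must close to 1e−6 relative on every solve.

### Adaptive convergence

The convergence loop starts from the uniform 0.5 mm mesh and shrinks
the refined-band target by a fixed factor (default 0.7) until three
interface quantities each change by < 10 % between successive meshes:
the maximum nerve-surface pressure (the clinical measurand) and the
area-weighted mean von Mises stress and mean equivalent elastic strain
over the interface evaluation elements.  Interface quantities — not
global maxima — are tracked deliberately: the reentrant implant-apex
corner is a genuine elastic singularity whose pointwise stress cannot
converge under refinement, and facet-wise *maxima* of stiff-side
staircase samples oscillate with the mesh, whereas the integral
interface metrics and the compliant-side pressure maximum settle.
Hitting the size floor or mesh cap without meeting the rule returns
the result flagged `converged=False`, never silently.

## Pressure readout

The nerve-surface pressure is p = −n·σ·n per facet, n the outward
nerve-to-bone normal, compression positive.  Traction is continuous
across a bonded interface, so either adjacent element can supply σ;
numerically the *compliant* side is reliable: its stress is
modulus-scaled from (continuous) displacements, while the stiff side
multiplies O(1e−4)-level strain differences by a modulus four orders
larger.  Each facet is therefore evaluated from the canal-side soft
tissue element, falling back to the nerve-side element at staircase
corners where bone abuts the nerve directly.  Tensile facets are kept
in the distribution but excluded from the headline maximum (the
conduction-block band refers to compression); a tensile fraction
above 5 % triggers a warning.  Equivalent elastic strain uses the
effective-Poisson convention ε_eq = √(½Σ(ε_i−ε_j)²)/(1+ν) with the
element's elastic ν, matching the display convention of commercial FE
packages.

## Parametric sweep

`run_sweep` executes every distance × stiffness combination (default
3 × 14 = 42 cases), each through its own adaptive loop (no mesh reuse
across stiffness grades), records failures per case, and classifies
with strict p < threshold.  `monotonicity_report` checks the expected
physics: pressure non-increasing in E at each distance; pressure
non-decreasing as d shrinks, within a 10 % tolerance; near-overlap of
the two closest-distance curves quantified as a max relative gap
(pass ≤ 0.25).  Changing only the threshold reclassifies cached
pressures without re-solving.

## Problem sizes used by the tests and the acceptance script

Unit tests run the geometry at a 1 mm grid (~10⁴ tets, < 1 s per
solve).  The acceptance pipeline runs the quarter model from the
0.5 mm start mesh down to a 0.18 mm band target (≲ 1.5·10⁵ tets,
minutes per case on one CPU), with the refinement window focused
axially (|x| ≤ 2 mm) under the implant.  These sizes were chosen as
the point where the stiff-bone pressure readout changes by only a few
percent per refinement step; the safety margin of the stiff-bone
cases (pressure ≈ 0.001–0.002 MPa vs threshold 0.026 MPa) is an order
of magnitude wider than any remaining discretisation drift.

## What the synthetic model does and does not capture

It captures the load path and the soft-inclusion mechanics that
control nerve pressure: a compliant canal embedded in much stiffer
bone sees normal tractions scaled down by roughly the tissue/bone
modulus ratio, which is why stiff bone yields ~0.001 MPa while
0.2 GPa bone approaches the threshold decade.  It does **not**
capture: thread-level stress concentrations (the published field
maxima, e.g. ~22.7 MPa cortical von Mises, depend on proprietary CAD
and are order-of-magnitude context only), patient-specific anatomy,
anisotropic or nonlinear tissue, dynamic/repetitive loading, or nerve
physiology (the 30–60 s exposure criterion is metadata).  Passing
tests therefore demonstrate correct mechanics of the simplified
model, not clinical validity.

## Numerical notes

* Mesh degeneracy: inverted/degenerate tets are rejected at element
  level; a memory guard refuses grids beyond 2.5M tets before
  allocation.
* Ties and edge cases: canal and nerve tissue share a modulus, so the
  compliant-side rule resolves ties toward the canal side; a fully
  tensile nerve surface reports a headline maximum of 0 with the full
  signed distribution retained.
* Determinism: there is no randomness anywhere in the pipeline;
  repeated runs produce byte-identical meshes, CSV and JSON.
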