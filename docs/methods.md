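# Methods

This note documents the models, algorithms and numerical choices behind
`capforge`, what the synthetic phantoms do and do not emulate, and the known
limitations.

## Coordinate conventions

All geometry is in millimeters. The canonical head frame has its origin at
the midpoint of the preauricular points, x along the LPA–RPA axis, y toward
the nasion (orthogonalized) and z = x × y through the vertex. Because input
meshes may come in either anatomical handedness, the vertex guess Cz0
disambiguates: if z would point away from Cz0, the x-axis is flipped
(RPA→LPA) so the frame stays right-handed with z up. The face/neck/ear
margin boxes are axis-aligned in this frame, which makes them well defined
for arbitrarily oriented input meshes; all box definitions are symmetric in
x, so the handedness flip does not change the cut.

## Landmark construction

Cross-sections are computed as exact plane/mesh intersection loops (every
triangle–plane crossing point, chained into closed polylines). Curve
distance is measured along the polyline; no spline smoothing is applied.
With mesh refinement the polyline length converges quadratically to the
smooth section length, and on a density-5 sphere of radius 100 mm the
residual landmark error is below 0.03 mm — comfortably inside the accuracy
with which fiducials can be clicked on real anatomy.

The vertex iteration alternates coronal-then-sagittal midpoint updates and
stops when successive Cz estimates move less than `tol` (default 10⁻⁶ mesh
units). The fixed point is order-independent; the iterate path is not,
which is why the order is fixed and documented. On sphere and ellipsoid
phantoms the iteration contracts essentially in one step (2 iterations to
10⁻⁶).

Montages are data: a `CurveRecipe` lists construction curves as triples of
already-placed anchor labels plus (fraction, label) placements, with the
fiducials and the converged Cz pre-placed. The built-in recipes follow the
modern standard nomenclature (T7/T8/P7/P8 primary; T3/T4/T5/T6 accepted as
aliases): reference rows at 10% steps, the 10% ring labeled at 10% steps of
each half-arc, intermediate F/FC/CP/P rows subdivided in equal quarters per
half-arc, sparse AF/PO rows at quarter points. The 10-5 recipe extends
10-10 with half-step positions on the reference rows (standard intermediate
names such as AFpz, FFCz; C-row 'h' names) and on the 10% ring, where no
standard short names exist and systematic neighbor-concatenated names are
used. Any exact grid can be swapped in by passing a custom recipe; nesting
(10-20 ⊂ 10-10 ⊂ 10-5 with identical shared positions) holds for the
built-ins by construction.

Arc endpoints snap to the nearest point on the loop polyline; the snapping
tolerance is twice the loop's mean segment length, reflecting that
fiducials are clicked near, not on, mesh vertices.

## Cap construction

Landmarks are always computed on the original fine surface; the cap body is
then decimated and landmarks are re-registered by exact nearest-point
queries, so landmark accuracy does not depend on cap coarseness.

*Decimation* is shortest-edge collapse to the midpoint with a link-condition
check (closedness is preserved) and a normal-flip guard; surviving vertices
are finally re-projected onto the input surface, which removes the inward
drift of midpoint collapses (two-sided sampled Hausdorff distance at
keep-ratio 0.05 on the density-5 sphere: 0.9 mm ≈ 0.9% of the radius). A
dual-mesh transform (face centroids → polygon per vertex) is available for
polygonal cap aesthetics.

*Cuts are exact, not Boolean-engine based.* Every cutter the pipeline uses
— circular grommet prisms (a swept regular polygon, 24 segments by
default) and margin boxes — is convex, so subtracting it from a triangle
surface reduces to per-triangle plane clipping: a triangle minus a convex
polytope is the disjoint union over planes i of (triangle ∩ outside(i) ∩
inside(1..i−1)), each piece a convex polygon obtained by Sutherland–Hodgman
clipping. The decomposition is exact but not conforming across seams, so a
T-junction stitching pass splits boundary edges at boundary vertices lying
on them; after stitching, the only boundary loops are the design holes
(verified: exactly one rim per grommet). An axis-aligned-bounding-box
prefilter keeps far faces untouched.

Grommet cutters are centered on the registered landmark and aligned with
the outward surface normal (barycentric blend of vertex normals at the
nearest face). Default cutter depth is 20 mm = 8 × the default wire
thickness, centered on the surface, guaranteeing full penetration after
wireframing.

*Margins.* The face box is centered (in x) on the nasion, x-width = head
width / 3, reaching from below the chin up to a fraction (default 0.25) of
the nasion→vertex height — the default keeps the 10% ring (Fpz, Fp1/Fp2)
intact, as in printed cap designs. The neck box spans the full x/y extent
over the lower third of the head height. Optional ear cut-outs are boxes
above each preauricular point (defaults: 25% of head depth wide, 15% of
head height tall); their sizes are exposed parameters since no standard
values exist. Cuts that would remove the vertex or more than 60% of the
surface are rejected.

*Margin thickening* tags edges with an endpoint within `margin_band_width`
(default 10 mm) of an exterior boundary loop for double wire thickness.
Only long loops (≥ 25% of the longest boundary loop) count as exterior
margin so grommet rims are not thickened.

*Wireframe extrusion* replaces each retained edge by a cylindrical strut of
diameter `wire_thickness` (doubled at tagged edges) with spherical joints
at shared vertices. The standalone operation refuses a thickness exceeding
half the shortest edge (a lattice-density sanity check); inside the
pipeline this check is advisory only, because hole rims legitimately carry
short clipped edges whose overlapping struts fuse in the re-tessellation.
The strut skeleton (segments, radii, joints) is attached as metadata.

## Printability

`remesh_solidify` evaluates the exact signed distance field of the
capsule/sphere skeleton on a regular grid (pitch ≤ wire_thickness / 4;
distances computed only in per-primitive local blocks) and runs marching
cubes at level 0. This resolves all strut–strut intersections into one
manifold surface with sub-pitch geometric error. A filled binary
voxelization is the fallback for meshes without a skeleton.

`repair` welds vertices (single-linkage clusters), removes degenerate
elements by collapsing their shortest edge (deleting them would open
slit-shaped holes), fills boundary loops of ≤ 12 edges by centroid fans
(larger openings are design features — grommets, the face opening — and
abort the repair rather than being silently sealed), reorients faces
outward, and re-diagnoses. The default weld tolerance is 10⁻⁴ × the
bounding-box diagonal; because a tolerance that large can pinch narrow
crevices between adjacent struts into non-manifold edges, repair backs off
(default, exact weld, then decades between) until the census is clean.
Marching-cubes output occasionally contains micro-slits where the level
surface passes within float32 rounding of grid nodes; the collapse/fill
rounds close these without measurable volume change.

`diagnose` counts non-manifold edges, boundary edges, zero-area faces
(≤ 10⁻¹² × scale²), zero-length edges, duplicate vertices, inverted faces
(minimum flips to a consistent outward orientation, via parity BFS over the
face-adjacency graph) and self-intersecting face pairs (uniform-grid broad
phase with cell size = the maximum face extent, Möller interval narrow
phase, vertex-sharing pairs excluded). "Printable" means every count is
zero and the enclosed volume is positive.

## Surface extraction

Foreground = threshold (grayscale) or label selection (integer volumes;
default all non-zero); the largest 26-connected component is kept, interior
cavities are filled, and marching cubes runs at level 0.5 on a σ = 1 voxel
Gaussian-smoothed indicator, in physical (mm) coordinates. Taubin smoothing
(λ = 0.5, μ = −0.53, default 5 iterations) removes voxel staircase without
shrinkage. Triangle density honors the stated contract — maximum
circumscribed-circle radius ≤ `max_circumradius` — by uniform subdivision
(each round halves every circumradius); the iso-surfacing internals of
dedicated ϵ-sampling meshers are not reproduced, only the density contract.
Foreground touching the grid boundary is rejected with advice to pad.

## Metrology

Circumference is the length of the closed 10% ring (Fpz–T7–Oz–T8) — the
standard cap-sizing ring — with a logged fallback to the Nz/LPA/Iz plane
when ring landmarks are absent. Radial projection uses rays from the
preauricular midpoint and takes the first intersection beyond the center.
Validation distances run along the sagittal reference curve from Iz and the
coronal curve from RPA; measured points (grommet-hole rim centroids,
perimeter-weighted) are projected to their closest curve positions. The
error report gives the coefficient of determination of measured vs
reference distances plus mean and SD of the absolute error. The
human-subject procedure of separate sagittal/coronal scalings is *not*
implemented — only the single-center radial projection; the former's exact
formula is not standardized.

## Phantoms and what they show

Sphere and ellipsoid phantoms (icosphere triangulations, fiducials at axis
intersections, Cz0 deterministically tilted 30° from the pole at a fixed
azimuth) have closed-form (sphere) or dense-sampling-oracle (ellipsoid)
landmark positions: every cross-section of a plane with an ellipsoid maps
to a circle on the unit sphere, which the oracle samples uniformly
(default 10⁵ points per curve) and processes with standalone arc/fraction
code, fully independent of the production curve machinery. Voxel-ball
volumes exercise extraction.

Phantoms are smooth, convex and symmetric; real heads are none of these.
Passing phantom tests therefore demonstrates the correctness of the
geometric construction (arc-length subdivision, bisection, cutting,
solidification) and its numerical accuracy, not robustness to anatomical
features like ears, nose or hair, nor to segmentation noise — for those,
the margin cuts and snapping tolerances are the relevant knobs.

## Problem sizes and determinism

Default demo/validation sizes: landmark accuracy on the density-5 sphere
(10 242 vertices); the end-to-end printable build on the density-4 sphere
(2 562 vertices → 5% edges kept → ~1.1 M faces after re-tessellation at
0.625 mm pitch), chosen as a representative cap at ordinary print
resolution. Everything is deterministic: identical inputs and
configuration give byte-identical landmark JSON and defect reports; the
only randomness anywhere (test rotations, seeded-defect fixtures) takes
explicit seeds.

## Known limitations

* Grommet outlines are regular polygons (24 segments ≈ circle); arbitrary
  outline curves are not supported.
* The wireframe uses round struts and spherical joints; the square
  cross-section option is approximated by the round one's diameter.
* Repair handles the defect classes produced by this pipeline; it is not a
  general mesh-fixing tool (e.g. it aborts on large holes by design).
* Landmark systems denser than 10-5 and custom per-optode mounting
  interfaces are out of scope; the recipe mechanism is the extension point.
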