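"""Cap construction: turn a head surface + landmark set into an open
wireframe cap with grommet holes and ergonomic margin cuts.

Pipeline order (landmark accuracy must not depend on cap coarseness):
landmarks are computed on the original fine surface, the cap body is
coarsened by edge-collapse decimation, landmarks are registered onto the
coarse body by proximity, grommet cutter solids are instanced along the
surface normals and subtracted, then face/neck/ear margin boxes are
subtracted, margin edges are tagged for double thickness, and finally every
retained edge is extruded into a round strut.

Cuts are exact: the cutters used here (boxes and polygonal prisms) are convex,
so subtracting one from a triangle surface reduces to per-triangle plane
clipping (Sutherland-Hodgman), which needs no general Boolean engine.  The
strut union is resolved later by :func:`capforge.printable.remesh_solidify`.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np
import trimesh

from .errors import TopologyError, ValidationError
from .geometry import CanonicalFrame, closest_point_on_mesh, interpolated_normal, weld_vertices
from .landmarks import LandmarkSet
from .mesh_io import PolyMesh

log = logging.getLogger(__name__)

__all__ = [
    "GrommetSpec", "CapParams", "dual_mesh", "coarsen", "register_landmarks",
    "place_grommets", "cut_grommet_holes", "cut_margins", "margin_boxes",
    "point_in_any_box", "thicken_margin", "wireframe", "boundary_loops",
]

#: documented safe wire thickness range (mm); prints hold up best at 2.5-3.5
WIRE_RANGE = (0.5, 6.0)


@dataclass(frozen=True)
class GrommetSpec:
    """Landmark grommet cutter: a circle (regular-polygon outline) swept
    along the local surface normal."""

    shape: str = "circle"       # "circle" or "polygon"
    radius: float = 4.0         # mm (4 mm is the standard 10-10 grommet)
    cutter_depth: float = 20.0  # mm; >= 4x wire thickness so holes punch through
    sections: int = 24          # outline segments for circular grommets

    def __post_init__(self):
        if self.radius <= 0:
            raise ValidationError("grommet radius must be positive")
        if self.cutter_depth <= 0:
            raise ValidationError("cutter depth must be positive")
        if self.shape not in ("circle", "polygon"):
            raise ValidationError(f"unknown grommet shape {self.shape!r}")
        n_min = 3 if self.shape == "polygon" else 8
        if self.sections < n_min:
            raise ValidationError("grommet outline needs more sections")


@dataclass(frozen=True)
class CapParams:
    """User-tunable cap design parameters (lengths in mm)."""

    keep_ratio: float = 0.05
    wire_thickness: float = 2.5
    face_width_fraction: float = 1.0 / 3.0
    face_height_fraction: float = 0.25
    neck_height_fraction: float = 1.0 / 3.0
    ear_cutout: bool = False
    ear_width_fraction: float = 0.25
    ear_height_fraction: float = 0.15
    margin_band_width: float = 10.0

    def __post_init__(self):
        if not (0 < self.keep_ratio <= 1):
            raise ValidationError("keep_ratio must be in (0, 1]")
        lo, hi = WIRE_RANGE
        if not (lo <= self.wire_thickness <= hi):
            raise ValidationError(
                f"wire thickness {self.wire_thickness} outside safe range "
                f"[{lo}, {hi}] mm (2.5-3.5 mm recommended)")
        for name in ("face_width_fraction", "face_height_fraction",
                     "neck_height_fraction", "ear_width_fraction",
                     "ear_height_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.margin_band_width < 0:
            raise ValidationError("margin_band_width must be >= 0")


# ---------------------------------------------------------------------------
# dual mesh
# ---------------------------------------------------------------------------

def dual_mesh(mesh: trimesh.Trimesh) -> PolyMesh:
    """Dual polygonal mesh: one vertex per input face (centroid), one polygon
    per input vertex (ring of incident face centroids in cyclic order)."""
    if not mesh.is_watertight or not mesh.is_winding_consistent:
        raise TopologyError("dual transform requires a closed manifold mesh")
    centroids = mesh.triangles_center
    faces = mesh.faces.view(np.ndarray)
    nv = len(mesh.vertices)
    # for each vertex, map "entry neighbor" -> (exit neighbor, face id);
    # consistent winding makes the fan traversal well defined
    ring_next: list[dict[int, tuple[int, int]]] = [dict() for _ in range(nv)]
    for fid, (a, b, c) in enumerate(faces):
        ring_next[a][b] = (c, fid)
        ring_next[b][c] = (a, fid)
        ring_next[c][a] = (b, fid)
    polygons: list[list[int]] = []
    for v in range(nv):
        nxt = ring_next[v]
        if not nxt:
            continue
        start = next(iter(nxt))
        ring = []
        cur = start
        for _ in range(len(nxt)):
            out, fid = nxt[cur]
            ring.append(fid)
            cur = out
            if cur == start:
                break
        else:
            raise TopologyError(f"vertex {v} has a non-closed face fan")
        if len(ring) != len(nxt):
            raise TopologyError(f"vertex {v} has a non-manifold face fan")
        polygons.append(ring)
    return PolyMesh(vertices=centroids.copy(), faces=polygons)


# ---------------------------------------------------------------------------
# edge-collapse coarsening
# ---------------------------------------------------------------------------

def coarsen(mesh: trimesh.Trimesh, keep_ratio: float,
            report_hausdorff: bool = True) -> trimesh.Trimesh:
    """Shortest-edge-collapse decimation until the unique-edge count drops to
    ``keep_ratio`` of the input's, preserving closedness (link condition).

    The (sampled, two-sided) Hausdorff distance to the input is logged and
    stored in ``metadata['hausdorff_to_input']``.
    """
    if not (0 < keep_ratio <= 1):
        raise ValidationError("keep_ratio must be in (0, 1]")
    if not mesh.is_watertight:
        raise TopologyError("coarsen requires a closed mesh")
    e0 = len(mesh.edges_unique)
    target = int(np.ceil(keep_ratio * e0))
    if keep_ratio == 1.0:
        out = trimesh.Trimesh(vertices=mesh.vertices.copy(),
                              faces=mesh.faces.copy(), process=False)
        out.metadata["hausdorff_to_input"] = 0.0
        return out

    pos = mesh.vertices.copy()
    faces: dict[int, tuple[int, int, int]] = {
        i: tuple(f) for i, f in enumerate(mesh.faces)
    }
    v2f: dict[int, set[int]] = {i: set() for i in range(len(pos))}
    for fid, f in faces.items():
        for v in f:
            v2f[v].add(fid)

    def neighbors(v):
        out = set()
        for fid in v2f[v]:
            out.update(faces[fid])
        out.discard(v)
        return out

    heap: list[tuple[float, int, int]] = []
    for u, v in mesh.edges_unique:
        d = float(np.linalg.norm(pos[u] - pos[v]))
        heapq.heappush(heap, (d, int(u), int(v)))

    n_edges = e0
    alive = np.ones(len(pos), dtype=bool)
    while n_edges > target and heap:
        d, u, v = heapq.heappop(heap)
        if not (alive[u] and alive[v]):
            continue
        shared = v2f[u] & v2f[v]
        if len(shared) != 2:
            continue  # stale entry or boundary/non-manifold edge
        if len(faces) - 2 < 4:
            continue  # a closed surface needs at least a tetrahedron
        cur = float(np.linalg.norm(pos[u] - pos[v]))
        if abs(cur - d) > 1e-12 * max(cur, 1.0):
            heapq.heappush(heap, (cur, u, v))
            continue
        nu, nvb = neighbors(u), neighbors(v)
        opposite = set()
        for fid in shared:
            opposite.update(faces[fid])
        opposite -= {u, v}
        if nu & nvb != opposite:
            continue  # link condition violated; collapse would pinch
        midpoint = 0.5 * (pos[u] + pos[v])
        # reject collapses that flip face normals (fold-over guard)
        ok = True
        for fid in (v2f[u] | v2f[v]) - shared:
            f = faces[fid]
            p = [midpoint if w in (u, v) else pos[w] for w in f]
            n_new = np.cross(p[1] - p[0], p[2] - p[0])
            q = [pos[w] for w in f]
            n_old = np.cross(q[1] - q[0], q[2] - q[0])
            denom = np.linalg.norm(n_new) * np.linalg.norm(n_old)
            if denom == 0 or (n_new @ n_old) / denom < 0.0:
                ok = False
                break
        if not ok:
            continue
        # perform collapse: v merges into u at the midpoint
        pos[u] = midpoint
        for fid in shared:
            for w in faces[fid]:
                v2f[w].discard(fid)
            del faces[fid]
        for fid in list(v2f[v]):
            f = faces[fid]
            faces[fid] = tuple(u if w == v else w for w in f)
            v2f[v].discard(fid)
            v2f[u].add(fid)
        alive[v] = False
        n_edges -= 3
        for w in neighbors(u):
            heapq.heappush(
                heap, (float(np.linalg.norm(pos[u] - pos[w])), u, int(w)))

    if n_edges > target:
        raise ValidationError(
            f"keep_ratio {keep_ratio} unreachable while preserving a closed "
            f"surface; minimum achievable ratio is {n_edges / e0:.4f}")

    used = sorted({v for f in faces.values() for v in f})
    remap = {v: i for i, v in enumerate(used)}
    new_v = pos[used]
    # midpoint collapses drift inward on convex surfaces; snap the surviving
    # vertices back onto the input surface
    new_v, _, _ = closest_point_on_mesh(mesh, new_v)
    new_f = np.array([[remap[a], remap[b], remap[c]]
                      for a, b, c in faces.values()], dtype=np.int64)
    out = trimesh.Trimesh(vertices=new_v, faces=new_f, process=False)
    if not out.is_watertight:
        raise TopologyError("decimation lost closedness (internal error)")
    if report_hausdorff:
        h = _sampled_hausdorff(mesh, out)
        out.metadata["hausdorff_to_input"] = h
        log.info("coarsened %d -> %d edges (Hausdorff %.3f mm)",
                 e0, n_edges, h)
    return out


def _sampled_hausdorff(a: trimesh.Trimesh, b: trimesh.Trimesh,
                       n_samples: int = 2000) -> float:
    """Two-sided Hausdorff distance estimated from vertex + face samples."""

    def pick(m):
        pts = m.vertices
        if len(pts) > n_samples:
            idx = np.linspace(0, len(pts) - 1, n_samples).astype(int)
            pts = pts[idx]
        return np.vstack([pts, m.triangles_center[
            np.linspace(0, len(m.faces) - 1,
                        min(len(m.faces), n_samples)).astype(int)]])

    _, d_ab, _ = closest_point_on_mesh(b, pick(a))
    _, d_ba, _ = closest_point_on_mesh(a, pick(b))
    return float(max(d_ab.max(), d_ba.max()))


# ---------------------------------------------------------------------------
# landmark registration and grommets
# ---------------------------------------------------------------------------

def register_landmarks(landmarks: LandmarkSet, mesh: trimesh.Trimesh,
                       warn_distance: float = 5.0) -> LandmarkSet:
    """Snap every landmark to its nearest point on ``mesh`` (e.g. the
    coarsened cap body); snap distances are stored on the result."""
    labels = landmarks.labels()
    pts = landmarks.array()
    snapped, dist, _ = closest_point_on_mesh(mesh, pts)
    for lbl, d in zip(labels, dist):
        if d > warn_distance:
            log.warning("landmark %s snapped %.2f mm (> %.1f mm bound)",
                        lbl, d, warn_distance)
    return LandmarkSet(
        system=landmarks.system,
        positions=dict(zip(labels, snapped)),
        fiducials=landmarks.fiducials,
        snap_distances=dict(zip(labels, dist.astype(float))),
    )


def place_grommets(mesh: trimesh.Trimesh, landmarks: LandmarkSet,
                   spec: GrommetSpec | None = None) -> list[trimesh.Trimesh]:
    """One closed convex cutter solid per landmark: the grommet outline swept
    to ``cutter_depth``, centered at the landmark, axis along the outward
    surface normal (normal-aligned instancing)."""
    if spec is None:
        spec = GrommetSpec()
    pts = landmarks.array()
    labels = landmarks.labels()
    _, dist, fids = closest_point_on_mesh(mesh, pts)
    cutters = []
    for lbl, p, d, fid in zip(labels, pts, dist, fids):
        if d > 1e-6 * max(1.0, float(np.abs(mesh.bounds).max())):
            log.debug("grommet %s center is %.3g mm off-surface", lbl, d)
        normal = interpolated_normal(mesh, p, int(fid))
        transform = trimesh.geometry.align_vectors([0, 0, 1], normal)
        transform = transform.copy()
        transform[:3, 3] = p
        cutter = trimesh.creation.cylinder(
            radius=spec.radius, height=spec.cutter_depth,
            sections=spec.sections, transform=transform)
        cutter.metadata["landmark_label"] = lbl
        cutters.append(cutter)
    # overlap warning
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            if np.linalg.norm(pts[i] - pts[j]) < 2 * spec.radius:
                log.warning("grommet cutters %s and %s overlap",
                            labels[i], labels[j])
    return cutters


# ---------------------------------------------------------------------------
# exact surface-vs-convex-solid subtraction
# ---------------------------------------------------------------------------

def _planes_from_convex(solid: trimesh.Trimesh) -> np.ndarray:
    """Half-space representation (k, 4) rows [nx ny nz d], inside where
    n.x <= d, from a convex solid's face planes (coplanar faces merged)."""
    n = solid.face_normals
    d = np.einsum("ij,ij->i", n, solid.triangles_center)
    scale = max(float(np.abs(solid.bounds).max()), 1.0)
    key = np.round(np.column_stack([n, d / scale]), 6)
    _, idx = np.unique(key, axis=0, return_index=True)
    return np.column_stack([n, d])[np.sort(idx)]


def _clip_polygon(poly: np.ndarray, normal: np.ndarray, offset: float,
                  keep_positive: bool, eps: float) -> np.ndarray:
    """Sutherland-Hodgman clip of a planar 3D polygon against one plane."""
    d = poly @ normal - offset
    if not keep_positive:
        d = -d
    out = []
    n = len(poly)
    for i in range(n):
        j = (i + 1) % n
        di, dj = d[i], d[j]
        if di >= -eps:
            out.append(poly[i])
        if (di > eps and dj < -eps) or (di < -eps and dj > eps):
            t = di / (di - dj)
            out.append(poly[i] + t * (poly[j] - poly[i]))
    if len(out) < 3:
        return np.zeros((0, 3))
    return np.asarray(out)


def subtract_convex(mesh: trimesh.Trimesh, planes: np.ndarray,
                    aabb: np.ndarray | None = None,
                    eps_rel: float = 1e-9) -> trimesh.Trimesh:
    """Remove from a triangle surface the part inside the convex polytope
    given by half-spaces ``planes`` (inside where n.x <= d for every row).

    Exact per-triangle decomposition: a triangle minus a convex region is the
    disjoint union over planes i of (triangle in outside(i) and inside(1..i-1)),
    each piece a convex polygon clipped with Sutherland-Hodgman.  ``aabb``
    ((2, 3) lo/hi) bounds the polytope and prunes the faces considered; far
    faces are kept untouched.
    """
    scale = float(np.ptp(mesh.bounds)) or 1.0
    eps = eps_rel * scale
    verts = mesh.vertices.view(np.ndarray)
    faces = mesh.faces.view(np.ndarray)
    nrm = planes[:, :3]
    off = planes[:, 3]
    sd = verts @ nrm.T - off  # (V, k) signed distances
    face_sd = sd[faces]       # (F, 3, k)
    fully_out = (face_sd >= -eps).all(axis=1).any(axis=1)
    fully_in = ~fully_out & (face_sd <= eps).all(axis=(1, 2))
    crossing = ~(fully_out | fully_in)
    if aabb is not None:
        tri_xyz = verts[faces]
        near = (np.all(tri_xyz.max(axis=1) >= aabb[0] - eps, axis=1)
                & np.all(tri_xyz.min(axis=1) <= aabb[1] + eps, axis=1))
        crossing &= near
        fully_in &= near

    keep_faces = faces[~fully_in & ~crossing]
    new_tris: list[np.ndarray] = []
    for f in faces[crossing]:
        tri = verts[f]
        for i in range(len(planes)):
            piece = _clip_polygon(tri, nrm[i], off[i], keep_positive=True,
                                  eps=eps)
            for j in range(i):
                if len(piece) < 3:
                    break
                piece = _clip_polygon(piece, nrm[j], off[j],
                                      keep_positive=False, eps=eps)
            if len(piece) >= 3:
                for k in range(1, len(piece) - 1):
                    new_tris.append(
                        np.stack([piece[0], piece[k], piece[k + 1]]))

    parts_v = [verts]
    parts_f = [keep_faces]
    if new_tris:
        tri_arr = np.stack(new_tris)
        nv = len(verts)
        parts_v.append(tri_arr.reshape(-1, 3))
        parts_f.append(np.arange(tri_arr.shape[0] * 3).reshape(-1, 3) + nv)
    all_v = np.vstack(parts_v)
    all_f = np.vstack(parts_f)
    all_v, all_f = weld_vertices(all_v, all_f, tolerance=1e-7 * scale)
    all_v, all_f = _stitch_t_junctions(all_v, all_f, eps=1e-6 * scale)
    # drop sliver faces created by clipping
    out = trimesh.Trimesh(vertices=all_v, faces=all_f, process=False)
    good = out.area_faces > (1e-12 * scale * scale)
    out = trimesh.Trimesh(vertices=all_v, faces=all_f[good], process=False)
    out.remove_unreferenced_vertices()
    return out


def _stitch_t_junctions(vertices: np.ndarray, faces: np.ndarray,
                        eps: float, max_rounds: int = 8):
    """Split boundary edges at boundary vertices lying on their interior.

    The piecewise clipping decomposition is geometrically exact but its
    seams are not conforming: a seam edge on one side may be split on the
    other (a T-junction), which would masquerade as a boundary crack.
    Splitting every such edge restores a conforming mesh; only true design
    holes remain as boundary."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    for _ in range(max_rounds):
        sorted_e = np.sort(
            np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]],
                            faces[:, [2, 0]]]), axis=1)
        uniq, counts = np.unique(sorted_e, axis=0, return_counts=True)
        bedges = uniq[counts == 1]
        if len(bedges) == 0:
            return vertices, faces
        bverts = np.unique(bedges)
        a = vertices[bedges[:, 0]]
        b = vertices[bedges[:, 1]]
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        denom = np.where(denom == 0, 1.0, denom)
        # split points per boundary edge: boundary vertices on its interior
        splits: dict[tuple[int, int], list[tuple[float, int]]] = {}
        p = vertices[bverts]
        for ei, (i0, i1) in enumerate(bedges):
            t = np.einsum("j,ij->i", ab[ei], p - a[ei]) / denom[ei]
            interior = (t > 1e-9) & (t < 1 - 1e-9)
            if not interior.any():
                continue
            proj = a[ei] + t[:, None] * ab[ei]
            d = np.linalg.norm(proj - p, axis=1)
            hit = interior & (d <= eps) & (bverts != i0) & (bverts != i1)
            if hit.any():
                key = (int(i0), int(i1))
                splits[key] = sorted(
                    (float(tv), int(vv)) for tv, vv in
                    zip(t[hit], bverts[hit]))
        if not splits:
            return vertices, faces
        new_faces = []
        for f in faces:
            fa, fb, fc = (int(x) for x in f)
            done = False
            for (x, y, z) in ((fa, fb, fc), (fb, fc, fa), (fc, fa, fb)):
                key = (x, y) if x < y else (y, x)
                if key in splits:
                    chain = [v for _, v in splits[key]]
                    if key != (x, y):
                        chain = chain[::-1]
                    pts = [x] + chain + [y]
                    for i in range(len(pts) - 1):
                        new_faces.append((pts[i], pts[i + 1], z))
                    done = True
                    break
            if not done:
                new_faces.append((fa, fb, fc))
        faces = np.asarray(new_faces, dtype=np.int64)
    return vertices, faces


def cut_grommet_holes(mesh: trimesh.Trimesh,
                      cutters: list[trimesh.Trimesh]) -> trimesh.Trimesh:
    """Boolean-difference the grommet cutter array from the surface: one new
    boundary loop per cutter."""
    out = mesh
    for i, cutter in enumerate(cutters):
        try:
            planes = _planes_from_convex(cutter)
            out = subtract_convex(out, planes, aabb=cutter.bounds.copy())
        except Exception as exc:  # noqa: BLE001
            label = cutter.metadata.get("landmark_label", i)
            raise ValidationError(
                f"grommet subtraction failed for cutter {label!r}: {exc}"
            ) from exc
    return out


# ---------------------------------------------------------------------------
# margin cuts
# ---------------------------------------------------------------------------

def _box_planes(frame: CanonicalFrame, lo, hi) -> np.ndarray:
    """World-space half-space rows for an axis-aligned box in frame coords."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    planes = []
    for axis in range(3):
        for sign, bound in ((1.0, hi[axis]), (-1.0, lo[axis])):
            n_frame = np.zeros(3)
            n_frame[axis] = sign
            n_world = frame.rotation.T @ n_frame
            d = sign * bound + n_world @ frame.origin
            planes.append(np.concatenate([n_world, [d]]))
    return np.asarray(planes)


def margin_boxes(mesh: trimesh.Trimesh, fiducials,
                 params: CapParams) -> list[np.ndarray]:
    """Half-space sets of the face box, neck box and optional ear boxes, in
    world coordinates (each entry is a (6, 4) plane array)."""
    frame, boxes = _margin_box_defs(mesh, fiducials, params)
    return [_box_planes(frame, lo_i, hi_i) for lo_i, hi_i in boxes]


def _margin_box_defs(mesh: trimesh.Trimesh, fiducials, params: CapParams):
    frame = CanonicalFrame.from_fiducials(fiducials)
    v = frame.to_frame(mesh.vertices)
    lo, hi = v.min(axis=0), v.max(axis=0)
    size = hi - lo
    pad = 0.05 * float(size.max())
    nz = frame.to_frame(fiducials.nz[None, :])[0]
    cz_guess = hi[2]

    boxes = []
    # face box: width = head width / 3, centered (in x) on Nz, opening the face
    half_w = 0.5 * params.face_width_fraction * size[0]
    z_top = nz[2] + params.face_height_fraction * (cz_guess - nz[2])
    boxes.append((
        [nz[0] - half_w, nz[1] - 0.1 * size[1], lo[2] - pad],
        [nz[0] + half_w, hi[1] + pad, z_top],
    ))
    # neck box: full x/y extent, lower third of the head height
    boxes.append((
        [lo[0] - pad, lo[1] - pad, lo[2] - pad],
        [hi[0] + pad, hi[1] + pad, lo[2] + params.neck_height_fraction * size[2]],
    ))
    if params.ear_cutout:
        half_ear = 0.5 * params.ear_width_fraction * size[1]
        ear_h = params.ear_height_fraction * size[2]
        for fid_pt in (fiducials.lpa, fiducials.rpa):
            p = frame.to_frame(fid_pt[None, :])[0]
            if p[0] < 0:
                x_lo, x_hi = lo[0] - pad, lo[0] + 0.12 * size[0]
            else:
                x_lo, x_hi = hi[0] - 0.12 * size[0], hi[0] + pad
            boxes.append((
                [x_lo, p[1] - half_ear, p[2] - pad],
                [x_hi, p[1] + half_ear, p[2] + ear_h],
            ))
    return frame, boxes


def point_in_any_box(point, boxes: list[np.ndarray], tol: float = 0.0) -> bool:
    p = np.asarray(point, dtype=float)
    for planes in boxes:
        if np.all(planes[:, :3] @ p - planes[:, 3] <= tol):
            return True
    return False


def cut_margins(mesh: trimesh.Trimesh, fiducials,
                params: CapParams | None = None) -> trimesh.Trimesh:
    """Open the face and set the lower rim by subtracting the margin boxes;
    the result is an open cap surface."""
    if params is None:
        params = CapParams()
    frame, box_defs = _margin_box_defs(mesh, fiducials, params)
    boxes = [_box_planes(frame, lo_i, hi_i) for lo_i, hi_i in box_defs]
    area_before = float(mesh.area)
    out = mesh
    for planes, (lo_i, hi_i) in zip(boxes, box_defs):
        corners = np.array([[x, y, z]
                            for x in (lo_i[0], hi_i[0])
                            for y in (lo_i[1], hi_i[1])
                            for z in (lo_i[2], hi_i[2])])
        world = frame.from_frame(corners)
        aabb = np.stack([world.min(axis=0), world.max(axis=0)])
        out = subtract_convex(out, planes, aabb=aabb)
    if len(out.faces) == 0:
        raise ValidationError("margin cuts removed the entire surface")
    removed = 1.0 - float(out.area) / area_before
    if removed > 0.6:
        raise ValidationError(
            f"margin cuts removed {removed:.0%} of the surface (> 60%); "
            "check the margin parameters")
    # the vertex (topmost point in the canonical frame) must survive
    frame = CanonicalFrame.from_fiducials(fiducials)
    v = frame.to_frame(mesh.vertices)
    cz_world = frame.from_frame(v[np.argmax(v[:, 2])][None, :])[0]
    if point_in_any_box(cz_world, boxes):
        raise ValidationError("margin cuts removed the vertex (Cz)")
    return out


# ---------------------------------------------------------------------------
# margin thickening and wireframe extrusion
# ---------------------------------------------------------------------------

def boundary_loops(mesh: trimesh.Trimesh) -> list[np.ndarray]:
    """Boundary loops as ordered vertex-index arrays.

    Boundary edges are walked in the direction induced by their single
    incident face, consuming each edge once, so loops that touch at a vertex
    are still separated and traversal always terminates."""
    edges = mesh.edges_sorted
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    bedges = uniq[counts == 1]
    if len(bedges) == 0:
        return []
    directed = set()
    for a, b, c in mesh.faces:
        directed.update([(int(a), int(b)), (int(b), int(c)), (int(c), int(a))])
    out_map: dict[int, list[int]] = {}
    for a, b in bedges:
        a, b = int(a), int(b)
        if (a, b) in directed:
            s, t = a, b
        else:
            s, t = b, a
        out_map.setdefault(s, []).append(t)
    loops = []
    for a, b in bedges:
        a, b = int(a), int(b)
        s, t = (a, b) if (a, b) in directed else (b, a)
        if t not in out_map.get(s, []):
            continue  # already consumed
        out_map[s].remove(t)
        loop = [s]
        cur = t
        while cur != s:
            loop.append(cur)
            nxts = out_map.get(cur, [])
            if not nxts:
                break  # open chain; report what we walked
            cur2 = nxts.pop(0)
            cur = cur2
        loops.append(np.asarray(loop, dtype=np.int64))
    return loops


def thicken_margin(cap: trimesh.Trimesh, band_width: float,
                   min_loop_fraction: float = 0.25) -> trimesh.Trimesh:
    """Tag edges within ``band_width`` of an exterior margin loop for double
    wire thickness; tags live in ``metadata['margin_edge_tags']`` (boolean,
    aligned with ``edges_unique``).

    Only long boundary loops (length >= ``min_loop_fraction`` x longest loop)
    count as exterior margin — grommet hole rims are not thickened.
    """
    loops = boundary_loops(cap)
    if not loops:
        raise TopologyError("mesh is closed; no margin to thicken")
    out = trimesh.Trimesh(vertices=cap.vertices.copy(), faces=cap.faces.copy(),
                          process=False)
    out.metadata.update(cap.metadata)
    edges = out.edges_unique
    tags = np.zeros(len(edges), dtype=bool)
    if band_width > 0:
        lengths = []
        for loop in loops:
            pts = cap.vertices[loop]
            seg = np.diff(np.vstack([pts, pts[:1]]), axis=0)
            lengths.append(float(np.linalg.norm(seg, axis=1).sum()))
        lmax = max(lengths)
        margin_loops = [l for l, ln in zip(loops, lengths)
                        if ln >= min_loop_fraction * lmax]
        segs_a = []
        segs_b = []
        for loop in margin_loops:
            pts = cap.vertices[loop]
            segs_a.append(pts)
            segs_b.append(np.vstack([pts[1:], pts[:1]]))
        a = np.vstack(segs_a)
        b = np.vstack(segs_b)
        vdist = _points_to_segments_distance(cap.vertices, a, b)
        near = vdist <= band_width
        tags = near[edges[:, 0]] | near[edges[:, 1]]
    out.metadata["margin_edge_tags"] = tags
    return out


def _points_to_segments_distance(points, a, b):
    """Min distance from each point to any segment (a[j], b[j])."""
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    out = np.full(len(points), np.inf)
    chunk = max(1, int(5e6 // max(len(a), 1)))
    for s in range(0, len(points), chunk):
        p = points[s:s + chunk]
        ap = p[:, None, :] - a[None, :, :]
        u = np.clip(np.einsum("pjk,jk->pj", ap, ab) / denom[None, :], 0, 1)
        proj = a[None, :, :] + u[..., None] * ab[None, :, :]
        d = np.linalg.norm(proj - p[:, None, :], axis=2).min(axis=1)
        out[s:s + chunk] = d
    return out


def wireframe(cap: trimesh.Trimesh, wire_thickness: float,
              margin_tags: np.ndarray | None = None,
              sections: int = 12,
              strict_edge_check: bool = True) -> trimesh.Trimesh:
    """Extrude every retained edge into a solid round strut (diameter =
    ``wire_thickness``; doubled at margin-tagged edges) with spherical
    joints at shared vertices.

    The returned mesh is the concatenated strut/joint geometry — each
    component closed — with the strut skeleton stored in metadata for
    :func:`capforge.printable.remesh_solidify`, which fuses the union into a
    single watertight solid.
    """
    edges = cap.edges_unique
    if len(edges) == 0:
        raise ValidationError("cap has no edges to extrude")
    elen = np.linalg.norm(
        cap.vertices[edges[:, 0]] - cap.vertices[edges[:, 1]], axis=1)
    if wire_thickness > float(elen.min()) / 2.0:
        msg = (f"wire thickness {wire_thickness} mm exceeds half the "
               f"shortest edge ({elen.min():.2f} mm); use a coarser "
               "keep_ratio")
        if strict_edge_check:
            raise ValidationError(msg)
        # hole rims clipped into the lattice legitimately carry short edges;
        # overlapping struts there fuse in the voxel re-tessellation
        log.info("%s (%d short edges tolerated)", msg,
                 int((elen < 2 * wire_thickness).sum()))
    if margin_tags is None:
        margin_tags = cap.metadata.get(
            "margin_edge_tags", np.zeros(len(edges), dtype=bool))
    margin_tags = np.asarray(margin_tags, dtype=bool)
    if len(margin_tags) != len(edges):
        raise ValidationError("margin tag array does not match edge count")
    radii = np.where(margin_tags, wire_thickness, wire_thickness / 2.0)

    parts = []
    for (i, j), r in zip(edges, radii):
        seg = (cap.vertices[i], cap.vertices[j])
        parts.append(trimesh.creation.cylinder(
            radius=r, segment=seg, sections=sections))
    vert_r = np.zeros(len(cap.vertices))
    for (i, j), r in zip(edges, radii):
        vert_r[i] = max(vert_r[i], r)
        vert_r[j] = max(vert_r[j], r)
    used = np.flatnonzero(vert_r > 0)
    for i in used:
        sph = trimesh.creation.icosphere(subdivisions=1, radius=vert_r[i])
        sph.apply_translation(cap.vertices[i])
        parts.append(sph)
    solid = trimesh.util.concatenate(parts)
    solid.metadata["struts"] = {
        "segments": np.stack([cap.vertices[edges[:, 0]],
                              cap.vertices[edges[:, 1]]], axis=1),
        "radii": radii,
        "joints": cap.vertices[used],
        "joint_radii": vert_r[used],
        "wire_thickness": float(wire_thickness),
    }
    return solid
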