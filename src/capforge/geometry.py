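"""Low-level computational-geometry primitives shared across the pipeline.

Everything here is exact/vectorized numpy; no spatial-index dependencies.
Meshes are ``trimesh.Trimesh`` objects with vertices in millimeters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import ValidationError

__all__ = [
    "CanonicalFrame",
    "closest_point_on_mesh",
    "interpolated_normal",
    "ray_mesh_intersections",
    "weld_vertices",
    "count_self_intersections",
]


# ---------------------------------------------------------------------------
# point / triangle proximity
# ---------------------------------------------------------------------------

def _closest_on_triangles(a, b, c, p):
    """Closest point to ``p`` on each triangle (a[i], b[i], c[i]).

    Vectorized version of Ericson's closest-point-on-triangle test.
    Returns (points (n,3), squared distances (n,)).
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = np.where(np.abs(d1 - d3) > 0, d1 - d3, 1.0)
    v = (d1 / denom)[:, None]
    out[m] = a[m] + v[m] * ab[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = np.where(np.abs(d2 - d6) > 0, d2 - d6, 1.0)
    w = (d2 / denom)[:, None]
    out[m] = a[m] + w[m] * ac[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    denom = np.where(np.abs(denom) > 0, denom, 1.0)
    w = ((d4 - d3) / denom)[:, None]
    out[m] = b[m] + w[m] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = va + vb + vc
    denom = np.where(np.abs(denom) > 0, denom, 1.0)
    v = (vb / denom)[:, None]
    w = (vc / denom)[:, None]
    out[m] = a[m] + v[m] * ab[m] + w[m] * ac[m]

    d2_ = np.einsum("ij,ij->i", out - p, out - p)
    return out, d2_


class _MeshProximity:
    """Brute-force-exact nearest-point queries accelerated by a centroid tree."""

    def __init__(self, mesh: trimesh.Trimesh):
        self.mesh = mesh
        self.tri = mesh.triangles.view(np.ndarray)
        self.centroids = self.tri.mean(axis=1)
        # max distance from a centroid to its triangle's farthest vertex
        self.reach = np.linalg.norm(
            self.tri - self.centroids[:, None, :], axis=2
        ).max(axis=1)
        self.rmax = float(self.reach.max()) if len(self.reach) else 0.0
        self.tree = cKDTree(self.centroids)

    def query(self, points):
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        out_pts = np.empty((n, 3))
        out_d = np.empty(n)
        out_f = np.empty(n, dtype=np.int64)
        k = min(8, len(self.centroids))
        d0, _ = self.tree.query(points, k=k)
        d0 = np.atleast_2d(d0)[:, -1]
        for i, p in enumerate(points):
            # any face with centroid beyond d0 + 2*rmax cannot beat candidates
            r = d0[i] + 2.0 * self.rmax + 1e-12
            idx = self.tree.query_ball_point(p, r)
            idx = np.asarray(idx, dtype=np.int64)
            t = self.tri[idx]
            cp, dsq = _closest_on_triangles(t[:, 0], t[:, 1], t[:, 2],
                                            np.broadcast_to(p, (len(idx), 3)))
            j = int(np.argmin(dsq))
            out_pts[i] = cp[j]
            out_d[i] = np.sqrt(dsq[j])
            out_f[i] = idx[j]
        return out_pts, out_d, out_f


def closest_point_on_mesh(mesh: trimesh.Trimesh, points):
    """Exact closest point(s) on ``mesh`` for each query point.

    Returns (surface points (n,3), distances (n,), face indices (n,)).
    """
    cache_key = "_capforge_proximity"
    prox = mesh._cache.cache.get(cache_key) if hasattr(mesh, "_cache") else None
    if prox is None or prox.mesh is not mesh:
        prox = _MeshProximity(mesh)
        try:
            mesh._cache.cache[cache_key] = prox
        except Exception:
            pass
    return prox.query(points)


def interpolated_normal(mesh: trimesh.Trimesh, point, face_index: int):
    """Outward unit normal at a surface point, barycentric-blended from
    the face's vertex normals (falls back to the face normal)."""
    tri = mesh.triangles[face_index]
    bary = trimesh.triangles.points_to_barycentric(
        tri[None, :, :], np.asarray(point, dtype=float)[None, :]
    )[0]
    vn = mesh.vertex_normals[mesh.faces[face_index]]
    n = (bary[:, None] * vn).sum(axis=0)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        n = mesh.face_normals[face_index]
        norm = np.linalg.norm(n)
    return n / norm


# ---------------------------------------------------------------------------
# ray casting
# ---------------------------------------------------------------------------

def ray_mesh_intersections(mesh: trimesh.Trimesh, origin, direction, eps=1e-9):
    """All ray/mesh intersections (Moller-Trumbore over every face).

    Returns sorted array of ray parameters t > eps (positions are
    ``origin + t * direction``). ``direction`` need not be unit length.
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    tri = mesh.triangles.view(np.ndarray)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    h = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(det) > eps * np.maximum(1.0, np.abs(det).max(initial=1.0))
    inv = np.where(ok, 1.0 / np.where(det == 0, 1.0, det), 0.0)
    s = origin - v0
    u = np.einsum("ij,ij->i", s, h) * inv
    q = np.cross(s, e1)
    v = np.einsum("j,ij->i", direction, q) * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > eps)
    return np.sort(t[hit])


# ---------------------------------------------------------------------------
# vertex welding
# ---------------------------------------------------------------------------

def weld_vertices(vertices, faces, tolerance: float = 0.0):
    """Merge vertices closer than ``tolerance`` (single-linkage clusters).

    ``tolerance == 0`` merges bit-identical coordinates only. Faces that
    degenerate (repeated vertex) after merging are dropped. Returns
    (vertices, faces).
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    if tolerance < 0:
        raise ValidationError("weld tolerance must be >= 0")
    if len(vertices) == 0:
        return vertices, faces
    if tolerance == 0.0:
        uniq, inverse = np.unique(vertices, axis=0, return_inverse=True)
        new_v = uniq
        remap = inverse
    else:
        tree = cKDTree(vertices)
        pairs = tree.query_pairs(tolerance, output_type="ndarray")
        parent = np.arange(len(vertices))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in pairs:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
        roots = np.array([find(i) for i in range(len(vertices))])
        uniq_roots, remap = np.unique(roots, return_inverse=True)
        # representative: mean of each cluster
        new_v = np.zeros((len(uniq_roots), 3))
        counts = np.bincount(remap)
        np.add.at(new_v, remap, vertices)
        new_v /= counts[:, None]
    new_f = remap[faces]
    good = (
        (new_f[:, 0] != new_f[:, 1])
        & (new_f[:, 1] != new_f[:, 2])
        & (new_f[:, 0] != new_f[:, 2])
    )
    return new_v, new_f[good]


# ---------------------------------------------------------------------------
# self-intersection census
# ---------------------------------------------------------------------------

def _tri_tri_overlap(t1, t2, eps):
    """Vectorized Moller interval test for triangle pairs.

    t1, t2: (n,3,3). Returns boolean (n,). Coplanar pairs are handled by a
    conservative 2D separating-axis test.
    """
    n = len(t1)
    if n == 0:
        return np.zeros(0, dtype=bool)
    p1, q1, r1 = t1[:, 0], t1[:, 1], t1[:, 2]
    p2, q2, r2 = t2[:, 0], t2[:, 1], t2[:, 2]

    n2 = np.cross(q2 - p2, r2 - p2)
    d1p = np.einsum("ij,ij->i", p1 - p2, n2)
    d1q = np.einsum("ij,ij->i", q1 - p2, n2)
    d1r = np.einsum("ij,ij->i", r1 - p2, n2)
    scale2 = np.linalg.norm(n2, axis=1) + 1e-300
    z = eps * scale2
    s1 = np.stack([d1p, d1q, d1r], axis=1)
    sep1 = np.all(s1 > z[:, None], axis=1) | np.all(s1 < -z[:, None], axis=1)

    n1 = np.cross(q1 - p1, r1 - p1)
    d2p = np.einsum("ij,ij->i", p2 - p1, n1)
    d2q = np.einsum("ij,ij->i", q2 - p1, n1)
    d2r = np.einsum("ij,ij->i", r2 - p1, n1)
    scale1 = np.linalg.norm(n1, axis=1) + 1e-300
    z1 = eps * scale1
    s2 = np.stack([d2p, d2q, d2r], axis=1)
    sep2 = np.all(s2 > z1[:, None], axis=1) | np.all(s2 < -z1[:, None], axis=1)

    result = np.zeros(n, dtype=bool)
    maybe = ~(sep1 | sep2)
    coplanar = maybe & (np.abs(s1).max(axis=1) <= z) & (np.abs(s2).max(axis=1) <= z1)
    cross = maybe & ~coplanar
    if np.any(cross):
        result[cross] = _interval_overlap(
            t1[cross], t2[cross], s1[cross], s2[cross]
        )
    if np.any(coplanar):
        idx = np.flatnonzero(coplanar)
        for i in idx:
            result[i] = _coplanar_overlap(t1[i], t2[i], n1[i])
    return result


def _interval_overlap(t1, t2, s1, s2):
    """Intersection intervals of both triangles on the plane-plane line.

    ``s1``: signed distances of t1's vertices to t2's plane; ``s2`` vice versa.
    """
    n1 = np.cross(t1[:, 1] - t1[:, 0], t1[:, 2] - t1[:, 0])
    n2 = np.cross(t2[:, 1] - t2[:, 0], t2[:, 2] - t2[:, 0])
    d = np.cross(n1, n2)
    axis = np.argmax(np.abs(d), axis=1)

    def interval(tri, dist):
        # coordinates of the triangle along the line's dominant axis
        n = len(tri)
        p = np.take_along_axis(tri, axis[:, None, None], axis=2)[:, :, 0]
        lo = np.full(n, np.inf)
        hi = np.full(n, -np.inf)
        for i0, i1 in ((0, 1), (1, 2), (2, 0)):
            di, dj = dist[:, i0], dist[:, i1]
            crossing = (di * dj) < 0
            denom = np.where(crossing, di - dj, 1.0)
            tpar = np.where(crossing, di / denom, 0.0)
            x = p[:, i0] + tpar * (p[:, i1] - p[:, i0])
            lo = np.where(crossing, np.minimum(lo, x), lo)
            hi = np.where(crossing, np.maximum(hi, x), hi)
            on = di == 0
            lo = np.where(on, np.minimum(lo, p[:, i0]), lo)
            hi = np.where(on, np.maximum(hi, p[:, i0]), hi)
        return lo, hi

    lo1, hi1 = interval(t1, s1)
    lo2, hi2 = interval(t2, s2)
    return (lo1 <= hi2) & (lo2 <= hi1) & (hi1 > -np.inf) & (hi2 > -np.inf)


def _coplanar_overlap(t1, t2, n):
    """2D SAT for coplanar triangles (projected on dominant normal axis)."""
    k = int(np.argmax(np.abs(n)))
    keep = [i for i in range(3) if i != k]
    a = t1[:, keep]
    b = t2[:, keep]
    for tri_a, tri_b in ((a, b), (b, a)):
        for i in range(3):
            edge = tri_a[(i + 1) % 3] - tri_a[i]
            ax = np.array([-edge[1], edge[0]])
            pa = tri_a @ ax
            pb = tri_b @ ax
            if pa.max() < pb.min() - 1e-12 or pb.max() < pa.min() - 1e-12:
                return False
    return True


def count_self_intersections(mesh: trimesh.Trimesh, eps: float = 1e-7,
                             max_pairs: int = 50_000_000) -> int:
    """Number of non-adjacent face pairs that geometrically intersect.

    Broad phase: uniform grid hash on face bounding boxes; narrow phase:
    Moller triangle-triangle test. Pairs sharing a vertex index are skipped
    (weld first for a meaningful census).
    """
    tri = mesh.triangles.view(np.ndarray)
    faces = mesh.faces.view(np.ndarray)
    nf = len(tri)
    if nf < 2:
        return 0
    lo = tri.min(axis=1)
    hi = tri.max(axis=1)
    ext = hi - lo
    # cell >= max face extent: every face spans at most 2 cells per axis
    cell = max(float(ext.max()), 1e-9) * 1.001
    gmin = lo.min(axis=0)
    ilo = np.floor((lo - gmin) / cell).astype(np.int64)
    ihi = np.floor((hi - gmin) / cell).astype(np.int64)
    dims = ihi.max(axis=0) + 1
    # enumerate (cell, face) pairs over the <= 8 corner cells, deduplicated
    keys_list = []
    ids_list = []
    base = np.arange(nf)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                cx = np.minimum(ilo[:, 0] + dx, ihi[:, 0])
                cy = np.minimum(ilo[:, 1] + dy, ihi[:, 1])
                cz = np.minimum(ilo[:, 2] + dz, ihi[:, 2])
                keys_list.append((cx * dims[1] + cy) * dims[2] + cz)
                ids_list.append(base)
    keys = np.concatenate(keys_list)
    face_ids = np.concatenate(ids_list)
    pair_key = keys * nf + face_ids
    _, first = np.unique(pair_key, return_index=True)
    keys = keys[first]
    face_ids = face_ids[first]
    order = np.argsort(keys, kind="stable")
    keys = keys[order]
    face_ids = face_ids[order]
    # candidate pairs within each cell, vectorized by cell-occupancy size
    boundaries = np.flatnonzero(np.diff(keys)) + 1
    starts = np.concatenate([[0], boundaries])
    sizes = np.diff(np.concatenate([starts, [len(keys)]]))
    pa_list, pb_list = [], []
    n_pairs = 0
    for m in np.unique(sizes):
        if m < 2:
            continue
        sel = starts[sizes == m]
        ids = face_ids[sel[:, None] + np.arange(m)[None, :]]  # (cells, m)
        iu, ju = np.triu_indices(int(m), k=1)
        pa_list.append(ids[:, iu].ravel())
        pb_list.append(ids[:, ju].ravel())
        n_pairs += ids.shape[0] * len(iu)
        if n_pairs > max_pairs:
            raise MemoryError("self-intersection broad phase exploded")
    if not pa_list:
        return 0
    pa = np.concatenate(pa_list)
    pb = np.concatenate(pb_list)
    swap = pa > pb
    pa[swap], pb[swap] = pb[swap], pa[swap]
    pairs = np.unique(np.stack([pa, pb], axis=1), axis=0)
    pa, pb = pairs[:, 0], pairs[:, 1]
    # drop pairs sharing any vertex index
    fa = faces[pa]
    fb = faces[pb]
    shared = np.zeros(len(pa), dtype=bool)
    for i in range(3):
        for j in range(3):
            shared |= fa[:, i] == fb[:, j]
    pa, pb = pa[~shared], pb[~shared]
    # bbox overlap check (grid cells are coarse)
    ok = np.all((lo[pa] <= hi[pb] + eps * cell) & (lo[pb] <= hi[pa] + eps * cell),
                axis=1)
    pa, pb = pa[ok], pb[ok]
    hits = 0
    chunk = 200_000
    for s in range(0, len(pa), chunk):
        sl = slice(s, s + chunk)
        hits += int(_tri_tri_overlap(tri[pa[sl]], tri[pb[sl]], eps).sum())
    return hits


# ---------------------------------------------------------------------------
# canonical head frame
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CanonicalFrame:
    """Right-handed head frame: origin at the LPA-RPA midpoint, x along the
    preauricular axis, y toward Nz (orthogonalized), z = x cross y toward the
    vertex.

    The vertex guess Cz0 disambiguates handedness: if x = LPA->RPA would put
    the vertex at negative z (a mirrored anatomy), the x-axis is flipped to
    RPA->LPA so that z always points up through the vertex."""

    origin: np.ndarray
    rotation: np.ndarray  # rows are the x/y/z axes in world coordinates

    @classmethod
    def from_fiducials(cls, fiducials) -> "CanonicalFrame":
        lpa = np.asarray(fiducials.lpa, dtype=float)
        rpa = np.asarray(fiducials.rpa, dtype=float)
        nz = np.asarray(fiducials.nz, dtype=float)
        origin = 0.5 * (lpa + rpa)
        x = rpa - lpa
        nx = np.linalg.norm(x)
        if nx < 1e-12:
            raise ValidationError("LPA and RPA coincide; frame undefined")
        x = x / nx
        y = nz - origin
        y = y - (y @ x) * x
        ny = np.linalg.norm(y)
        if ny < 1e-12:
            raise ValidationError("Nz lies on the LPA-RPA axis; frame undefined")
        y = y / ny
        z = np.cross(x, y)
        cz0 = getattr(fiducials, "cz0", None)
        if cz0 is not None and float(z @ (np.asarray(cz0, float) - origin)) < 0:
            x = -x
            z = -z
        return cls(origin=origin, rotation=np.stack([x, y, z]))

    def to_frame(self, points):
        pts = np.asarray(points, dtype=float)
        return (pts - self.origin) @ self.rotation.T

    def from_frame(self, points):
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation + self.origin
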