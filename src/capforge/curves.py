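"""Surface curves: mesh/plane cross-sections and arc-length operations.

The 10-20 construction is built entirely from three primitives:

* ``cross_section`` — the closed intersection loop of a plane (through three
  anchor points) with a closed head mesh;
* ``arc_on_loop`` — the sub-arc of such a loop running from one anchor to
  another through a third ("via") point;
* ``point_at_fraction`` — the point at a given arc-length fraction.

Curve distance is measured along the polyline (no spline smoothing); with
mesh refinement the polyline length converges quadratically to the smooth
geodesic of the section plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import NoIntersectionError, SnapError, ValidationError

__all__ = ["SurfaceCurve", "cross_section", "arc_on_loop", "point_at_fraction"]


@dataclass
class SurfaceCurve:
    """An ordered polyline lying on a mesh, arc-length parameterized.

    For closed curves the start point is not repeated; ``cumulative_length``
    then has ``len(points) + 1`` entries, the last one closing the loop.
    """

    points: np.ndarray
    closed: bool
    cumulative_length: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValidationError("curve points must be (n, 3)")
        if len(self.points) < 2:
            raise ValidationError("curve needs at least 2 points")
        seg = np.diff(self.points, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        if np.any(seglen == 0):
            # drop exact duplicates rather than fail: section code can emit them
            keep = np.concatenate([[True], seglen > 0])
            self.points = self.points[keep]
            seglen = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            if len(self.points) < 2:
                raise ValidationError("curve degenerate after deduplication")
        if self.closed:
            wrap = np.linalg.norm(self.points[0] - self.points[-1])
            if wrap == 0:
                self.points = self.points[:-1]
                seglen = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
                wrap = np.linalg.norm(self.points[0] - self.points[-1])
            seglen = np.concatenate([seglen, [wrap]])
        self.cumulative_length = np.concatenate([[0.0], np.cumsum(seglen)])

    @property
    def length(self) -> float:
        return float(self.cumulative_length[-1])

    @property
    def segment_starts(self) -> np.ndarray:
        return self.points

    @property
    def segment_ends(self) -> np.ndarray:
        if self.closed:
            return np.vstack([self.points[1:], self.points[:1]])
        return self.points[1:]

    def mean_segment_length(self) -> float:
        n_seg = len(self.points) if self.closed else len(self.points) - 1
        return self.length / n_seg

    def point_at_length(self, s: float) -> np.ndarray:
        cum = self.cumulative_length
        s = float(np.clip(s, 0.0, cum[-1]))
        i = int(np.searchsorted(cum, s, side="right")) - 1
        i = min(i, len(cum) - 2)
        seg_a = self.points[i]
        seg_b = self.points[(i + 1) % len(self.points)] if self.closed else self.points[i + 1]
        denom = cum[i + 1] - cum[i]
        u = 0.0 if denom == 0 else (s - cum[i]) / denom
        return seg_a + u * (seg_b - seg_a)

    def nearest(self, point) -> tuple[np.ndarray, float, float]:
        """Closest point on the polyline: (point, arc-length s, distance)."""
        p = np.asarray(point, dtype=float)
        a = self.segment_starts if self.closed else self.points[:-1]
        b = self.segment_ends
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        denom = np.where(denom == 0, 1.0, denom)
        u = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
        proj = a + u[:, None] * ab
        d = np.linalg.norm(proj - p, axis=1)
        i = int(np.argmin(d))
        s = self.cumulative_length[i] + u[i] * (
            self.cumulative_length[i + 1] - self.cumulative_length[i]
        )
        return proj[i], float(s), float(d[i])


def cross_section(mesh: trimesh.Trimesh, p1, p2, p3) -> SurfaceCurve:
    """Closed intersection loop of the plane through p1, p2, p3 with ``mesh``.

    When the plane cuts the surface in several loops, the loop minimizing the
    summed distance to the three anchor points is returned.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    normal = np.cross(p2 - p1, p3 - p1)
    scale = max(np.linalg.norm(p2 - p1), np.linalg.norm(p3 - p1), 1e-300)
    if np.linalg.norm(normal) < 1e-12 * scale * scale:
        raise ValidationError("cross-section anchor points are collinear")
    normal = normal / np.linalg.norm(normal)
    path = mesh.section(plane_origin=p1, plane_normal=normal)
    if path is None:
        raise NoIntersectionError("plane does not intersect the mesh")
    loops = [np.asarray(d, dtype=float) for d in path.discrete]
    loops = [lo for lo in loops if len(lo) >= 4]
    if not loops:
        raise NoIntersectionError("plane/mesh intersection is degenerate")
    anchors = np.stack([p1, p2, p3])

    def loop_cost(lo):
        d = np.linalg.norm(lo[None, :, :] - anchors[:, None, :], axis=2)
        return float(d.min(axis=1).sum())

    best = min(loops, key=loop_cost)
    if not np.allclose(best[0], best[-1]):
        raise NoIntersectionError("plane/mesh intersection is not a closed loop")
    return SurfaceCurve(points=best[:-1], closed=True)


def arc_on_loop(loop: SurfaceCurve, a, b, via, tolerance: float | None = None
                ) -> SurfaceCurve:
    """Open sub-arc of a closed loop from (near) ``a`` to (near) ``b``
    passing through (near) ``via``.

    Endpoints are snapped to the nearest points on the loop. ``tolerance``
    defaults to twice the loop's mean segment length.
    """
    if not loop.closed:
        raise ValidationError("arc_on_loop requires a closed loop")
    if tolerance is None:
        tolerance = 2.0 * loop.mean_segment_length()
    snapped = []
    for name, p in (("a", a), ("b", b), ("via", via)):
        pt, s, d = loop.nearest(p)
        if d > tolerance:
            raise SnapError(
                f"point {name} is {d:.6g} from the loop (tolerance {tolerance:.6g})",
                distance=d,
            )
        snapped.append((pt, s))
    (pa, sa), (pb, sb), (pv, sv) = snapped
    L = loop.length
    if np.linalg.norm(pa - pb) == 0:
        raise ValidationError("arc endpoints coincide on the loop")
    if np.linalg.norm(pv - pa) == 0 or np.linalg.norm(pv - pb) == 0:
        raise ValidationError("via point coincides with an arc endpoint")

    fwd = (sb - sa) % L  # traversing in increasing-s direction
    via_fwd = (sv - sa) % L
    go_forward = via_fwd <= fwd
    cum = loop.cumulative_length

    def collect(s_start, s_end):
        """Loop vertices with arc length strictly inside (s_start, s_end) mod L,
        walked forward from s_start."""
        verts_s = cum[:-1]
        rel = (verts_s - s_start) % L
        span = (s_end - s_start) % L
        inside = (rel > 1e-12 * max(L, 1.0)) & (rel < span - 1e-12 * max(L, 1.0))
        order = np.argsort(rel[inside])
        return loop.points[inside][order]

    if go_forward:
        mid = collect(sa, sb)
        pts = np.vstack([pa[None, :], mid, pb[None, :]])
    else:
        mid = collect(sb, sa)
        pts = np.vstack([pb[None, :], mid, pa[None, :]])[::-1]
    return SurfaceCurve(points=pts, closed=False)


def point_at_fraction(curve: SurfaceCurve, t: float) -> np.ndarray:
    """Point at arc-length fraction ``t`` in [0, 1] along ``curve``."""
    if not (0.0 <= t <= 1.0):
        raise ValidationError(f"fraction {t} outside [0, 1]")
    if curve.length <= 0:
        raise ValidationError("curve has zero length")
    return curve.point_at_length(t * curve.length)
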