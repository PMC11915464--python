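"""Synthetic head phantoms with analytically known fiducials and landmarks.

Sphere and ellipsoid phantoms use the canonical frame convention
Nz on +x, RPA on +y, vertex on +z (right handed, mm).  The initial vertex
guess Cz0 is deliberately displaced from the true pole by a fixed,
deterministic tilt so the Cz bisection always has work to do.

``oracle_landmarks`` recomputes montage positions by dense uniform sampling
of the *analytic* plane/quadric intersection curves — fully independent of
the production cross-section machinery — and is the ground truth used in
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .errors import CapforgeError, ResourceError, ValidationError
from .landmarks import Fiducials
from .mesh_io import VolumeImage
from .montage import CurveRecipe, default_recipe

__all__ = ["Phantom", "make_sphere", "make_ellipsoid", "make_voxel_ball",
           "oracle_landmarks"]

#: densities above this would produce unwieldy meshes (> ~2.6M vertices)
MAX_DENSITY = 8

#: deterministic Cz0 displacement: tilt from the pole, and azimuth from +x
DEFAULT_CZ0_TILT_DEG = 30.0
DEFAULT_CZ0_AZIMUTH_DEG = 40.0


@dataclass
class Phantom:
    """A synthetic closed head surface with known fiducials."""

    mesh: trimesh.Trimesh
    fiducials: Fiducials
    kind: str
    radii: np.ndarray  # (a, b, c) semi-axes in mm
    analytic_landmarks: dict[str, np.ndarray] | None = None


def _cz0_direction(tilt_deg: float, azimuth_deg: float) -> np.ndarray:
    t = np.deg2rad(tilt_deg)
    p = np.deg2rad(azimuth_deg)
    return np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])


def make_sphere(radius: float = 100.0, density: int = 5,
                cz0_tilt_deg: float = DEFAULT_CZ0_TILT_DEG) -> Phantom:
    """Icosphere phantom of the given radius (mm).

    ``density`` is the icosphere subdivision level.  Fiducials sit at the
    axis intersections of the analytic sphere; Cz0 is tilted
    ``cz0_tilt_deg`` (<= 30 degrees) away from the true pole.
    """
    if radius <= 0:
        raise ValidationError("sphere radius must be positive")
    if density < 0:
        raise ValidationError("density must be >= 0")
    if density > MAX_DENSITY:
        raise ResourceError(
            f"density {density} exceeds the guard ({MAX_DENSITY})")
    if not (0 <= cz0_tilt_deg <= 30):
        raise ValidationError("Cz0 tilt must be within [0, 30] degrees")
    mesh = trimesh.creation.icosphere(subdivisions=density, radius=radius)
    mesh = trimesh.Trimesh(vertices=mesh.vertices.copy(),
                           faces=mesh.faces.copy(), process=False)
    r = float(radius)
    fid = Fiducials(
        nz=[r, 0, 0], iz=[-r, 0, 0], lpa=[0, -r, 0], rpa=[0, r, 0],
        cz0=r * _cz0_direction(cz0_tilt_deg, DEFAULT_CZ0_AZIMUTH_DEG),
    )
    return Phantom(mesh=mesh, fiducials=fid, kind="sphere",
                   radii=np.array([r, r, r]),
                   analytic_landmarks=sphere_analytic_landmarks(r))


def sphere_analytic_landmarks(radius: float) -> dict[str, np.ndarray]:
    """Closed-form reference-row landmarks on the analytic sphere.

    Sagittal-row labels lie at polar angle t*pi from Nz in the x-z plane for
    arc fraction t; coronal-row labels analogously in the y-z plane from LPA.
    The 10% ring (latitude z = R sin 0.1*pi) labels follow by azimuthal
    proportionality.
    """
    r = float(radius)
    out: dict[str, np.ndarray] = {"Cz": np.array([0.0, 0.0, r])}
    sag = {"Fpz": 0.1, "AFz": 0.2, "Fz": 0.3, "FCz": 0.4, "CPz": 0.6,
           "Pz": 0.7, "POz": 0.8, "Oz": 0.9}
    for label, t in sag.items():
        a = t * np.pi
        out[label] = r * np.array([np.cos(a), 0.0, np.sin(a)])
    cor = {"T7": 0.1, "C5": 0.2, "C3": 0.3, "C1": 0.4, "C2": 0.6,
           "C4": 0.7, "C6": 0.8, "T8": 0.9}
    for label, t in cor.items():
        a = t * np.pi
        out[label] = r * np.array([0.0, -np.cos(a), np.sin(a)])
    # 10% horizontal ring: latitude circle through Fpz, T7, Oz, T8
    z0 = r * np.sin(0.1 * np.pi)
    rho = r * np.cos(0.1 * np.pi)
    ring_left = {"Fp1": 0.1, "AF7": 0.2, "F7": 0.3, "FT7": 0.4, "TP7": 0.6,
                 "P7": 0.7, "PO7": 0.8, "O1": 0.9}
    for label, t in ring_left.items():
        phi = -t * np.pi
        out[label] = np.array([rho * np.cos(phi), rho * np.sin(phi), z0])
        right = label.replace("7", "8").replace("1", "2")
        out[right] = np.array([rho * np.cos(phi), -rho * np.sin(phi), z0])
    return out


def make_ellipsoid(a: float, b: float, c: float, density: int = 5,
                   cz0_tilt_deg: float = DEFAULT_CZ0_TILT_DEG) -> Phantom:
    """Triaxial ellipsoid phantom with semi-axes (a, b, c) mm.

    Fiducials at the axis intersections; no closed-form landmark table
    (use :func:`oracle_landmarks`).
    """
    for name, v in (("a", a), ("b", b), ("c", c)):
        if v <= 0:
            raise ValidationError(f"semi-axis {name} must be positive")
    if density < 0 or density > MAX_DENSITY:
        raise ResourceError(f"density must be in [0, {MAX_DENSITY}]")
    unit = trimesh.creation.icosphere(subdivisions=density, radius=1.0)
    verts = unit.vertices * np.array([a, b, c])
    mesh = trimesh.Trimesh(vertices=verts, faces=unit.faces.copy(),
                           process=False)
    dir0 = _cz0_direction(cz0_tilt_deg, DEFAULT_CZ0_AZIMUTH_DEG)
    cz0 = dir0 * np.array([a, b, c])  # on the analytic ellipsoid
    fid = Fiducials(nz=[a, 0, 0], iz=[-a, 0, 0], lpa=[0, -b, 0],
                    rpa=[0, b, 0], cz0=cz0)
    analytic = sphere_analytic_landmarks(1.0) if a == b == c else None
    if analytic is not None:
        analytic = {k: v * a for k, v in analytic.items()}
    return Phantom(mesh=mesh, fiducials=fid, kind="ellipsoid",
                   radii=np.array([a, b, c], dtype=float),
                   analytic_landmarks=analytic)


def make_voxel_ball(radius: float, grid=(64, 64, 64), voxel_size=1.0,
                    center=None) -> VolumeImage:
    """Binary voxelized ball: value 1 strictly inside radius (in voxels).

    The ball must fit strictly inside the grid (no boundary contact).
    """
    grid = tuple(int(g) for g in np.broadcast_to(np.asarray(grid), (3,)))
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,)).copy()
    if radius < 0:
        raise ValidationError("radius must be >= 0")
    if center is None:
        center = (np.asarray(grid) - 1) / 2.0
    center = np.asarray(center, dtype=float)
    if radius > 0:
        lo = center - radius
        hi = center + radius
        if np.any(lo <= 0) or np.any(hi >= np.asarray(grid) - 1):
            raise ValidationError(
                "ball touches the grid boundary; enlarge the grid or pad")
    ii, jj, kk = np.meshgrid(*(np.arange(g) for g in grid), indexing="ij")
    d2 = ((ii - center[0]) ** 2 + (jj - center[1]) ** 2
          + (kk - center[2]) ** 2)
    arr = (d2 < radius ** 2).astype(np.uint8)
    return VolumeImage(array=arr, voxel_size=voxel_size)


# ---------------------------------------------------------------------------
# dense-sampling oracle (independent of the production curve code)
# ---------------------------------------------------------------------------

def _dense_plane_quadric_loop(p1, p2, p3, radii, n: int) -> np.ndarray:
    """Dense polyline of the intersection of the plane through p1,p2,p3 with
    the ellipsoid diag(radii): map to the unit sphere, intersect plane with
    sphere (a circle, closed form), sample uniformly in angle, map back."""
    radii = np.asarray(radii, dtype=float)
    q1, q2, q3 = (np.asarray(p) / radii for p in (p1, p2, p3))
    nrm = np.cross(q2 - q1, q3 - q1)
    nn = np.linalg.norm(nrm)
    if nn < 1e-14:
        raise ValidationError("oracle: collinear anchor points")
    nrm = nrm / nn
    d = float(nrm @ q1)  # plane offset; circle radius sqrt(1 - d^2)
    if abs(d) >= 1.0:
        raise ValidationError("oracle: plane misses the unit sphere")
    center = d * nrm
    rad = np.sqrt(1.0 - d * d)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(helper @ nrm) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = helper - (helper @ nrm) * nrm
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(nrm, e1)
    ang = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    circ = center + rad * (np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2)
    return circ * radii


def _cumlen(pts: np.ndarray, closed: bool) -> np.ndarray:
    seg = np.diff(pts, axis=0)
    ln = np.linalg.norm(seg, axis=1)
    if closed:
        ln = np.concatenate([ln, [np.linalg.norm(pts[0] - pts[-1])]])
    return np.concatenate([[0.0], np.cumsum(ln)])


def _project_param(loop: np.ndarray, cum: np.ndarray, p) -> tuple[float, np.ndarray]:
    """Continuous arc-length parameter of the closest point on a closed
    dense polyline (projection onto segments, not nearest sample)."""
    p = np.asarray(p, dtype=float)
    a = loop
    b = np.vstack([loop[1:], loop[:1]])
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    u = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
    proj = a + u[:, None] * ab
    d = np.einsum("ij,ij->i", proj - p, proj - p)
    i = int(np.argmin(d))
    s = cum[i] + u[i] * (cum[i + 1] - cum[i])
    return float(s), proj[i]


def _oracle_arc(loop: np.ndarray, a, b, via) -> np.ndarray:
    """Sub-polyline of a closed dense loop from the projection of ``a`` to
    the projection of ``b``, through the projection of ``via``."""
    n = len(loop)
    cum = _cumlen(loop, closed=True)
    total = cum[-1]
    (sa, pa), (sb, pb), (sv, _) = (_project_param(loop, cum, p)
                                   for p in (a, b, via))
    fwd = (sb - sa) % total
    via_fwd = (sv - sa) % total
    samples_s = cum[:-1]
    if via_fwd <= fwd:
        rel = (samples_s - sa) % total
        inside = (rel > 1e-12 * total) & (rel < fwd - 1e-12 * total)
        order = np.argsort(rel[inside])
        mid = loop[inside][order]
        return np.vstack([pa[None, :], mid, pb[None, :]])
    back = (sa - sb) % total
    rel = (samples_s - sb) % total
    inside = (rel > 1e-12 * total) & (rel < back - 1e-12 * total)
    order = np.argsort(rel[inside])
    mid = loop[inside][order]
    return np.vstack([pb[None, :], mid, pa[None, :]])[::-1]


def _oracle_fraction_point(arc: np.ndarray, t: float) -> np.ndarray:
    cum = _cumlen(arc, closed=False)
    s = t * cum[-1]
    i = int(np.searchsorted(cum, s, side="right")) - 1
    i = min(i, len(arc) - 2)
    denom = cum[i + 1] - cum[i]
    u = 0.0 if denom == 0 else (s - cum[i]) / denom
    return arc[i] + u * (arc[i + 1] - arc[i])


def oracle_landmarks(phantom: Phantom, system: str = "10-10",
                     n_dense: int = 100_000,
                     recipe: CurveRecipe | None = None
                     ) -> dict[str, np.ndarray]:
    """Brute-force landmark positions on the *analytic* phantom surface.

    Every construction curve is sampled with ``n_dense`` uniform points of
    the exact plane/ellipsoid intersection; arcs, fractions and the Cz
    bisection are evaluated on these dense polylines with standalone code.
    Supported for sphere and ellipsoid phantoms only.
    """
    if phantom.kind not in ("sphere", "ellipsoid"):
        raise CapforgeError(
            f"oracle unsupported for phantom kind {phantom.kind!r}")
    if n_dense < 10_000:
        raise ValidationError("n_dense must be >= 10000")
    if recipe is None:
        recipe = default_recipe(system)
    radii = phantom.radii
    fid = phantom.fiducials
    nz, iz, lpa, rpa = fid.nz, fid.iz, fid.lpa, fid.rpa

    # Cz by alternating bisection on dense analytic curves
    cz = np.asarray(fid.cz0, dtype=float)
    for _ in range(200):
        loop = _dense_plane_quadric_loop(lpa, rpa, cz, radii, n_dense)
        cz_mid = _oracle_fraction_point(_oracle_arc(loop, lpa, rpa, cz), 0.5)
        loop = _dense_plane_quadric_loop(nz, iz, cz_mid, radii, n_dense)
        cz_new = _oracle_fraction_point(_oracle_arc(loop, nz, iz, cz_mid), 0.5)
        delta = np.linalg.norm(cz_new - cz)
        cz = cz_new
        if delta < 1e-9 * radii.max():
            break

    placed = {"Nz": nz, "Iz": iz, "LPA": lpa, "RPA": rpa, "Cz": cz}
    out = {"Cz": cz}
    for entry in recipe.entries:
        a, v, b = (placed[l] for l in entry.anchors)
        loop = _dense_plane_quadric_loop(a, v, b, radii, n_dense)
        arc = _oracle_arc(loop, a, b, v)
        for frac, label in entry.placements:
            p = _oracle_fraction_point(arc, frac)
            placed[label] = p
            out[label] = p
    return out
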