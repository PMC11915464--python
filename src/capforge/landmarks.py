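"""10-20 / 10-10 / 10-5 cranial landmark computation on a closed head mesh.

Given the five user-supplied fiducials — nasion (Nz), inion (Iz), left and
right preauricular points (LPA, RPA) and an initial vertex guess (Cz0) — the
true vertex Cz is found by alternating bisection of the coronal
(LPA-Cz-RPA) and sagittal (Nz-Cz-Iz) reference cross-section curves until
successive estimates move less than a threshold (default 1e-6 mesh units).
All further landmarks are placed at arc-length fractions of cross-section
curves per a declarative :class:`~capforge.montage.CurveRecipe`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import Delaunay

from .curves import SurfaceCurve, arc_on_loop, cross_section, point_at_fraction
from .errors import (CapforgeError, ConvergenceError, RecipeError,
                     ValidationError)
from .geometry import CanonicalFrame, closest_point_on_mesh
from .montage import SYSTEMS, CurveRecipe, canonical_label, default_recipe

log = logging.getLogger(__name__)

__all__ = ["Fiducials", "LandmarkSet", "refine_cz", "compute_landmarks",
           "landmark_mesh", "reference_curves"]


@dataclass
class Fiducials:
    """The five cranial reference points, in mesh units (mm)."""

    nz: np.ndarray
    iz: np.ndarray
    lpa: np.ndarray
    rpa: np.ndarray
    cz0: np.ndarray

    def __post_init__(self):
        for name in ("nz", "iz", "lpa", "rpa", "cz0"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        if np.allclose(self.nz, self.iz):
            raise ValidationError("Nz and Iz coincide")
        if np.allclose(self.lpa, self.rpa):
            raise ValidationError("LPA and RPA coincide")
        # both reference planes must be well defined
        for trip, name in (((self.nz, self.iz, self.cz0), "sagittal"),
                           ((self.lpa, self.rpa, self.cz0), "coronal")):
            a, b, c = trip
            n = np.cross(b - a, c - a)
            scale = max(np.linalg.norm(b - a), np.linalg.norm(c - a))
            if np.linalg.norm(n) < 1e-10 * scale * scale:
                raise ValidationError(
                    f"fiducials are degenerate: {name} plane undefined")

    def as_dict(self) -> dict[str, list[float]]:
        return {"Nz": self.nz.tolist(), "Iz": self.iz.tolist(),
                "LPA": self.lpa.tolist(), "RPA": self.rpa.tolist(),
                "Cz0": self.cz0.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Fiducials":
        keymap = {k.lower(): k for k in d}
        try:
            return cls(nz=d[keymap["nz"]], iz=d[keymap["iz"]],
                       lpa=d[keymap["lpa"]], rpa=d[keymap["rpa"]],
                       cz0=d[keymap["cz0"]])
        except KeyError as exc:
            raise ValidationError(f"fiducial dict missing key {exc}") from exc


@dataclass
class LandmarkSet:
    """Labeled montage positions on the head surface, plus the fiducials."""

    system: str
    positions: dict[str, np.ndarray]
    fiducials: Fiducials | None = None
    snap_distances: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.system not in SYSTEMS:
            raise ValidationError(f"unknown landmark system {self.system!r}")
        self.positions = {k: np.asarray(v, dtype=float).reshape(3)
                          for k, v in self.positions.items()}

    @property
    def cz(self) -> np.ndarray:
        return self.positions["Cz"]

    def __getitem__(self, label: str) -> np.ndarray:
        return self.positions[canonical_label(label)]

    def __contains__(self, label: str) -> bool:
        return canonical_label(label) in self.positions

    def labels(self) -> list[str]:
        return list(self.positions)

    def array(self) -> np.ndarray:
        return np.stack([self.positions[k] for k in self.positions])

    def as_dict(self) -> dict[str, list[float]]:
        return {k: v.tolist() for k, v in self.positions.items()}


def _snap_to_surface(mesh: trimesh.Trimesh, point) -> np.ndarray:
    pts, _, _ = closest_point_on_mesh(mesh, np.asarray(point, dtype=float)[None, :])
    return pts[0]


def refine_cz(mesh: trimesh.Trimesh, fiducials: Fiducials,
              tol: float = 1e-6, max_iter: int = 100
              ) -> tuple[np.ndarray, int]:
    """Iteratively bisect the coronal and sagittal reference curves.

    Update order per construction convention: coronal first (LPA-Cz-RPA
    midpoint), then sagittal (Nz-Cz-Iz midpoint).  Stops when successive Cz
    estimates are closer than ``tol`` (mesh units; default 1e-6).

    Returns the converged vertex (a point on the surface) and the number of
    iterations used.
    """
    nz, iz = fiducials.nz, fiducials.iz
    lpa, rpa = fiducials.lpa, fiducials.rpa
    cz = _snap_to_surface(mesh, fiducials.cz0)
    delta = np.inf
    for it in range(1, max_iter + 1):
        coronal = cross_section(mesh, lpa, rpa, cz)
        arc_c = arc_on_loop(coronal, lpa, rpa, cz)
        cz_mid = point_at_fraction(arc_c, 0.5)
        sagittal = cross_section(mesh, nz, iz, cz_mid)
        arc_s = arc_on_loop(sagittal, nz, iz, cz_mid)
        cz_new = point_at_fraction(arc_s, 0.5)
        delta = float(np.linalg.norm(cz_new - cz))
        cz = cz_new
        if delta < tol:
            log.debug("Cz converged after %d iterations (delta %.3g)", it, delta)
            return cz, it
    raise ConvergenceError(
        f"Cz refinement did not converge in {max_iter} iterations "
        f"(last delta {delta:.3g})", last_delta=delta)


def reference_curves(mesh: trimesh.Trimesh, fiducials: Fiducials,
                     cz=None) -> dict[str, SurfaceCurve]:
    """The sagittal (Nz->Cz->Iz) and coronal (LPA->Cz->RPA) reference arcs."""
    if cz is None:
        cz, _ = refine_cz(mesh, fiducials)
    sagittal = arc_on_loop(cross_section(mesh, fiducials.nz, fiducials.iz, cz),
                           fiducials.nz, fiducials.iz, cz)
    coronal = arc_on_loop(cross_section(mesh, fiducials.lpa, fiducials.rpa, cz),
                          fiducials.lpa, fiducials.rpa, cz)
    return {"sagittal": sagittal, "coronal": coronal}


def compute_landmarks(mesh: trimesh.Trimesh, fiducials: Fiducials,
                      system: str = "10-10",
                      recipe: CurveRecipe | None = None,
                      tol: float = 1e-6) -> LandmarkSet:
    """Compute the full landmark montage for ``system`` on a closed mesh."""
    if system not in SYSTEMS:
        raise ValidationError(f"unknown landmark system {system!r}")
    if recipe is None:
        recipe = default_recipe(system)
    cz, _ = refine_cz(mesh, fiducials, tol=tol)
    placed: dict[str, np.ndarray] = {
        "Nz": fiducials.nz, "Iz": fiducials.iz,
        "LPA": fiducials.lpa, "RPA": fiducials.rpa, "Cz": cz,
    }
    montage: dict[str, np.ndarray] = {"Cz": cz}
    for entry in recipe.entries:
        try:
            a, v, b = (placed[canonical_label(l)] for l in entry.anchors)
        except KeyError as exc:
            raise RecipeError(
                f"recipe anchor {exc} not placed before curve "
                f"{entry.anchors}") from exc
        try:
            loop = cross_section(mesh, a, v, b)
            arc = arc_on_loop(loop, a, b, v)
        except CapforgeError as exc:
            raise type(exc)(
                f"curve through {entry.anchors} failed: {exc}") from exc
        for frac, label in entry.placements:
            p = point_at_fraction(arc, frac)
            placed[label] = p
            montage[label] = p
    log.info("placed %d landmarks (%s system)", len(montage), system)
    return LandmarkSet(system=system, positions=montage, fiducials=fiducials)


def landmark_mesh(landmarks: LandmarkSet) -> trimesh.Trimesh:
    """Triangulated landmark surface: vertices are exactly the landmark
    positions; connectivity from a Delaunay triangulation in a stereographic
    parameter domain about the vertex direction."""
    labels = landmarks.labels()
    pts = landmarks.array()
    if len(pts) < 4:
        raise ValidationError("landmark mesh needs at least 4 landmarks")
    if landmarks.fiducials is not None:
        frame = CanonicalFrame.from_fiducials(landmarks.fiducials)
        origin = frame.origin
        zdir = frame.rotation[2]
    else:
        origin = pts.mean(axis=0)
        zdir = landmarks.cz - origin
        zdir = zdir / np.linalg.norm(zdir)
    rel = pts - origin
    r = np.linalg.norm(rel, axis=1)
    if np.any(r < 1e-12):
        raise ValidationError("landmark coincides with projection center")
    u = rel / r[:, None]
    # rotate zdir to +z
    x = np.array([1.0, 0.0, 0.0])
    if abs(zdir @ x) > 0.9:
        x = np.array([0.0, 1.0, 0.0])
    ex = x - (x @ zdir) * zdir
    ex /= np.linalg.norm(ex)
    ey = np.cross(zdir, ex)
    uz = u @ zdir
    if np.any(uz <= -0.999):
        raise ValidationError("landmark at the antipode of the vertex")
    # stereographic projection from the south pole
    px = (u @ ex) / (1.0 + uz)
    py = (u @ ey) / (1.0 + uz)
    plane = np.stack([px, py], axis=1)
    span = plane.max(axis=0) - plane.min(axis=0)
    if np.any(~np.isfinite(plane)) or min(span) < 1e-12:
        raise ValidationError("landmarks are coplanar-degenerate")
    tri = Delaunay(plane)
    mesh = trimesh.Trimesh(vertices=pts, faces=tri.simplices, process=False)
    # orient faces outward (away from the projection center)
    centers = mesh.triangles_center - origin
    flip = np.einsum("ij,ij->i", mesh.face_normals, centers) < 0
    faces = mesh.faces.copy()
    faces[flip] = faces[flip][:, ::-1]
    mesh = trimesh.Trimesh(vertices=pts, faces=faces, process=False)
    mesh.metadata["landmark_labels"] = labels
    return mesh
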