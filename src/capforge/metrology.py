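"""Quantitative cap/head measurement and landmark validation.

Conventions:

* Circumference is measured on the 10% ring (the closed cross-section
  through Fpz, T7, Oz — the standard cap-sizing ring), so values compare
  directly to head-tape measurements.
* Radial projection uses the canonical-frame origin (the LPA-RPA midpoint)
  as the head center.
* Validation distances run along the sagittal reference curve from Iz and
  along the coronal reference curve from RPA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh

from .capbuild import boundary_loops
from .curves import SurfaceCurve, cross_section
from .errors import CapforgeError, ValidationError
from .geometry import CanonicalFrame, ray_mesh_intersections
from .landmarks import LandmarkSet, reference_curves

log = logging.getLogger(__name__)

__all__ = ["ValidationReport", "circumference", "scale_to_circumference",
           "geodesic_landmark_distances", "radial_project",
           "landmark_error_stats", "grommet_hole_centroids",
           "measure_along_row", "ROW_LABELS"]

#: ordered labels lying on each reference curve (10-10 dialect)
ROW_LABELS = {
    "sagittal": ("Fpz", "AFz", "Fz", "FCz", "Cz", "CPz", "Pz", "POz", "Oz"),
    "coronal": ("T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8"),
}

#: curve origin per row, following the standard measurement convention
ROW_ORIGIN = {"sagittal": "Iz", "coronal": "RPA"}


@dataclass(frozen=True)
class ValidationReport:
    """Measured-vs-reference landmark distances and their error statistics."""

    pairs: dict  # label -> (reference mm, measured mm)
    r_squared: float
    mean_error: float
    sd_error: float

    def as_dict(self) -> dict:
        return {
            "pairs": {k: [float(a), float(b)] for k, (a, b) in self.pairs.items()},
            "r_squared": float(self.r_squared),
            "mean_error": float(self.mean_error),
            "sd_error": float(self.sd_error),
        }


def _ring_anchors(landmarks: LandmarkSet):
    if all(l in landmarks for l in ("Fpz", "T7", "Oz")):
        return landmarks["Fpz"], landmarks["T7"], landmarks["Oz"]
    if landmarks.fiducials is None:
        raise ValidationError(
            "circumference needs Fpz/T7/Oz landmarks or fiducials")
    f = landmarks.fiducials
    log.info("circumference: falling back to the Nz/LPA/Iz fiducial ring")
    return f.nz, f.lpa, f.iz


def circumference(mesh: trimesh.Trimesh, landmarks: LandmarkSet) -> float:
    """Length (mm) of the closed 10% ring cross-section (Fpz-T7-Oz)."""
    a, b, c = _ring_anchors(landmarks)
    return cross_section(mesh, a, b, c).length


def scale_to_circumference(mesh: trimesh.Trimesh, landmarks: LandmarkSet,
                           target: float) -> tuple[trimesh.Trimesh, float]:
    """Uniformly scale the head about the canonical-frame origin so the 10%
    ring circumference equals ``target`` (mm).  Returns (mesh, factor)."""
    if target <= 0:
        raise ValidationError("target circumference must be positive")
    current = circumference(mesh, landmarks)
    factor = target / current
    if landmarks.fiducials is not None:
        origin = CanonicalFrame.from_fiducials(landmarks.fiducials).origin
    else:
        origin = mesh.vertices.mean(axis=0)
    verts = origin + factor * (mesh.vertices - origin)
    out = trimesh.Trimesh(vertices=verts, faces=mesh.faces.copy(),
                          process=False)
    out.metadata["scale_factor"] = float(factor)
    return out, float(factor)


def _row_curve(mesh: trimesh.Trimesh, landmarks: LandmarkSet,
               row: str) -> SurfaceCurve:
    if row not in ROW_LABELS:
        raise ValidationError(f"row must be 'sagittal' or 'coronal', got {row!r}")
    if landmarks.fiducials is None:
        raise ValidationError("row measurement requires fiducials")
    curves = reference_curves(mesh, landmarks.fiducials, cz=landmarks.cz)
    return curves[row]


def _origin_param(curve: SurfaceCurve, origin_point) -> float:
    _, s, d = curve.nearest(origin_point)
    if d > 4.0 * curve.mean_segment_length():
        raise ValidationError(
            f"row origin is {d:.3g} mm away from the reference curve")
    return s


def geodesic_landmark_distances(mesh: trimesh.Trimesh,
                                landmarks: LandmarkSet, row: str,
                                origin_label: str | None = None
                                ) -> dict[str, float]:
    """Arc-length distance (mm) from the row origin (Iz sagittal, RPA
    coronal) to each row landmark, along the reference cross-section."""
    curve = _row_curve(mesh, landmarks, row)
    if origin_label is None:
        origin_label = ROW_ORIGIN[row]
    f = landmarks.fiducials
    fid_points = {"Nz": f.nz, "Iz": f.iz, "LPA": f.lpa, "RPA": f.rpa}
    if origin_label in fid_points:
        origin_point = fid_points[origin_label]
    elif origin_label in landmarks:
        origin_point = landmarks[origin_label]
    else:
        raise ValidationError(f"unknown origin label {origin_label!r}")
    s0 = _origin_param(curve, origin_point)
    out = {}
    for label in ROW_LABELS[row]:
        if label not in landmarks:
            continue
        _, s, d = curve.nearest(landmarks[label])
        if d > 4.0 * curve.mean_segment_length():
            raise ValidationError(
                f"landmark {label} is {d:.3g} mm off the {row} curve")
        out[label] = float(abs(s - s0))
    return out


def measure_along_row(mesh: trimesh.Trimesh, landmarks: LandmarkSet,
                      row: str, points: dict[str, np.ndarray],
                      origin_label: str | None = None) -> dict[str, float]:
    """Distance from the row origin to arbitrary measured points (e.g.
    grommet-hole centroids), along the reference curve: each point is
    projected to its closest curve position first."""
    curve = _row_curve(mesh, landmarks, row)
    if origin_label is None:
        origin_label = ROW_ORIGIN[row]
    f = landmarks.fiducials
    fid_points = {"Nz": f.nz, "Iz": f.iz, "LPA": f.lpa, "RPA": f.rpa}
    origin_point = fid_points.get(origin_label)
    if origin_point is None:
        origin_point = landmarks[origin_label]
    s0 = _origin_param(curve, origin_point)
    out = {}
    for label, p in points.items():
        _, s, _ = curve.nearest(p)
        out[label] = float(abs(s - s0))
    return out


def radial_project(points, center, target_mesh: trimesh.Trimesh):
    """Map each point to the first ray/surface intersection beyond the
    center, along the ray center -> point."""
    center = np.asarray(center, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.empty_like(pts)
    misses = []
    for i, p in enumerate(pts):
        direction = p - center
        norm = np.linalg.norm(direction)
        if norm < 1e-12:
            misses.append(i)
            continue
        direction = direction / norm
        ts = ray_mesh_intersections(target_mesh, center, direction)
        if len(ts) == 0:
            misses.append(i)
            continue
        out[i] = center + ts[0] * direction
    if misses:
        raise CapforgeError(
            f"radial projection rays missed the target surface for point "
            f"indices {misses}")
    return out if np.asarray(points).ndim == 2 else out[0]


def landmark_error_stats(reference: dict[str, float],
                         measured: dict[str, float]) -> ValidationReport:
    """R-squared of the linear fit of measured vs reference distances, and
    the mean and standard deviation of the absolute pairwise error."""
    labels = sorted(set(reference) & set(measured))
    if len(labels) < 3:
        raise ValidationError(
            f"need at least 3 matched label pairs, got {len(labels)}")
    ref = np.array([reference[l] for l in labels], dtype=float)
    mes = np.array([measured[l] for l in labels], dtype=float)
    if np.ptp(ref) == 0 or np.ptp(mes) == 0:
        r2 = 1.0 if np.allclose(ref, mes) else 0.0
    else:
        r = np.corrcoef(ref, mes)[0, 1]
        r2 = float(r * r)
    err = np.abs(mes - ref)
    return ValidationReport(
        pairs={l: (float(r_), float(m_)) for l, r_, m_ in zip(labels, ref, mes)},
        r_squared=r2,
        mean_error=float(err.mean()),
        sd_error=float(err.std()),
    )


def grommet_hole_centroids(cap: trimesh.Trimesh, landmarks: LandmarkSet,
                           grommet_radius: float,
                           match_tolerance: float | None = None
                           ) -> dict[str, np.ndarray]:
    """Recover grommet-hole centers from a built cap: small boundary loops
    (perimeter up to 3x the grommet circumference) are matched to the
    nearest landmark within ``match_tolerance`` (default 2x radius)."""
    if match_tolerance is None:
        match_tolerance = 2.0 * grommet_radius
    max_perimeter = 3.0 * (2 * np.pi * grommet_radius)
    labels = landmarks.labels()
    pts = landmarks.array()
    out: dict[str, np.ndarray] = {}
    for loop in boundary_loops(cap):
        ring = cap.vertices[loop]
        seg = np.diff(np.vstack([ring, ring[:1]]), axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        perimeter = float(seglen.sum())
        if perimeter > max_perimeter or perimeter == 0:
            continue
        # perimeter-weighted centroid of the rim polyline
        mid = ring + 0.5 * seg
        centroid = (mid * seglen[:, None]).sum(axis=0) / perimeter
        d = np.linalg.norm(pts - centroid, axis=1)
        i = int(np.argmin(d))
        if d[i] <= match_tolerance:
            label = labels[i]
            if label in out:
                log.warning("multiple hole rims match landmark %s", label)
            out[label] = centroid
    return out
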