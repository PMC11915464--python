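"""Circumference, scaling, geodesic row distances, projection, statistics."""

import numpy as np
import pytest
import trimesh

from capforge import metrology
from capforge.errors import CapforgeError, ValidationError
from capforge.landmarks import LandmarkSet
from capforge.metrology import (circumference, geodesic_landmark_distances,
                                landmark_error_stats, radial_project,
                                scale_to_circumference)
from capforge.phantoms import make_ellipsoid, make_sphere


RING = 2 * np.pi * 100 * np.cos(0.1 * np.pi)  # 10% ring on R=100 sphere


def test_sphere_ring_circumference(sphere100, sphere100_landmarks):
    c = circumference(sphere100.mesh, sphere100_landmarks)
    assert c == pytest.approx(RING, rel=5e-3)


def test_circumference_scales_linearly(sphere100, sphere100_landmarks):
    scaled = trimesh.Trimesh(vertices=sphere100.mesh.vertices * 1.1,
                             faces=sphere100.mesh.faces, process=False)
    lm = LandmarkSet(system="10-10",
                     positions={k: v * 1.1 for k, v in
                                sphere100_landmarks.positions.items()},
                     fiducials=sphere100.fiducials)
    c0 = circumference(sphere100.mesh, sphere100_landmarks)
    c1 = circumference(scaled, lm)
    assert c1 / c0 == pytest.approx(1.1, rel=1e-9)


def test_fiducial_fallback_ring(sphere100):
    lm = LandmarkSet(system="10-10", positions={"Cz": [0, 0, 100.0]},
                     fiducials=sphere100.fiducials)
    c = circumference(sphere100.mesh, lm)  # Nz/LPA/Iz great circle
    assert c == pytest.approx(2 * np.pi * 100, rel=5e-3)


def test_collinear_anchors_rejected(sphere100, sphere100_landmarks):
    lm = LandmarkSet(
        system="10-10",
        positions={"Fpz": [100, 0, 0], "T7": [0, 0, 0], "Oz": [-100, 0, 0]})
    with pytest.raises(CapforgeError):
        circumference(sphere100.mesh, lm)


class TestScaleToCircumference:
    def test_current_target_is_identity(self, sphere100, sphere100_landmarks):
        c = circumference(sphere100.mesh, sphere100_landmarks)
        out, factor = scale_to_circumference(sphere100.mesh,
                                             sphere100_landmarks, c)
        assert factor == pytest.approx(1.0, abs=1e-12)

    def test_620mm_target_inverts_ring_formula(self, sphere100,
                                               sphere100_landmarks):
        out, factor = scale_to_circumference(sphere100.mesh,
                                             sphere100_landmarks, 620.0)
        r = np.linalg.norm(out.vertices, axis=1).mean()
        expect = 620.0 / (2 * np.pi * np.cos(0.1 * np.pi))
        assert r == pytest.approx(expect, rel=5e-3)


class TestGeodesicDistances:
    def test_sagittal_from_iz(self, sphere100, sphere100_landmarks):
        d = geodesic_landmark_distances(sphere100.mesh, sphere100_landmarks,
                                        "sagittal")
        assert d["Oz"] == pytest.approx(0.1 * np.pi * 100, rel=5e-3)
        assert d["Cz"] == pytest.approx(0.5 * np.pi * 100, rel=5e-3)

    def test_distances_increase_along_row(self, sphere100,
                                          sphere100_landmarks):
        for row in ("sagittal", "coronal"):
            d = geodesic_landmark_distances(sphere100.mesh,
                                            sphere100_landmarks, row)
            ordered = [d[l] for l in metrology.ROW_LABELS[row] if l in d]
            if row == "coronal":
                ordered = ordered[::-1]  # origin RPA: T7 is farthest
            else:
                ordered = ordered[::-1]  # origin Iz: Fpz is farthest
            assert all(a < b for a, b in zip(ordered, ordered[1:]))


class TestRadialProject:
    def test_concentric_spheres_scale_exactly(self):
        inner = make_sphere(100.0, 3).mesh
        outer = trimesh.Trimesh(vertices=inner.vertices * 1.03,
                                faces=inner.faces, process=False)
        p = inner.vertices[123]
        q = radial_project(p[None, :], [0, 0, 0], outer)[0]
        assert np.allclose(q, 1.03 * p, atol=1e-9)

    def test_surface_point_is_fixed(self):
        mesh = make_sphere(10.0, 3).mesh
        p = mesh.triangles_center[7]
        q = radial_project(p[None, :], [0, 0, 0], mesh)[0]
        assert np.linalg.norm(q - p) < 1e-9

    def test_matches_dense_ray_march_on_ellipsoid(self):
        ph = make_ellipsoid(10, 8, 9, density=4)
        center = np.zeros(3)
        p = np.array([3.0, 2.0, 5.0])
        q = radial_project(p[None, :], center, ph.mesh)[0]
        # independent oracle: march along the ray until the implicit
        # ellipsoid function changes sign on the mesh's inscribed surface
        d = p / np.linalg.norm(p)
        ts = np.linspace(0.1, 20, 400_000)
        pts = ts[:, None] * d
        val = ((pts[:, 0] / 10) ** 2 + (pts[:, 1] / 8) ** 2
               + (pts[:, 2] / 9) ** 2)
        t_cross = ts[np.searchsorted(val, 1.0)]
        assert np.linalg.norm(q - t_cross * d) < 0.05  # mesh-chord error

    def test_missing_ray_reports_indices(self):
        mesh = make_sphere(1.0, 2).mesh
        with pytest.raises(CapforgeError, match="missed"):
            radial_project(np.array([[5.0, 0, 0]]), [3.0, 0, 0], mesh)


class TestErrorStats:
    def test_identity_gives_perfect_fit(self):
        ref = {"a": 1.0, "b": 2.0, "c": 3.0}
        rep = landmark_error_stats(ref, dict(ref))
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.mean_error == 0 and rep.sd_error == 0

    def test_constant_offset(self):
        ref = {"a": 10.0, "b": 20.0, "c": 30.0}
        mes = {k: v + 1.0 for k, v in ref.items()}
        rep = landmark_error_stats(ref, mes)
        assert rep.mean_error == pytest.approx(1.0)
        assert rep.sd_error == pytest.approx(0.0, abs=1e-12)
        assert rep.r_squared == pytest.approx(1.0)

    def test_toy_table_matches_hand_computation(self):
        ref = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0, "e": 5.0}
        mes = {"a": 1.1, "b": 1.9, "c": 3.2, "d": 3.8, "e": 5.1}
        rep = landmark_error_stats(ref, mes)
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([1.1, 1.9, 3.2, 3.8, 5.1])
        r2 = (np.corrcoef(x, y)[0, 1]) ** 2
        assert rep.r_squared == pytest.approx(r2)
        assert rep.mean_error == pytest.approx(np.abs(y - x).mean())
        assert rep.sd_error == pytest.approx(np.abs(y - x).std())

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            landmark_error_stats({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})
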