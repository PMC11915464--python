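"""Dual mesh, decimation, registration, grommets, cuts and wireframe."""

import numpy as np
import pytest
import trimesh

from capforge import capbuild
from capforge.capbuild import (CapParams, GrommetSpec, boundary_loops,
                               coarsen, cut_grommet_holes, cut_margins,
                               dual_mesh, place_grommets, register_landmarks,
                               thicken_margin, wireframe)
from capforge.errors import TopologyError, ValidationError
from capforge.geometry import closest_point_on_mesh
from capforge.landmarks import LandmarkSet
from capforge.phantoms import make_sphere


@pytest.fixture(scope="module")
def sphere_d3():
    return make_sphere(100.0, 3)


class TestDualMesh:
    def test_tetrahedron_is_self_dual(self):
        tet = trimesh.Trimesh(
            vertices=[[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
            faces=[[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]],
            process=False)
        dual = dual_mesh(tet)
        assert len(dual.vertices) == 4
        assert len(dual.faces) == 4
        assert all(len(f) == 3 for f in dual.faces)

    def test_icosahedron_dual_is_pentagonal_dodecahedron(self):
        ico = trimesh.creation.icosahedron()
        dual = dual_mesh(ico)
        assert len(dual.vertices) == 20  # one per input face
        assert len(dual.faces) == 12     # one per input vertex
        assert all(len(f) == 5 for f in dual.faces)

    def test_counts_swap_for_sphere(self, sphere_d3):
        dual = dual_mesh(sphere_d3.mesh)
        assert len(dual.vertices) == len(sphere_d3.mesh.faces)
        assert len(dual.faces) == len(sphere_d3.mesh.vertices)

    def test_open_mesh_rejected(self, sphere_d3):
        open_mesh = trimesh.Trimesh(vertices=sphere_d3.mesh.vertices,
                                    faces=sphere_d3.mesh.faces[:-5],
                                    process=False)
        with pytest.raises(TopologyError):
            dual_mesh(open_mesh)


class TestCoarsen:
    def test_keep_ratio_one_is_identity(self, sphere_d3):
        out = coarsen(sphere_d3.mesh, 1.0)
        assert np.array_equal(out.faces, sphere_d3.mesh.faces)
        assert out.metadata["hausdorff_to_input"] == 0.0

    def test_five_percent_stays_closed(self, sphere_d3):
        out = coarsen(sphere_d3.mesh, 0.05)
        e0 = len(sphere_d3.mesh.edges_unique)
        assert len(out.edges_unique) <= 0.05 * e0 + 3
        assert out.is_watertight
        # shape roughly preserved at this very coarse density (~30 vertices);
        # the 2%-of-radius bound at production density is asserted in the
        # acceptance suite
        assert out.metadata["hausdorff_to_input"] < 0.2 * 100

    def test_unreachable_ratio_reports_minimum(self):
        tiny = make_sphere(1.0, 1).mesh
        with pytest.raises(ValidationError, match="minimum achievable"):
            coarsen(tiny, 0.01)


class TestRegister:
    def test_on_surface_points_are_fixed(self, sphere_d3):
        lm = LandmarkSet(system="10-20", positions={
            "Cz": sphere_d3.mesh.vertices[0],
            "Fz": sphere_d3.mesh.vertices[10],
            "Pz": sphere_d3.mesh.vertices[20]})
        reg = register_landmarks(lm, sphere_d3.mesh)
        assert max(reg.snap_distances.values()) < 1e-9

    def test_offset_point_projects_back(self, sphere_d3):
        v = sphere_d3.mesh.vertices[5]
        n = sphere_d3.mesh.vertex_normals[5]
        lm = LandmarkSet(system="10-20", positions={"Cz": v + 1.0 * n})
        reg = register_landmarks(lm, sphere_d3.mesh)
        assert np.linalg.norm(reg["Cz"] - v) < 0.05

    def test_snap_onto_coarse_sphere_bounded(self, sphere_d3):
        coarse = coarsen(sphere_d3.mesh, 0.05)
        labels = {f"p{i}": sphere_d3.mesh.vertices[i * 37]
                  for i in range(12)}
        reg = register_landmarks(LandmarkSet(system="10-20",
                                             positions=labels), coarse)
        assert max(reg.snap_distances.values()) < 0.2 * 100
        # cross-check against brute-force nearest-triangle scan
        pts, dist, _ = closest_point_on_mesh(coarse, np.stack(
            list(labels.values())))
        assert np.allclose(sorted(dist),
                           sorted(reg.snap_distances.values()), atol=1e-12)


class TestGrommets:
    def test_polar_grommet_axis_is_z(self, sphere_d3):
        lm = LandmarkSet(system="10-20", positions={"Cz": [0, 0, 100.0]})
        reg = register_landmarks(lm, sphere_d3.mesh)
        cutter = place_grommets(sphere_d3.mesh, reg, GrommetSpec())[0]
        # prism axis: direction of maximal extent
        ext = cutter.bounds[1] - cutter.bounds[0]
        assert ext[2] == pytest.approx(20.0, abs=0.2)
        assert ext[0] == pytest.approx(2 * 4.0, rel=0.05)
        assert ext[1] == pytest.approx(2 * 4.0, rel=0.05)

    def test_axes_match_analytic_normals(self, sphere_d3):
        rng = np.random.default_rng(3)
        pts = sphere_d3.mesh.vertices[rng.choice(len(sphere_d3.mesh.vertices),
                                                 8, replace=False)]
        lm = LandmarkSet(system="10-20",
                         positions={f"p{i}": p for i, p in enumerate(pts)})
        reg = register_landmarks(lm, sphere_d3.mesh)
        cutters = place_grommets(sphere_d3.mesh, reg, GrommetSpec())
        for p, cutter in zip(pts, cutters):
            axis = p / np.linalg.norm(p)  # analytic sphere normal
            center = cutter.triangles_center.mean(axis=0)
            # cutter cap centers lie along +-axis from the landmark
            spread = (cutter.vertices - center) @ axis
            assert abs(spread).max() == pytest.approx(10.0, rel=0.05)

    def test_hole_census_and_centroid_proximity(self, sphere_d3):
        labels = {"Cz": [0, 0, 100.0],
                  "Fz": 100 * np.array([np.cos(0.3 * np.pi), 0,
                                        np.sin(0.3 * np.pi)]),
                  "Pz": 100 * np.array([-np.cos(0.3 * np.pi), 0,
                                        np.sin(0.3 * np.pi)])}
        reg = register_landmarks(
            LandmarkSet(system="10-20", positions=labels), sphere_d3.mesh)
        spec = GrommetSpec()
        cutters = place_grommets(sphere_d3.mesh, reg, spec)
        holed = cut_grommet_holes(sphere_d3.mesh, cutters)
        loops = boundary_loops(holed)
        assert len(loops) == 3
        for loop in loops:
            ring = holed.vertices[loop]
            centroid = ring.mean(axis=0)
            d = min(np.linalg.norm(centroid - reg[k]) for k in labels)
            assert d < spec.radius / 2

    def test_zero_cutters_identity(self, sphere_d3):
        out = cut_grommet_holes(sphere_d3.mesh, [])
        assert len(out.faces) == len(sphere_d3.mesh.faces)


class TestMargins:
    def test_face_and_neck_cuts(self, sphere_d3):
        capped = cut_margins(sphere_d3.mesh, sphere_d3.fiducials, CapParams())
        # neck: outside the face opening everything below -R/3 in z is gone
        v = capped.vertices
        away_from_face = v[:, 0] < 0  # back half (Nz is on +x)
        assert v[away_from_face, 2].min() > -100 / 3 - 1e-6
        # Nz removed, vertex kept
        _, d_nz, _ = closest_point_on_mesh(capped, np.array([[100., 0, 0]]))
        assert d_nz[0] > 5.0
        _, d_cz, _ = closest_point_on_mesh(capped, np.array([[0., 0, 100]]))
        assert d_cz[0] < 5.0

    def test_overcut_rejected(self, sphere_d3):
        params = CapParams(neck_height_fraction=0.95)
        with pytest.raises(ValidationError):
            cut_margins(sphere_d3.mesh, sphere_d3.fiducials, params)


class TestThickenMargin:
    def test_closed_mesh_rejected(self, sphere_d3):
        with pytest.raises(TopologyError):
            thicken_margin(sphere_d3.mesh, 5.0)

    def test_zero_band_tags_nothing(self, sphere_d3):
        capped = cut_margins(sphere_d3.mesh, sphere_d3.fiducials)
        tagged = thicken_margin(capped, 0.0)
        assert tagged.metadata["margin_edge_tags"].sum() == 0

    def test_tags_match_bruteforce_distance_scan(self, sphere_d3):
        capped = cut_margins(sphere_d3.mesh, sphere_d3.fiducials)
        band = 12.0
        tagged = thicken_margin(capped, band, min_loop_fraction=0.0)
        tags = tagged.metadata["margin_edge_tags"]
        loops = boundary_loops(capped)
        segs = []
        for loop in loops:
            pts = capped.vertices[loop]
            for i in range(len(pts)):
                segs.append((pts[i], pts[(i + 1) % len(pts)]))

        def dist_to_boundary(p):
            best = np.inf
            for a, b in segs:
                ab = b - a
                t = np.clip(np.dot(p - a, ab) / max(np.dot(ab, ab), 1e-30),
                            0, 1)
                best = min(best, np.linalg.norm(a + t * ab - p))
            return best

        edges = tagged.edges_unique
        rng = np.random.default_rng(0)
        for idx in rng.choice(len(edges), 60, replace=False):
            a, b = edges[idx]
            expect = (dist_to_boundary(capped.vertices[a]) <= band
                      or dist_to_boundary(capped.vertices[b]) <= band)
            assert bool(tags[idx]) == expect


class TestWireframe:
    def test_thick_wire_on_fine_mesh_rejected(self, sphere_d3):
        capped = cut_margins(sphere_d3.mesh, sphere_d3.fiducials)
        with pytest.raises(ValidationError, match="keep_ratio"):
            wireframe(capped, wire_thickness=25.0)

    def test_output_is_edge_manifold_and_closed(self, sphere_d3):
        coarse = coarsen(sphere_d3.mesh, 0.05)
        capped = cut_margins(coarse, sphere_d3.fiducials)
        solid = wireframe(capped, 2.5, strict_edge_check=False)
        edges = np.sort(np.concatenate(
            [solid.faces[:, [0, 1]], solid.faces[:, [1, 2]],
             solid.faces[:, [2, 0]]]), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        assert (counts == 2).all()

    def test_bounding_box_containment(self, sphere_d3):
        coarse = coarsen(sphere_d3.mesh, 0.05)
        capped = cut_margins(coarse, sphere_d3.fiducials)
        t = 2.5
        solid = wireframe(capped, t, strict_edge_check=False)
        lo, hi = capped.bounds
        assert (solid.bounds[0] >= lo - t - 1e-9).all()
        assert (solid.bounds[1] <= hi + t + 1e-9).all()

    def test_margin_tags_double_strut_radius(self, sphere_d3):
        coarse = coarsen(sphere_d3.mesh, 0.05)
        capped = cut_margins(coarse, sphere_d3.fiducials)
        capped = thicken_margin(capped, 10.0)
        solid = wireframe(capped, 2.5, strict_edge_check=False)
        struts = solid.metadata["struts"]
        tags = capped.metadata["margin_edge_tags"]
        assert set(np.unique(struts["radii"])) == {1.25, 2.5}
        assert np.allclose(struts["radii"][tags], 2.5)
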