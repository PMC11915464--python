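"""Defect diagnosis, welding, repair and voxel re-tessellation."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from capforge.errors import RepairError, ValidationError
from capforge.geometry import weld_vertices
from capforge.phantoms import make_sphere
from capforge.printable import diagnose, remesh_solidify, repair, weld


@pytest.fixture(scope="module")
def clean_sphere():
    return make_sphere(10.0, 3).mesh


class TestDiagnose:
    def test_clean_sphere_all_zero(self, clean_sphere):
        rep = diagnose(clean_sphere)
        assert rep.is_printable
        assert rep.volume == pytest.approx(4 / 3 * np.pi * 1000, rel=0.02)

    def test_stacked_identical_triangles_flagged(self):
        mesh = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0],
                      [0, 0, 0], [1, 0, 0], [0, 1, 0]],
            faces=[[0, 1, 2], [3, 4, 5]], process=False)
        rep = diagnose(mesh, check_self_intersections=False)
        assert rep.duplicate_vertices == 3
        assert rep.boundary_edges == 6
        assert not rep.is_printable

    def test_degenerate_elements_counted(self):
        mesh = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 0, 1e-15]],
            faces=[[0, 1, 2], [0, 1, 3]], process=False)
        rep = diagnose(mesh, check_self_intersections=False)
        assert rep.zero_area_faces >= 1
        assert rep.zero_length_edges >= 1

    def test_open_cube_has_four_boundary_edges(self):
        cube = trimesh.creation.box(extents=(1, 1, 1))
        top = cube.face_normals[:, 2] > 0.9
        open_cube = trimesh.Trimesh(vertices=cube.vertices,
                                    faces=cube.faces[~top], process=False)
        rep = diagnose(open_cube, check_self_intersections=False)
        assert rep.boundary_edges == 4  # the quad ring; diagonal vanishes

    def test_crossing_triangles_detected(self):
        mesh = trimesh.Trimesh(
            vertices=[[-1, -1, 0], [1, -1, 0], [0, 2, 0],
                      [0, -1, -1], [0, -1, 1], [0, 2, 0.2]],
            faces=[[0, 1, 2], [3, 4, 5]], process=False)
        rep = diagnose(mesh)
        assert rep.self_intersecting_pairs == 1

    def test_inverted_face_count(self, clean_sphere):
        faces = clean_sphere.faces.copy()
        faces[0] = faces[0][::-1]
        flipped = trimesh.Trimesh(vertices=clean_sphere.vertices, faces=faces,
                                  process=False)
        rep = diagnose(flipped, check_self_intersections=False)
        assert rep.inverted_faces == 1


class TestWeld:
    def test_zero_tolerance_merges_exact_duplicates_only(self):
        mesh = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 0],
                      [1, 0, 1e-9]],
            faces=[[0, 1, 2], [3, 4, 2]], process=False)
        out = weld(mesh, 0.0)
        assert len(out.vertices) == 4

    def test_tolerance_refused_at_feature_size(self, clean_sphere):
        with pytest.raises(ValidationError):
            weld(clean_sphere, tolerance=3.0, min_feature=2.5)

    @settings(deadline=None, derandomize=True, max_examples=10)
    @given(st.floats(0.0, 0.3))
    def test_weld_idempotent(self, tol):
        mesh = make_sphere(5.0, 2).mesh
        once = weld(mesh, tol)
        twice = weld(once, tol)
        assert len(twice.vertices) == len(once.vertices)
        assert len(twice.faces) == len(once.faces)

    def test_stl_weld_recovers_off_vertex_count(self, tmp_path):
        from capforge.mesh_io import read_mesh, write_mesh
        mesh = make_sphere(7.0, 2).mesh
        write_mesh(mesh, tmp_path / "m.stl")
        write_mesh(mesh, tmp_path / "m.off")
        a = read_mesh(tmp_path / "m.stl")   # STL merge is bit-exact on read
        b = read_mesh(tmp_path / "m.off")
        assert len(weld(a, 1e-6).vertices) == len(b.vertices)


class TestRepair:
    def test_clean_sphere_identity_up_to_face_order(self, clean_sphere):
        out = repair(clean_sphere)
        assert len(out.vertices) == len(clean_sphere.vertices)
        assert out.volume == pytest.approx(clean_sphere.volume, rel=1e-9)

    def test_punctured_sphere_sealed_with_small_volume_change(self,
                                                              clean_sphere):
        faces = np.delete(clean_sphere.faces.view(np.ndarray),
                          [3, 50, 200], axis=0)
        holey = trimesh.Trimesh(vertices=clean_sphere.vertices, faces=faces,
                                process=False)
        out = repair(holey)
        assert diagnose(out).is_printable
        assert abs(out.volume - clean_sphere.volume) / clean_sphere.volume < 1e-3

    def test_inside_out_sphere_reoriented(self, clean_sphere):
        inv = trimesh.Trimesh(vertices=clean_sphere.vertices,
                              faces=clean_sphere.faces[:, ::-1].copy(),
                              process=False)
        assert inv.volume < 0
        out = repair(inv)
        assert out.volume > 0

    def test_large_hole_aborts(self, clean_sphere):
        # remove a 30-face patch: the boundary loop exceeds the fill cap
        center = clean_sphere.triangles_center
        patch = np.argsort(np.linalg.norm(center - [0, 0, 10], axis=1))[:30]
        faces = np.delete(clean_sphere.faces.view(np.ndarray), patch, axis=0)
        holey = trimesh.Trimesh(vertices=clean_sphere.vertices, faces=faces,
                                process=False)
        with pytest.raises(RepairError) as exc:
            repair(holey)
        assert exc.value.report is not None

    def test_repair_idempotent_on_seeded_defects(self, clean_sphere):
        rng = np.random.default_rng(11)
        faces = np.delete(clean_sphere.faces.view(np.ndarray),
                          rng.choice(len(clean_sphere.faces), 2,
                                     replace=False), axis=0)
        # add a duplicated vertex wart
        verts = np.vstack([clean_sphere.vertices,
                           clean_sphere.vertices[:1] + 1e-9])
        holey = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        once = repair(holey)
        twice = repair(once)
        assert len(twice.vertices) == len(once.vertices)
        assert len(twice.faces) == len(once.faces)
        assert twice.volume == pytest.approx(once.volume, rel=1e-12)


class TestRemeshSolidify:
    def _wire(self, segments, radii, thickness):
        parts = [trimesh.creation.cylinder(radius=r, segment=s, sections=12)
                 for s, r in zip(segments, radii)]
        solid = trimesh.util.concatenate(parts)
        solid.metadata["struts"] = {
            "segments": np.asarray(segments, dtype=float),
            "radii": np.asarray(radii, dtype=float),
            "joints": np.zeros((0, 3)),
            "joint_radii": np.zeros(0),
            "wire_thickness": thickness,
        }
        return solid

    def test_single_strut_volume_matches_cylinder(self):
        wire = self._wire([[[0, 0, 0], [10, 0, 0]]], [1.0], 2.0)
        out = remesh_solidify(wire, 0.5)
        expect = np.pi * 1.0 ** 2 * 10
        assert out.is_watertight
        assert abs(out.volume - expect) / expect < 0.10

    def test_crossing_struts_fuse_into_one_component(self):
        wire = self._wire([[[-5, 0, 0], [5, 0, 0]], [[0, -5, 0.5], [0, 5, 0.5]]],
                          [1.0, 1.0], 2.0)
        out = remesh_solidify(wire, 0.5)
        assert out.is_watertight
        assert len(out.split(only_watertight=False)) == 1
        assert diagnose(out).is_printable

    def test_pitch_guard(self):
        wire = self._wire([[[0, 0, 0], [10, 0, 0]]], [1.0], 2.0)
        with pytest.raises(ValidationError):
            remesh_solidify(wire, 5.0)


def test_weld_vertices_single_linkage_chain():
    """Chained near-duplicates merge transitively (single linkage)."""
    v = np.array([[0, 0, 0], [0.9, 0, 0], [1.8, 0, 0], [5, 0, 0],
                  [0, 5, 0], [0, 0, 5]])
    f = np.array([[0, 3, 4], [2, 4, 5]])
    wv, wf = weld_vertices(v, f, tolerance=1.0)
    assert len(wv) == 4  # first three collapse into one cluster
    assert len(wf) == 2
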