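"""Cz refinement, montage placement, equivariances, landmark mesh."""

import numpy as np
import pytest
import trimesh

import capforge as cf
from capforge.capbuild import boundary_loops
from capforge.errors import RecipeError, ValidationError
from capforge.landmarks import Fiducials, landmark_mesh, refine_cz
from capforge.montage import CurveRecipe, RecipeEntry, default_recipe
from capforge.phantoms import make_sphere


def test_fiducial_validation():
    with pytest.raises(ValidationError):
        Fiducials(nz=[1, 0, 0], iz=[1, 0, 0], lpa=[0, -1, 0], rpa=[0, 1, 0],
                  cz0=[0, 0, 1])
    with pytest.raises(ValidationError):  # Cz0 in the Nz-Iz line: degenerate
        Fiducials(nz=[1, 0, 0], iz=[-1, 0, 0], lpa=[0, -1, 0], rpa=[0, 1, 0],
                  cz0=[0.5, 0, 0])


def test_cz_converges_to_pole_from_30_degrees(sphere100):
    cz, iters = refine_cz(sphere100.mesh, sphere100.fiducials)
    assert iters < 50
    assert np.linalg.norm(cz - [0, 0, 100]) < 1e-3 * 100


def test_cz_bisection_residuals(sphere100):
    from capforge.landmarks import reference_curves
    cz, _ = refine_cz(sphere100.mesh, sphere100.fiducials)
    curves = reference_curves(sphere100.mesh, sphere100.fiducials, cz=cz)
    for row in ("sagittal", "coronal"):
        curve = curves[row]
        _, s_cz, _ = curve.nearest(cz)
        assert abs(s_cz - curve.length / 2) / curve.length < 1e-4


def test_cz_iteration_limit_raises():
    ph = make_sphere(10.0, 3)
    from capforge.errors import ConvergenceError
    with pytest.raises(ConvergenceError):
        refine_cz(ph.mesh, ph.fiducials, tol=0.0, max_iter=3)


def test_sagittal_row_matches_analytic_positions(sphere100,
                                                 sphere100_landmarks):
    lm = sphere100_landmarks
    for label, p in sphere100.analytic_landmarks.items():
        assert np.linalg.norm(lm[label] - p) < 0.5, label


def test_coronal_row_labels_present(sphere100_landmarks):
    for label in ("C5", "C3", "C1", "C2", "C4", "C6", "T7", "T8"):
        assert label in sphere100_landmarks


def test_legacy_t3_t4_aliases(sphere100_landmarks):
    assert np.allclose(sphere100_landmarks["T3"], sphere100_landmarks["T7"])


def test_label_nesting_across_systems(sphere_d4):
    sets = {}
    for system in ("10-20", "10-10", "10-5"):
        sets[system] = cf.compute_landmarks(sphere_d4.mesh,
                                            sphere_d4.fiducials, system)
    assert set(sets["10-20"].positions) < set(sets["10-10"].positions)
    assert set(sets["10-10"].positions) < set(sets["10-5"].positions)
    for a, b in (("10-20", "10-10"), ("10-10", "10-5")):
        for k in sets[a].positions:
            assert np.allclose(sets[a][k], sets[b][k], atol=1e-9), k


def test_ten_twenty_has_21_positions(sphere_d4):
    lm = cf.compute_landmarks(sphere_d4.mesh, sphere_d4.fiducials, "10-20")
    assert len(lm.positions) == 21


def test_unresolved_recipe_anchor_raises(sphere_d4):
    bad = CurveRecipe((RecipeEntry(("Nz", "Qz", "Iz"), ((0.5, "X"),)),))
    with pytest.raises(RecipeError):
        cf.compute_landmarks(sphere_d4.mesh, sphere_d4.fiducials, "10-20",
                             recipe=bad)


class TestEquivariance:
    def _transformed(self, ph, fun):
        f = ph.fiducials
        mesh = trimesh.Trimesh(vertices=fun(ph.mesh.vertices),
                               faces=ph.mesh.faces.copy(), process=False)
        fid = Fiducials(nz=fun(f.nz[None])[0], iz=fun(f.iz[None])[0],
                        lpa=fun(f.lpa[None])[0], rpa=fun(f.rpa[None])[0],
                        cz0=fun(f.cz0[None])[0])
        return mesh, fid

    def test_scale(self, sphere_d4):
        base = cf.compute_landmarks(sphere_d4.mesh, sphere_d4.fiducials,
                                    "10-20")
        s = 1.37
        mesh, fid = self._transformed(sphere_d4, lambda v: v * s)
        scaled = cf.compute_landmarks(mesh, fid, "10-20")
        err = max(np.linalg.norm(scaled[k] - s * base[k])
                  for k in base.positions)
        assert err < 1e-9 * 100 * s

    def test_rigid_motion(self, sphere_d4):
        base = cf.compute_landmarks(sphere_d4.mesh, sphere_d4.fiducials,
                                    "10-20")
        rng = np.random.default_rng(7)
        R = trimesh.transformations.euler_matrix(
            *rng.uniform(0, 2 * np.pi, 3))[:3, :3]
        t = rng.uniform(-40, 40, 3)
        mesh, fid = self._transformed(sphere_d4, lambda v: v @ R.T + t)
        moved = cf.compute_landmarks(mesh, fid, "10-20")
        err = max(np.linalg.norm(moved[k] - (base[k] @ R.T + t))
                  for k in base.positions)
        assert err < 1e-9 * 100

    def test_mirror_swaps_left_right(self, sphere_d4):
        base = cf.compute_landmarks(sphere_d4.mesh, sphere_d4.fiducials,
                                    "10-20")
        f = sphere_d4.fiducials
        mesh = trimesh.Trimesh(
            vertices=sphere_d4.mesh.vertices * [1, -1, 1],
            faces=sphere_d4.mesh.faces[:, ::-1].copy(), process=False)
        fid = Fiducials(nz=f.nz * [1, -1, 1], iz=f.iz * [1, -1, 1],
                        lpa=f.rpa * [1, -1, 1], rpa=f.lpa * [1, -1, 1],
                        cz0=f.cz0 * [1, -1, 1])
        mirrored = cf.compute_landmarks(mesh, fid, "10-20")

        def swap(label):
            table = {"1": "2", "2": "1", "3": "4", "4": "3",
                     "5": "6", "6": "5", "7": "8", "8": "7"}
            return (label[:-1] + table[label[-1]]
                    if label[-1] in table else label)

        err = max(np.linalg.norm(mirrored[swap(k)] - base[k] * [1, -1, 1])
                  for k in base.positions)
        assert err < 1e-6 * 100


class TestLandmarkMesh:
    def test_vertices_are_exactly_landmarks(self, sphere100_landmarks):
        mesh = landmark_mesh(sphere100_landmarks)
        assert np.array_equal(mesh.vertices, sphere100_landmarks.array())
        assert mesh.metadata["landmark_labels"] == sphere100_landmarks.labels()

    def test_every_landmark_in_a_triangle(self, sphere100_landmarks):
        mesh = landmark_mesh(sphere100_landmarks)
        assert set(np.unique(mesh.faces)) == set(range(len(mesh.vertices)))

    def test_manifold_with_single_boundary_rim(self, sphere100_landmarks):
        mesh = landmark_mesh(sphere100_landmarks)
        edges = np.sort(np.concatenate([mesh.faces[:, [0, 1]],
                                        mesh.faces[:, [1, 2]],
                                        mesh.faces[:, [2, 0]]]), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        assert counts.max() <= 2
        assert len(boundary_loops(mesh)) == 1

    def test_too_few_points_rejected(self):
        from capforge.landmarks import LandmarkSet
        lm = LandmarkSet(system="10-20",
                         positions={"Cz": [0, 0, 1], "Fz": [1, 0, 1],
                                    "Pz": [0, 1, 1]})
        with pytest.raises(ValidationError):
            landmark_mesh(lm)
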