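"""Mesh construction, measures, flips and I/O."""

import numpy as np
import pytest

from memcurv import TriMesh, build_triangulated_sphere, flip_edge, icosahedron
from memcurv.errors import ConstraintInfeasibleError


class TestConstruction:
    def test_icosahedron_counts(self):
        mesh = icosahedron(1.0)
        assert (mesh.n_vertices, mesh.n_faces, mesh.n_edges) == (12, 20, 30)
        assert mesh.euler_characteristic == 2

    @pytest.mark.parametrize(
        "target, V, F, E",
        [
            (12, 12, 20, 30),
            (642, 642, 1280, 1920),     # class I, T = 64
            (5882, 5882, 11760, 17640),  # class II, T = 3 * 14^2 = 588
        ],
    )
    def test_geodesic_counts(self, target, V, F, E):
        mesh = build_triangulated_sphere(target, max(0.06 * V ** 0.5 * 10, 1.3) if target > 12 else 1.0,
                                         l_min=None, l_max=None)
        assert mesh.n_vertices == V
        assert mesh.n_faces == F
        assert mesh.n_edges == E
        assert mesh.euler_characteristic == 2
        mesh.validate()

    def test_nearest_class_reported(self):
        mesh = build_triangulated_sphere(650, 10.0, l_min=None, l_max=None)
        assert mesh.construction["achieved_vertices"] == 642
        assert mesh.construction["requested_vertices"] == 650

    def test_tether_infeasible_radius(self):
        with pytest.raises(ConstraintInfeasibleError):
            build_triangulated_sphere(642, 1.0)  # far too small for 642 vertices

    def test_tether_bounds_hold_at_model_density(self):
        mesh = build_triangulated_sphere(1002, 10.0)
        el = mesh.edge_lengths()
        assert el.min() >= 1.0
        assert el.max() <= np.sqrt(3.0)


class TestMeasures:
    def test_unit_cube(self, unit_cube_mesh):
        m = unit_cube_mesh.measure()
        assert m.total_area == pytest.approx(6.0)
        assert m.enclosed_volume == pytest.approx(1.0)

    def test_regular_tetrahedron(self):
        # edge a = 2: area = sqrt(3) a^2, volume = a^3 / (6 sqrt 2)
        v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        f = np.array([[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 2]])
        mesh = TriMesh(v, f)
        a = 2 * np.sqrt(2)
        m = mesh.measure()
        assert m.total_area == pytest.approx(np.sqrt(3) * a ** 2)
        assert m.enclosed_volume == pytest.approx(a ** 3 / (6 * np.sqrt(2)))

    def test_sphere_continuum_limit(self):
        mesh = build_triangulated_sphere(2562, 10.0, l_min=None, l_max=None)
        m = mesh.measure()
        assert m.total_area == pytest.approx(4 * np.pi * 100, rel=0.01)
        assert m.enclosed_volume == pytest.approx(4 / 3 * np.pi * 1000, rel=0.01)

    def test_refinement_converges_monotonically(self):
        errs = []
        for target in (162, 642, 2562):
            mesh = build_triangulated_sphere(target, 1.0, l_min=None, l_max=None)
            m = mesh.measure()
            errs.append(abs(m.total_area - 4 * np.pi) / (4 * np.pi))
        assert errs[0] > errs[1] > errs[2]


class TestFlips:
    def test_flip_is_involution(self, sphere_642):
        mesh = sphere_642.copy()
        before = {tuple(sorted(t)) for t in mesh.faces.tolist()}
        edge = tuple(mesh.edges[100])
        assert flip_edge(mesh, edge)
        mid = {tuple(sorted(t)) for t in mesh.faces.tolist()}
        assert mid != before
        # the new diagonal connects the two opposite vertices; flipping it back
        quad = [t for t in before ^ mid]
        new_edge = set.intersection(*[set(t) for t in mid - before])
        assert len(new_edge) == 2
        assert flip_edge(mesh, tuple(new_edge))
        after = {tuple(sorted(t)) for t in mesh.faces.tolist()}
        assert after == before

    def test_flip_preserves_counts_and_orientation(self, sphere_642):
        mesh = sphere_642.copy()
        V, E, F = mesh.n_vertices, mesh.n_edges, mesh.n_faces
        vol0 = mesh.measure().enclosed_volume
        assert flip_edge(mesh, tuple(mesh.edges[7]))
        mesh.validate()
        assert (mesh.n_vertices, mesh.n_edges, mesh.n_faces) == (V, E, F)
        assert mesh.measure().enclosed_volume == pytest.approx(vol0, rel=0.01)

    def test_planar_quad_flip_areas_conserved(self, unit_cube_mesh):
        # the x = 0 cube face is a planar unit square split by diagonal
        # (0, 3); flipping swaps to diagonal (1, 2) and conserves area/volume
        mesh = unit_cube_mesh
        assert flip_edge(mesh, (0, 3))
        mesh.validate()
        m = mesh.measure()
        assert m.total_area == pytest.approx(6.0)
        assert m.enclosed_volume == pytest.approx(1.0)
        quads = {tuple(sorted(t)) for t in mesh.faces.tolist()}
        assert (0, 1, 2) in quads and (1, 2, 3) in quads

    def test_thousand_random_flips_keep_euler_characteristic(self, sphere_642):
        mesh = sphere_642.copy()
        rng = np.random.default_rng(0)
        done = 0
        attempts = 0
        while done < 1000 and attempts < 20000:
            e = tuple(mesh.edges[rng.integers(mesh.n_edges)])
            if flip_edge(mesh, e, l_min=0.1, l_max=5.0):
                done += 1
            attempts += 1
        assert done == 1000
        assert mesh.euler_characteristic == 2
        mesh.validate()

    def test_rejected_flip_signals_false(self, sphere_642):
        mesh = sphere_642.copy()
        # a tether bound that no new edge can satisfy forces rejection
        assert flip_edge(mesh, tuple(mesh.edges[0]), l_min=10.0) is False


class TestIncidenceBookkeeping:
    def test_incremental_edges_match_rebuild_after_flips(self, sphere_642):
        mesh = sphere_642.copy()
        rng = np.random.default_rng(3)
        for _ in range(200):
            flip_edge(mesh, tuple(mesh.edges[rng.integers(mesh.n_edges)]),
                      l_min=0.1, l_max=5.0)
        fresh = TriMesh(mesh.vertices.copy(), mesh.faces.copy())
        assert np.array_equal(mesh.edges, fresh.edges)


class TestIO:
    @pytest.mark.parametrize("ext", ["off", "ply"])
    def test_roundtrip(self, tmp_path, unit_cube_mesh, ext):
        path = tmp_path / f"mesh.{ext}"
        unit_cube_mesh.save(path)
        back = TriMesh.load(path)
        assert back.n_vertices == 8
        assert back.measure().enclosed_volume == pytest.approx(1.0)
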