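"""Triangular meshing and FE strain recovery from dot displacements."""

import numpy as np
import pytest

from strainquant import build_mesh, element_strain, node_strain
from strainquant.strain_fem import TriMesh, _signed_area2
from strainquant.tracking import DotTracks


def unit_grid9():
    return np.array([(x, y) for y in (0, 1, 2) for x in (0, 1, 2)], dtype=float)


def tracks_from(frames, reference=0):
    return DotTracks(positions=np.asarray(frames, dtype=float), reference_frame=reference)


def sym(A):
    return 0.5 * (A + A.T)


class TestBuildMesh:
    def test_three_points_single_element(self):
        mesh = build_mesh([(0, 0), (1, 0), (0, 1)])
        assert mesh.n_elements == 1
        assert sorted(mesh.elements[0]) == [0, 1, 2]

    def test_unit_grid_has_eight_half_area_triangles(self):
        mesh = build_mesh(unit_grid9())
        assert mesh.n_elements == 8
        assert np.allclose(mesh.element_areas, 0.5)
        # independent geometric oracle: the triangles tile the convex hull
        assert mesh.element_areas.sum() == pytest.approx(4.0)
        # every triangle is a half unit square (legs 1, 1, hypotenuse sqrt 2)
        for el in mesh.elements:
            p = mesh.nodes[el]
            sides = sorted(
                np.linalg.norm(p[i] - p[j]) for i, j in ((0, 1), (1, 2), (2, 0))
            )
            assert np.allclose(sides, [1.0, 1.0, np.sqrt(2)])

    def test_elements_counter_clockwise(self):
        mesh = build_mesh(unit_grid9())
        assert np.all(_signed_area2(mesh.nodes, mesh.elements) > 0)

    def test_every_node_used(self):
        mesh = build_mesh(unit_grid9())
        assert set(mesh.elements.ravel()) == set(range(9))
        assert np.all(mesh.node_areas > 0)

    def test_collinear_points_error(self):
        with pytest.raises(ValueError):
            build_mesh([(0, 0), (1, 1), (2, 2)])

    def test_too_few_nodes_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            build_mesh([(0, 0), (1, 0)])

    def test_deterministic(self):
        m1 = build_mesh(unit_grid9())
        m2 = build_mesh(unit_grid9())
        assert np.array_equal(m1.elements, m2.elements)


class TestElementStrain:
    def setup_method(self):
        self.mesh = build_mesh(unit_grid9())

    def test_pure_translation_gives_zero(self):
        displaced = self.mesh.nodes + np.array([3.7, -1.2])
        for e in range(self.mesh.n_elements):
            assert np.allclose(element_strain(self.mesh, e, displaced), 0, atol=1e-14)

    def test_uniaxial_stretch(self):
        a = 0.05
        displaced = self.mesh.nodes * np.array([1 + a, 1.0])
        for e in range(self.mesh.n_elements):
            eps = element_strain(self.mesh, e, displaced)
            assert np.allclose(eps, [[a, 0], [0, 0]], atol=1e-14)

    def test_simple_shear(self):
        g = 0.03
        displaced = self.mesh.nodes.copy()
        displaced[:, 0] += g * self.mesh.nodes[:, 1]
        for e in range(self.mesh.n_elements):
            eps = element_strain(self.mesh, e, displaced)
            assert np.allclose(eps, [[0, g / 2], [g / 2, 0]], atol=1e-14)

    def test_random_affine_matches_symmetric_part(self, rng):
        for _ in range(20):
            A = np.eye(2) + 0.1 * rng.standard_normal((2, 2))
            displaced = self.mesh.nodes @ A.T
            expected = sym(A) - np.eye(2)
            for e in range(self.mesh.n_elements):
                eps = element_strain(self.mesh, e, displaced)
                assert np.allclose(eps, expected, atol=1e-12)

    def test_matches_finite_difference_on_shape_functions(self, rng):
        """The constant element gradient equals a central finite difference
        of the linearly interpolated displacement field."""
        mesh = build_mesh([(0.0, 0.0), (2.0, 0.3), (0.5, 1.7)])
        u = rng.standard_normal((3, 2)) * 0.1
        displaced = mesh.nodes + u

        def interp_u(p):
            # barycentric interpolation of u at point p
            X = mesh.nodes[mesh.elements[0]]
            T = np.column_stack((X[1] - X[0], X[2] - X[0]))
            lam12 = np.linalg.solve(T, p - X[0])
            lam = np.array([1 - lam12.sum(), *lam12])
            return lam @ u[mesh.elements[0]]

        c = mesh.nodes.mean(axis=0)
        h = 1e-6
        grad_fd = np.empty((2, 2))
        for j in range(2):
            dp = np.zeros(2)
            dp[j] = h
            grad_fd[:, j] = (interp_u(c + dp) - interp_u(c - dp)) / (2 * h)
        eps = element_strain(mesh, 0, displaced)
        assert np.allclose(eps, sym(grad_fd), atol=1e-8)

    def test_degenerate_element_error(self):
        mesh = TriMesh(
            nodes=np.array([(0.0, 0.0), (1.0, 0.0), (2.0, 0.0)]),
            elements=np.array([[0, 1, 2]]),
            element_areas=np.array([0.0]),
        )
        with pytest.raises(ValueError, match="degenerate"):
            element_strain(mesh, 0, mesh.nodes)


class TestNodeStrain:
    def test_affine_exactness_at_every_node_and_frame(self, rng):
        """For tracks from time-dependent affine maps, every nodal tensor
        equals sym(A(t)) - I to machine precision."""
        nodes = unit_grid9() * 40
        mesh = build_mesh(nodes)
        n_frames = 7
        As = np.eye(2) + 0.08 * rng.standard_normal((n_frames, 2, 2))
        As[0] = np.eye(2)
        bs = rng.uniform(-5, 5, size=(n_frames, 2))
        bs[0] = 0
        positions = np.einsum("tij,nj->tni", As, nodes) + bs[:, None, :]
        trace = node_strain(mesh, tracks_from(positions))
        for t in range(n_frames):
            expected = sym(As[t]) - np.eye(2)
            assert np.abs(trace.node_strain[t] - expected).max() <= 1e-12

    def test_static_tracks_give_zero_mean_series(self):
        nodes = unit_grid9()
        mesh = build_mesh(nodes)
        trace = node_strain(mesh, tracks_from([nodes] * 5))
        assert np.allclose(trace.mean_xx, 0, atol=1e-15)
        assert np.allclose(trace.mean_yy, 0, atol=1e-15)

    def test_heterogeneous_field_matches_loop_oracle(self, rng):
        """Nodal recovery equals an explicit per-node area-weighted loop."""
        nodes = unit_grid9() * 10
        mesh = build_mesh(nodes)
        # quadratic displacement field: strains vary between elements
        u = 1e-3 * np.column_stack((nodes[:, 0] ** 2 / 10, nodes[:, 0] * nodes[:, 1] / 10))
        displaced = nodes + u
        trace = node_strain(mesh, tracks_from([nodes, displaced]))
        for n in range(9):
            acc = np.zeros((2, 2))
            wsum = 0.0
            for e in range(mesh.n_elements):
                if n in mesh.elements[e]:
                    a = mesh.element_areas[e]
                    acc += a * element_strain(mesh, e, displaced)
                    wsum += a
            assert np.allclose(trace.node_strain[1, n], acc / wsum, atol=1e-14)

    def test_translation_invariance_of_trace(self, rng):
        nodes = unit_grid9() * 25
        mesh = build_mesh(nodes)
        A = np.eye(2) + 0.05 * rng.standard_normal((2, 2))
        pos = np.stack([nodes, nodes @ A.T])
        t0 = node_strain(mesh, tracks_from(pos))
        t1 = node_strain(mesh, tracks_from(pos + np.array([11.0, -3.0])))
        # mesh built on untranslated reference; constant offsets cancel in u
        assert np.allclose(t0.node_strain, t1.node_strain, atol=1e-12)

    def test_rotation_leaks_quadratic_spurious_strain(self):
        """A rigid rotation by theta reads as ~theta^2/2 linear strain."""
        nodes = unit_grid9() * 50
        mesh = build_mesh(nodes)
        th = 0.01
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        c = nodes.mean(axis=0)
        rotated = (nodes - c) @ R.T + c
        trace = node_strain(mesh, tracks_from([nodes, rotated]))
        exx = trace.mean_xx[1]
        assert abs(exx) <= 1e-4
        assert abs(exx) == pytest.approx(th**2 / 2, rel=1e-3)

    def test_mesh_invariance_for_affine_fields(self, rng):
        """Delaunay and a fixed-diagonal triangulation of the 3x3 grid give
        identical nodal strains for affine deformations."""
        nodes = unit_grid9()
        delaunay = build_mesh(nodes)
        # fixed \-diagonal split of each grid square
        els = []
        for i in range(2):
            for j in range(2):
                n0 = 3 * i + j
                els += [[n0, n0 + 1, n0 + 3], [n0 + 1, n0 + 4, n0 + 3]]
        els = np.array(els)
        fixed = TriMesh(
            nodes=nodes,
            elements=els,
            element_areas=np.abs(_signed_area2(nodes, els)) / 2,
        )
        A = np.eye(2) + 0.06 * rng.standard_normal((2, 2))
        pos = np.stack([nodes, nodes @ A.T])
        td = node_strain(delaunay, tracks_from(pos))
        tf = node_strain(fixed, tracks_from(pos))
        assert np.allclose(td.node_strain, tf.node_strain, atol=1e-13)

    def test_node_count_mismatch_error(self):
        mesh = build_mesh(unit_grid9())
        with pytest.raises(ValueError, match="node count"):
            node_strain(mesh, tracks_from(np.zeros((2, 4, 2))))
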