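import numpy as np
import pytest

from maxalign import (
    DegenerateGeometryError,
    ICPParams,
    MeshProximity,
    RigidTransform,
    estimate_rigid_transform,
    icp_refine,
    initial_alignment,
    nearest_point_on_mesh,
    nearest_point_on_triangle,
)
from maxalign.synthetic import dome_mesh


class TestRigidTransform:
    def test_identity_and_inverse(self, rng):
        T = RigidTransform.from_axis_angle([1, 1, 0], 33.0, (1, 2, 3))
        pts = rng.standard_normal((10, 3))
        np.testing.assert_allclose(T.inverse().apply(T.apply(pts)), pts, atol=1e-12)

    def test_compose_order(self, rng):
        A = RigidTransform.from_axis_angle([0, 0, 1], 90.0, (1, 0, 0))
        B = RigidTransform.from_axis_angle([1, 0, 0], 45.0, (0, 2, 0))
        pts = rng.standard_normal((5, 3))
        np.testing.assert_allclose(
            A.compose(B).apply(pts), A.apply(B.apply(pts)), atol=1e-12
        )

    def test_rejects_non_rotation(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestEstimateRigidTransform:
    def test_identity(self, rng):
        pts = rng.standard_normal((10, 3))
        T = estimate_rigid_transform(pts, pts)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(T.translation, 0, atol=1e-12)

    def test_pure_translation(self, rng):
        pts = rng.standard_normal((10, 3))
        T = estimate_rigid_transform(pts, pts + [5.0, 0.0, 0.0])
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(T.translation, [5, 0, 0], atol=1e-12)

    def test_recovers_known_rotation(self, rng):
        pts = rng.standard_normal((10, 3))
        Q = RigidTransform.from_axis_angle([0, 0, 1], 30.0)
        T = estimate_rigid_transform(pts, Q.apply(pts))
        np.testing.assert_allclose(T.rotation, Q.rotation, atol=1e-9)

    def test_equivariant_under_conjugation(self, rng):
        pts = rng.standard_normal((12, 3))
        tgt = RigidTransform.from_axis_angle([1, 2, 0], 17.0, (0.3, 0, -1)).apply(pts)
        Q = RigidTransform.from_axis_angle([0, 1, 1], 52.0)
        T = estimate_rigid_transform(pts, tgt)
        TQ = estimate_rigid_transform(Q.apply(pts), Q.apply(tgt))
        np.testing.assert_allclose(
            TQ.rotation, Q.rotation @ T.rotation @ Q.rotation.T, atol=1e-9
        )

    def test_collinear_rejected(self):
        pts = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(DegenerateGeometryError):
            estimate_rigid_transform(pts, pts)

    def test_too_few_pairs(self):
        with pytest.raises(DegenerateGeometryError):
            estimate_rigid_transform(np.zeros((2, 3)), np.zeros((2, 3)))


class TestInitialAlignment:
    def test_identical_clouds(self):
        pts = dome_mesh().vertices
        T = initial_alignment(pts, pts)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(T.translation, 0, atol=1e-6)

    def test_translated_clouds(self):
        pts = dome_mesh().vertices
        T = initial_alignment(pts, pts + [3.0, -2.0, 1.0])
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(T.translation, [3, -2, 1], atol=1e-6)

    def test_large_rotation_recovered_into_icp_basin(self):
        pts = dome_mesh().vertices
        Q = RigidTransform.from_axis_angle([0, 0, 1], 170.0, (4.0, -7.0, 2.0))
        T = initial_alignment(Q.apply(pts), pts)
        residual = T.compose(Q)
        assert residual.rotation_angle_deg() < 5.0

    def test_isotropic_falls_back_to_centroids(self, rng):
        # points on a sphere: all covariance eigenvalues equal; enough points
        # that the sampling spread stays within the 1.05 isotropy ratio
        p = rng.standard_normal((20_000, 3))
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        with pytest.warns(UserWarning, match="near-isotropic"):
            T = initial_alignment(p, p + [0.0, 0.0, 2.0])
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(T.translation, [0, 0, 2], atol=1e-9)


def _grid_oracle(p, a, b, c, n=120, refinements=3):
    """Independent dense-barycentric-grid closest-point search."""
    lo_u, hi_u, lo_v, hi_v = 0.0, 1.0, 0.0, 1.0
    best = None
    for _ in range(refinements + 1):
        us = np.linspace(lo_u, hi_u, n)
        vs = np.linspace(lo_v, hi_v, n)
        uu, vv = np.meshgrid(us, vs)
        mask = uu + vv <= 1.0 + 1e-12
        U, V = uu[mask], vv[mask]
        pts = a + U[:, None] * (b - a) + V[:, None] * (c - a)
        d = np.linalg.norm(pts - p, axis=1)
        i = int(np.argmin(d))
        best = d[i]
        w_u = (hi_u - lo_u) * 2.5 / n
        w_v = (hi_v - lo_v) * 2.5 / n
        lo_u, hi_u = max(0.0, U[i] - w_u), min(1.0, U[i] + w_u)
        lo_v, hi_v = max(0.0, V[i] - w_v), min(1.0, V[i] + w_v)
    return best


class TestNearestPointOnTriangle:
    def test_interior_projection(self):
        cp, d = nearest_point_on_triangle(
            (0.25, 0.25, 1.0), (0, 0, 0), (1, 0, 0), (0, 1, 0)
        )
        np.testing.assert_allclose(cp, [0.25, 0.25, 0.0], atol=1e-12)
        assert np.isclose(d, 1.0)

    def test_vertex_region(self):
        cp, d = nearest_point_on_triangle(
            (-1.0, -1.0, 0.0), (0, 0, 0), (1, 0, 0), (0, 1, 0)
        )
        np.testing.assert_allclose(cp, [0, 0, 0], atol=1e-12)
        assert np.isclose(d, np.sqrt(2.0))

    def test_degenerate_triangle_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            nearest_point_on_triangle((0, 0, 1), (0, 0, 0), (1, 0, 0), (2, 0, 0))

    def test_matches_dense_grid_oracle(self, rng):
        for _ in range(150):
            a, b, c = rng.uniform(-1, 1, (3, 3))
            if np.linalg.norm(np.cross(b - a, c - a)) < 1e-3:
                continue
            p = rng.uniform(-2, 2, 3)
            _, d = nearest_point_on_triangle(p, a, b, c)
            d_oracle = _grid_oracle(p, a, b, c)
            assert d <= d_oracle + 1e-12
            assert abs(d - d_oracle) < 1e-5


class TestNearestPointOnMesh:
    def test_mesh_vertex_is_at_distance_zero(self, unit_cube):
        cp, d, _ = nearest_point_on_mesh(unit_cube.vertices[3], unit_cube)
        assert d < 1e-12
        np.testing.assert_allclose(cp, unit_cube.vertices[3], atol=1e-12)

    def test_point_above_cube(self, unit_cube):
        cp, d, fid = nearest_point_on_mesh((0.5, 0.5, 10.0), unit_cube)
        assert np.isclose(d, 9.0)
        assert fid in (2, 3)  # a top face
        np.testing.assert_allclose(cp, [0.5, 0.5, 1.0], atol=1e-12)

    def test_matches_exhaustive_scan(self, rng):
        mesh = dome_mesh(n_rings=3, n_segments=20)  # 100 faces
        assert mesh.n_faces == 100
        prox = MeshProximity(mesh)
        queries = rng.uniform(-100, 100, (200, 3))
        _, dist, fid = prox.query(queries)
        tri = mesh.triangles()
        from maxalign.registration import _closest_on_triangles

        for q, d_fast, f_fast in zip(queries, dist, fid):
            cps = _closest_on_triangles(
                np.broadcast_to(q, (100, 3)), tri[:, 0], tri[:, 1], tri[:, 2]
            )
            ds = np.linalg.norm(cps - q, axis=1)
            f_brute = int(np.argmin(ds))  # argmin takes lowest index on ties
            assert abs(ds[f_brute] - d_fast) < 1e-12
            assert f_brute == f_fast


class TestIcpRefine:
    def test_fixed_point(self):
        mesh = dome_mesh()
        report = icp_refine(mesh.vertices, mesh)
        assert report.iterations_run <= 2
        assert report.rms_per_iteration[-1] < 1e-9
        assert report.final_transform.rotation_angle_deg() < 1e-9

    def test_recovers_small_displacement(self):
        # from an identity init ICP slides slowly along the smooth shell, so
        # give it an ample iteration budget (the pipeline normally seeds ICP
        # with the principal-axes alignment instead)
        mesh = dome_mesh()
        D = RigidTransform.from_axis_angle([0, 0, 1], 5.0, (0.5, 0.3, -0.2))
        report = icp_refine(
            D.apply(mesh.vertices),
            mesh,
            params=ICPParams(
                max_iterations=1000, rms_change_tolerance=1e-9, trim_fraction=0.0
            ),
        )
        err = report.final_transform.compose(D)
        assert err.rotation_angle_deg() < 0.05
        assert np.linalg.norm(err.translation) < 0.01

    def test_noisy_displacement_rms_near_noise_floor(self, rng):
        mesh = dome_mesh()
        sigma = 0.1
        D = RigidTransform.from_axis_angle([0, 0, 1], 5.0, (0.5, 0.3, -0.2))
        src = D.apply(mesh.vertices) + rng.normal(0, sigma, mesh.vertices.shape)
        report = icp_refine(
            src,
            mesh,
            params=ICPParams(
                max_iterations=500, rms_change_tolerance=1e-7, trim_fraction=0.0
            ),
        )
        assert 0.8 * sigma <= report.rms_per_iteration[-1] <= 1.3 * sigma
        err = report.final_transform.compose(D)
        assert err.rotation_angle_deg() < 0.3
        assert np.linalg.norm(err.translation) < 0.1

    def test_rms_monotone_nonincreasing(self, rng):
        mesh = dome_mesh()
        D = RigidTransform.from_axis_angle([1, 1, 0], 12.0, (3.0, -4.0, 2.0))
        src = D.apply(mesh.vertices) + rng.normal(0, 0.05, mesh.vertices.shape)
        report = icp_refine(src, mesh)
        r = report.rms_per_iteration
        assert all(r[i + 1] <= r[i] + 1e-12 for i in range(len(r) - 1))

    def test_exact_overlap_reaches_numerical_zero(self):
        mesh = dome_mesh()
        report = icp_refine(
            mesh.vertices, mesh, params=ICPParams(trim_fraction=0.0)
        )
        assert report.rms_per_iteration[-1] < 1e-7

    def test_final_transform_reproduces_final_rms(self):
        mesh = dome_mesh()
        D = RigidTransform.from_axis_angle([0, 1, 0], 8.0, (1.0, 0.5, -2.0))
        src = D.apply(mesh.vertices)
        report = icp_refine(src, mesh)
        prox = MeshProximity(mesh)
        _, dist, _ = prox.query(report.final_transform.apply(src))
        n_keep = len(src) - int(np.floor(0.1 * len(src)))
        rms = float(np.sqrt(np.mean(np.sort(dist)[:n_keep] ** 2)))
        assert rms <= report.rms_per_iteration[-1] + 1e-9

    def test_all_correspondences_rejected(self):
        from maxalign import RegistrationError

        mesh = dome_mesh()
        with pytest.raises(RegistrationError, match="max_correspondence_distance"):
            icp_refine(
                mesh.vertices + 500.0,
                mesh,
                params=ICPParams(max_correspondence_distance=0.1),
            )

    def test_subsampling_is_seeded(self):
        mesh = dome_mesh()
        D = RigidTransform.from_axis_angle([0, 0, 1], 3.0, (0.5, 0, 0))
        src = D.apply(mesh.vertices)
        p = ICPParams(sample_count=100)
        r1 = icp_refine(src, mesh, params=p, seed=5)
        r2 = icp_refine(src, mesh, params=p, seed=5)
        np.testing.assert_array_equal(
            r1.final_transform.rotation, r2.final_transform.rotation
        )
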