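import numpy as np
import pytest
import trimesh

from maxalign import (
    MeshFormatError,
    MeshValidationError,
    RigidTransform,
    TriangleMesh,
    compute_normals,
    deviation_palette,
    read_stl,
    validate_mesh,
    write_colored_ply,
    write_stl,
)


class TestStlRoundTrip:
    def test_binary_single_triangle_size_and_content(self, single_triangle, tmp_path):
        path = tmp_path / "tri.stl"
        write_stl(single_triangle, path, dialect="binary")
        assert path.stat().st_size == 84 + 50
        mesh = read_stl(path)
        assert mesh.n_vertices == 3
        assert mesh.n_faces == 1
        np.testing.assert_allclose(
            np.sort(mesh.vertices, axis=0),
            np.sort(single_triangle.vertices, axis=0),
        )

    def test_ascii_equals_binary_after_merging(self, single_triangle, tmp_path):
        pa, pb = tmp_path / "a.stl", tmp_path / "b.stl"
        write_stl(single_triangle, pa, dialect="ascii")
        write_stl(single_triangle, pb, dialect="binary")
        ma, mb = read_stl(pa), read_stl(pb)
        np.testing.assert_allclose(ma.vertices, mb.vertices, atol=1e-6)
        np.testing.assert_array_equal(ma.faces, mb.faces)

    @pytest.mark.parametrize("dialect", ["binary", "ascii"])
    def test_cube_round_trip_merges_vertices(self, unit_cube, tmp_path, dialect):
        path = tmp_path / "cube.stl"
        write_stl(unit_cube, path, dialect=dialect)
        mesh = read_stl(path)
        assert mesh.n_vertices == 8
        assert mesh.n_faces == 12
        # same vertex set within merge tolerance
        d = np.abs(
            np.sort(mesh.vertices.view("f8,f8,f8"), axis=0, order=["f0", "f1", "f2"])
            .view(np.float64).reshape(-1, 3)
            - np.sort(unit_cube.vertices.view("f8,f8,f8"), axis=0, order=["f0", "f1", "f2"])
            .view(np.float64).reshape(-1, 3)
        )
        assert d.max() < 1e-6

    def test_trimesh_reads_our_binary_output(self, unit_cube, tmp_path):
        """Independent reader agrees on the cube geometry."""
        path = tmp_path / "cube.stl"
        write_stl(unit_cube, path, dialect="binary")
        tm = trimesh.load(str(path), process=True)
        assert len(tm.faces) == 12
        assert len(tm.vertices) == 8
        assert np.isclose(tm.volume, 1.0)

    def test_we_read_trimesh_output(self, tmp_path):
        tm = trimesh.creation.box(extents=(1, 1, 1))
        path = tmp_path / "tm.stl"
        tm.export(str(path))
        mesh = read_stl(path)
        assert mesh.n_vertices == 8
        assert mesh.n_faces == 12

    def test_empty_mesh_write_rejected(self, tmp_path):
        empty = TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(MeshValidationError):
            write_stl(empty, tmp_path / "x.stl")


class TestStlErrors:
    def test_truncated_binary_names_byte_offset(self, unit_cube, tmp_path):
        path = tmp_path / "cube.stl"
        write_stl(unit_cube, path, dialect="binary")
        data = path.read_bytes()
        (tmp_path / "trunc.stl").write_bytes(data[:-30])
        with pytest.raises(MeshFormatError, match="byte offset"):
            read_stl(tmp_path / "trunc.stl")

    def test_malformed_ascii_names_line(self, tmp_path):
        bad = (
            "solid t\nfacet normal 0 0 1\nouter loop\n"
            "vertex 0 0 0\nvertex 1 0 zero\nvertex 0 1 0\n"
            "endloop\nendfacet\nendsolid t\n"
        )
        (tmp_path / "bad.stl").write_text(bad)
        with pytest.raises(MeshFormatError, match="line 5"):
            read_stl(tmp_path / "bad.stl")

    def test_missing_file(self, tmp_path):
        from maxalign import MeshIOError

        with pytest.raises(MeshIOError):
            read_stl(tmp_path / "nope.stl")


class TestValidateMesh:
    def test_removes_zero_area_face(self, unit_cube):
        v = unit_cube.vertices
        f = np.vstack([unit_cube.faces[:9], [[0, 0, 1]], unit_cube.faces[9:]])
        mesh, report = validate_mesh(TriangleMesh(v, f))
        assert mesh.n_faces == 12
        assert report["faces_removed"] == 1

    def test_clean_mesh_unchanged_and_idempotent(self, unit_cube):
        m1, r1 = validate_mesh(unit_cube)
        assert r1["faces_removed"] == 0
        assert r1["unreferenced_vertices_removed"] == 0
        m2, r2 = validate_mesh(m1)
        np.testing.assert_array_equal(m1.faces, m2.faces)
        np.testing.assert_array_equal(m1.vertices, m2.vertices)
        assert r2["faces_removed"] == 0

    def test_all_degenerate_yields_empty(self):
        v = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])  # collinear
        f = np.array([[0, 1, 2], [0, 0, 1]])
        mesh, report = validate_mesh(TriangleMesh(v, f))
        assert mesh.n_faces == 0
        assert mesh.n_vertices == 0
        assert report["faces_removed"] == 2


class TestNormals:
    def test_right_hand_rule(self, single_triangle):
        mesh = compute_normals(single_triangle)
        np.testing.assert_allclose(mesh.face_normals[0], [0, 0, 1], atol=1e-12)

    def test_reversed_winding_flips(self, single_triangle):
        rev = TriangleMesh(single_triangle.vertices, single_triangle.faces[:, ::-1])
        mesh = compute_normals(rev)
        np.testing.assert_allclose(mesh.face_normals[0], [0, 0, -1], atol=1e-12)

    def test_cube_vertex_normals_point_outward(self, unit_cube):
        mesh = compute_normals(unit_cube)
        centroid = mesh.vertices.mean(axis=0)
        dots = np.einsum("ij,ij->i", mesh.vertex_normals, mesh.vertices - centroid)
        assert np.all(dots > 0)

    def test_normals_rotate_with_mesh(self, unit_cube):
        Q = RigidTransform.from_axis_angle([1, 2, 3], 37.0, (0.5, -1, 2))
        base = compute_normals(unit_cube)
        rotated = compute_normals(Q.apply_mesh(unit_cube))
        np.testing.assert_allclose(
            rotated.face_normals, base.face_normals @ Q.rotation.T, atol=1e-9
        )

    def test_degenerate_face_instructs_validation(self):
        v = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(MeshValidationError, match="validate_mesh"):
            compute_normals(TriangleMesh(v, np.array([[0, 1, 2]])))


class TestColoredPly:
    def test_palette_midpoint_endpoints_clamp(self):
        colors = deviation_palette(np.array([0.0, -2.0, 2.0, 5.0]), 2.0)
        np.testing.assert_array_equal(colors[0], [0, 255, 0])  # green
        np.testing.assert_array_equal(colors[1], [0, 0, 255])  # blue
        np.testing.assert_array_equal(colors[2], [255, 0, 0])  # red
        np.testing.assert_array_equal(colors[3], colors[2])  # clamped

    def test_written_colors_read_back(self, unit_cube, tmp_path):
        scalars = np.zeros(8)
        scalars[0] = 2.0
        path = tmp_path / "dev.ply"
        write_colored_ply(unit_cube, scalars, path, palette_range=2.0)
        tm = trimesh.load(str(path), process=False)
        np.testing.assert_array_equal(tm.visual.vertex_colors[0][:3], [255, 0, 0])
        np.testing.assert_array_equal(tm.visual.vertex_colors[1][:3], [0, 255, 0])
        assert len(tm.faces) == 12

    def test_scalar_count_mismatch(self, unit_cube, tmp_path):
        with pytest.raises(MeshValidationError):
            write_colored_ply(unit_cube, np.zeros(5), tmp_path / "x.ply", 2.0)
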