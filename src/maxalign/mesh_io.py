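"""Triangulated surface-mesh I/O: STL (binary/ASCII) and colored ASCII PLY.

All coordinates are interpreted as millimetres throughout the package; STL
itself carries no unit, and millimetres is the convention of CBCT-derived
surface exports. Binary STL stores single-precision coordinates, so a
write/read round trip is exact only to the float32 quantum of the
coordinate magnitude (about 1e-5 mm at 100 mm).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import MeshFormatError, MeshIOError, MeshValidationError

__all__ = [
    "TriangleMesh",
    "read_stl",
    "write_stl",
    "validate_mesh",
    "compute_normals",
    "write_colored_ply",
    "deviation_palette",
]

# Default tolerance for reunifying STL's per-facet vertex duplication.
# Far below CBCT voxel size (~0.3 mm) so distinct anatomy never merges.
MERGE_TOLERANCE_MM = 1e-6

_BINARY_RECORD = np.dtype(
    [("normal", "<f4", (3,)), ("vertices", "<f4", (3, 3)), ("attr", "<u2")]
)


@dataclass
class TriangleMesh:
    """Indexed triangle surface in millimetre coordinates.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of 0-based vertex indices
    vertex_normals, face_normals : optional unit vectors
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_normals: np.ndarray | None = None
    face_normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be an (m, 3) array")
        for attr in ("vertex_normals", "face_normals"):
            val = getattr(self, attr)
            if val is not None:
                setattr(self, attr, np.ascontiguousarray(val, dtype=np.float64))

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def check(self) -> None:
        """Raise MeshValidationError on any violated structural invariant."""
        if not np.all(np.isfinite(self.vertices)):
            raise MeshValidationError("non-finite vertex coordinates")
        if self.n_faces:
            if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
                raise MeshValidationError("face index out of vertex range")
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise MeshValidationError("face references the same vertex twice")
        for attr in ("vertex_normals", "face_normals"):
            nrm = getattr(self, attr)
            if nrm is not None:
                lengths = np.linalg.norm(nrm, axis=1)
                if not np.allclose(lengths, 1.0, atol=1e-6):
                    raise MeshValidationError(f"{attr} are not unit length")

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.vertex_normals is None else self.vertex_normals.copy(),
            None if self.face_normals is None else self.face_normals.copy(),
        )

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]


def _merge_duplicate_vertices(
    vertices: np.ndarray, faces: np.ndarray, tolerance: float
) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices closer than `tolerance`; faces are remapped.

    Representative of each cluster is the vertex with the lowest original
    index, so output order is deterministic.
    """
    n = len(vertices)
    if n == 0:
        return vertices, faces
    tree = cKDTree(vertices)
    pairs = tree.query_pairs(tolerance, output_type="ndarray")
    if len(pairs) == 0:
        return vertices, faces
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    # representative per component = lowest original index
    order = np.argsort(labels, kind="stable")
    comp_sorted = labels[order]
    first = np.ones(n, dtype=bool)
    first[1:] = comp_sorted[1:] != comp_sorted[:-1]
    rep_of_comp = np.empty(labels.max() + 1, dtype=np.int64)
    rep_of_comp[comp_sorted[first]] = order[first]
    rep = rep_of_comp[labels]  # original index of each vertex's representative
    keep = np.unique(rep)
    new_index = np.full(n, -1, dtype=np.int64)
    new_index[keep] = np.arange(len(keep))
    return vertices[keep], new_index[rep[faces]]


def _looks_binary(data: bytes) -> bool:
    if len(data) >= 84:
        count = int(np.frombuffer(data[80:84], dtype="<u4")[0])
        if len(data) == 84 + 50 * count:
            return True
    head = data[:512].lstrip()
    return not head.lower().startswith(b"solid")


def _parse_binary(data: bytes) -> np.ndarray:
    if len(data) < 84:
        raise MeshFormatError(
            f"truncated binary STL header: file ends at byte {len(data)}, "
            "84-byte header required"
        )
    count = int(np.frombuffer(data[80:84], dtype="<u4")[0])
    expected = 84 + 50 * count
    if len(data) < expected:
        complete = (len(data) - 84) // 50
        raise MeshFormatError(
            f"truncated binary STL: triangle record {complete} is incomplete "
            f"at byte offset {84 + 50 * complete} (declared {count} triangles, "
            f"file is {len(data)} bytes, expected {expected})"
        )
    records = np.frombuffer(data[84:expected], dtype=_BINARY_RECORD)
    tris = records["vertices"].astype(np.float64)
    if not np.all(np.isfinite(tris)):
        bad = int(np.flatnonzero(~np.isfinite(tris).all(axis=(1, 2)))[0])
        raise MeshFormatError(
            f"non-finite coordinates in binary STL record {bad} "
            f"at byte offset {84 + 50 * bad}"
        )
    return tris


_VERTEX_RE = re.compile(r"^vertex\s+(\S+)\s+(\S+)\s+(\S+)\s*$")


def _parse_ascii(text: str) -> np.ndarray:
    tris: list[list[list[float]]] = []
    current: list[list[float]] = []
    in_loop = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        word = line.split(None, 1)[0].lower()
        if word == "vertex":
            if not in_loop:
                raise MeshFormatError(
                    f"malformed ASCII STL at line {lineno}: vertex outside 'outer loop'"
                )
            m = _VERTEX_RE.match(line)
            if not m:
                raise MeshFormatError(
                    f"malformed ASCII STL facet at line {lineno}: {line!r}"
                )
            try:
                current.append([float(g) for g in m.groups()])
            except ValueError:
                raise MeshFormatError(
                    f"malformed ASCII STL facet at line {lineno}: "
                    f"non-numeric coordinate in {line!r}"
                ) from None
        elif word == "outer":
            in_loop = True
            current = []
        elif word == "endloop":
            if len(current) != 3:
                raise MeshFormatError(
                    f"malformed ASCII STL at line {lineno}: loop closed with "
                    f"{len(current)} vertices (3 required)"
                )
            tris.append(current)
            in_loop = False
        elif word in ("solid", "endsolid", "facet", "endfacet"):
            continue
        else:
            raise MeshFormatError(
                f"malformed ASCII STL at line {lineno}: unexpected token {word!r}"
            )
    if not tris:
        raise MeshFormatError("ASCII STL contains no facets")
    return np.asarray(tris, dtype=np.float64)


def read_stl(
    path: str | Path,
    merge_tolerance: float = MERGE_TOLERANCE_MM,
    area_epsilon: float = 1e-12,
) -> TriangleMesh:
    """Read an STL file (binary or ASCII, auto-detected) into a TriangleMesh.

    Per-facet duplicate vertices within `merge_tolerance` mm are merged so
    faces share indices; degenerate faces (repeated indices or area below
    `area_epsilon` mm^2) are then removed.
    """
    path = Path(path)
    try:
        data = path.read_bytes()
    except OSError as exc:
        raise MeshIOError(f"cannot read STL file {path}: {exc}") from exc
    if _looks_binary(data):
        tris = _parse_binary(data)
    else:
        try:
            text = data.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise MeshFormatError(
                f"STL file {path} is neither valid binary nor decodable ASCII: {exc}"
            ) from exc
        tris = _parse_ascii(text)
    n_tri = len(tris)
    vertices = tris.reshape(-1, 3)
    faces = np.arange(3 * n_tri, dtype=np.int64).reshape(-1, 3)
    vertices, faces = _merge_duplicate_vertices(vertices, faces, merge_tolerance)
    mesh, _ = validate_mesh(TriangleMesh(vertices, faces), area_epsilon=area_epsilon)
    return mesh


def _raw_face_normals(mesh: TriangleMesh) -> np.ndarray:
    tri = mesh.triangles()
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(cross, axis=1)
    out = np.zeros_like(cross)
    ok = norms > 0
    out[ok] = cross[ok] / norms[ok, None]
    return out


def write_stl(
    mesh: TriangleMesh, path: str | Path, dialect: str = "binary"
) -> None:
    """Write a mesh to STL. `dialect` is "binary" or "ascii".

    Binary records carry zeroed attribute bytes; facet normals are
    recomputed from the winding order.
    """
    if mesh.n_faces == 0 or mesh.n_vertices == 0:
        raise MeshValidationError("refusing to write an empty mesh")
    mesh.check()
    path = Path(path)
    normals = _raw_face_normals(mesh)
    tri = mesh.triangles()
    try:
        if dialect == "binary":
            records = np.zeros(mesh.n_faces, dtype=_BINARY_RECORD)
            records["normal"] = normals.astype(np.float32)
            records["vertices"] = tri.astype(np.float32)
            with open(path, "wb") as fh:
                fh.write(b"\0" * 80)
                fh.write(np.uint32(mesh.n_faces).tobytes())
                fh.write(records.tobytes())
        elif dialect == "ascii":
            with open(path, "w") as fh:
                fh.write("solid maxalign\n")
                for nrm, (a, b, c) in zip(normals, tri):
                    fh.write(
                        "facet normal {:.17g} {:.17g} {:.17g}\n".format(*nrm)
                    )
                    fh.write("outer loop\n")
                    for v in (a, b, c):
                        fh.write("vertex {:.17g} {:.17g} {:.17g}\n".format(*v))
                    fh.write("endloop\nendfacet\n")
                fh.write("endsolid maxalign\n")
        else:
            raise ValueError(f"unknown STL dialect {dialect!r}")
    except OSError as exc:
        raise MeshIOError(f"cannot write STL file {path}: {exc}") from exc


def validate_mesh(
    mesh: TriangleMesh, area_epsilon: float = 1e-12
) -> tuple[TriangleMesh, dict]:
    """Remove degenerate faces and unreferenced vertices.

    Drops faces with a repeated vertex index or area < `area_epsilon` mm^2,
    then drops vertices no remaining face references. Idempotent. Returns
    the cleaned mesh and a report of removal counts. Stored normals are
    subset alongside, or dropped for removed elements.
    """
    if not np.all(np.isfinite(mesh.vertices)):
        raise MeshValidationError("non-finite vertex coordinates")
    f = mesh.faces
    repeated = np.zeros(len(f), dtype=bool)
    if len(f):
        if len(f) and (f.min() < 0 or (mesh.n_vertices and f.max() >= mesh.n_vertices)):
            raise MeshValidationError("face index out of vertex range")
        repeated = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
    tri = mesh.vertices[np.where(repeated[:, None], 0, f)] if len(f) else np.zeros((0, 3, 3))
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    ) if len(f) else np.zeros(0)
    small = areas < area_epsilon
    keep_faces = ~(repeated | small)
    new_faces = f[keep_faces]
    referenced = np.zeros(mesh.n_vertices, dtype=bool)
    if len(new_faces):
        referenced[new_faces.ravel()] = True
    new_index = np.cumsum(referenced) - 1
    report = {
        "repeated_index_faces_removed": int(repeated.sum()),
        "small_area_faces_removed": int((small & ~repeated).sum()),
        "faces_removed": int((~keep_faces).sum()),
        "unreferenced_vertices_removed": int((~referenced).sum()),
    }
    if report["faces_removed"] == 0 and report["unreferenced_vertices_removed"] == 0:
        return mesh, report
    cleaned = TriangleMesh(
        mesh.vertices[referenced],
        new_index[new_faces],
        None
        if mesh.vertex_normals is None
        else mesh.vertex_normals[referenced],
        None if mesh.face_normals is None else mesh.face_normals[keep_faces],
    )
    return cleaned, report


def compute_normals(mesh: TriangleMesh) -> TriangleMesh:
    """Return a copy carrying face and area-weighted vertex normals.

    Face normals follow the stored winding order (right-hand rule); vertex
    normals are the normalized area-weighted mean of incident face normals.
    """
    if mesh.n_faces == 0:
        raise MeshValidationError("cannot compute normals of an empty mesh")
    mesh.check()
    tri = mesh.triangles()
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(cross, axis=1)
    if np.any(norms <= 0):
        raise MeshValidationError(
            "degenerate (zero-area) face encountered; run validate_mesh first"
        )
    face_normals = cross / norms[:, None]
    # |cross| = 2*area, so accumulating the raw cross products area-weights
    vertex_acc = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(vertex_acc, mesh.faces[:, k], cross)
    vlen = np.linalg.norm(vertex_acc, axis=1)
    fallback = vlen <= 1e-300
    vertex_acc[fallback] = face_normals[0]
    vlen[fallback] = 1.0
    vertex_normals = vertex_acc / vlen[:, None]
    out = mesh.copy()
    out.face_normals = face_normals
    out.vertex_normals = vertex_normals
    return out


def deviation_palette(values: np.ndarray, palette_range: float) -> np.ndarray:
    """Map signed mm values to uint8 RGB: -range→blue, 0→green, +range→red.

    Linear in each half; values beyond the range clamp to the end colors.
    """
    if palette_range <= 0:
        raise ValueError("palette_range must be positive")
    t = np.clip(np.asarray(values, dtype=np.float64) / palette_range, -1.0, 1.0)
    rgb = np.zeros((len(t), 3))
    neg = t < 0
    rgb[neg, 1] = 1.0 + t[neg]  # green fades in from blue
    rgb[neg, 2] = -t[neg]
    rgb[~neg, 0] = t[~neg]
    rgb[~neg, 1] = 1.0 - t[~neg]
    return np.clip(np.rint(rgb * 255), 0, 255).astype(np.uint8)


def write_colored_ply(
    mesh: TriangleMesh,
    scalar_per_vertex: np.ndarray,
    path: str | Path,
    palette_range: float = 2.0,
) -> None:
    """Write an ASCII PLY with per-vertex uchar red/green/blue from a scalar
    deviation field (mm), using the blue-green-red palette."""
    scalars = np.asarray(scalar_per_vertex, dtype=np.float64).ravel()
    if len(scalars) != mesh.n_vertices:
        raise MeshValidationError(
            f"scalar count {len(scalars)} != vertex count {mesh.n_vertices}"
        )
    colors = deviation_palette(scalars, palette_range)
    path = Path(path)
    try:
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {mesh.n_vertices}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write(
                "property uchar red\nproperty uchar green\nproperty uchar blue\n"
            )
            fh.write(f"element face {mesh.n_faces}\n")
            fh.write("property list uchar int vertex_indices\n")
            fh.write("end_header\n")
            for v, c in zip(mesh.vertices, colors):
                fh.write(
                    f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g} {c[0]} {c[1]} {c[2]}\n"
                )
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    except OSError as exc:
        raise MeshIOError(f"cannot write PLY file {path}: {exc}") from exc
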