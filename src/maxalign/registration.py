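"""Rigid surface registration: Kabsch fits, closest-point queries, trimmed ICP.

The alignment strategy mirrors landmark-free accuracy evaluation in surface
inspection tools: a coarse principal-axes initial alignment of the reference
region, then iterative-closest-point refinement in which each iteration
finds, for every (transformed) source point, the exact nearest point on the
target *surface* (point-to-triangle, not vertex-to-vertex — insensitive to
differing tessellations), optionally discards the worst residuals (trimming,
robust to plate/metal artifacts), solves the closed-form least-squares rigid
fit on the survivors, and composes. The minimized step metric is classic
point-to-point least squares on the current closest-surface-point pairs.

The per-iteration RMS over surviving correspondences is non-increasing after
the first re-correspondence: re-correspondence can only shorten each point's
distance, trimming keeps a fixed-size best subset, and the Kabsch step
minimizes the squared sum — the standard alternating-minimization argument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, RegistrationError
from .mesh_io import TriangleMesh

__all__ = [
    "RigidTransform",
    "ICPParams",
    "RegistrationReport",
    "estimate_rigid_transform",
    "initial_alignment",
    "nearest_point_on_triangle",
    "nearest_point_on_mesh",
    "MeshProximity",
    "icp_refine",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion p -> rotation @ p + translation (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.ascontiguousarray(self.rotation, dtype=np.float64)
        t = np.ascontiguousarray(self.translation, dtype=np.float64).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal within 1e-9")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation determinant is not +1 within 1e-9")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls, axis, degrees: float, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        R = Rotation.from_rotvec(np.deg2rad(degrees) * axis).as_matrix()
        return cls(R, np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return points @ self.rotation.T + self.translation

    def apply_mesh(self, mesh: TriangleMesh) -> TriangleMesh:
        out = mesh.copy()
        out.vertices = self.apply(mesh.vertices)
        for attr in ("vertex_normals", "face_normals"):
            nrm = getattr(mesh, attr)
            if nrm is not None:
                setattr(out, attr, nrm @ self.rotation.T)
        return out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying `other` first, then `self`."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        cos = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


@dataclass(frozen=True)
class ICPParams:
    """Tunables of the optimized-alignment stage.

    trim_fraction discards the worst residuals each iteration (robustness to
    fixation-plate/metal rendering artifacts); max_correspondence_distance
    additionally rejects pairs beyond a hard gate (mm, inf = unbounded);
    sample_count, when set, registers a seeded uniform subsample of the
    reference-region points instead of all of them.
    """

    max_iterations: int = 100
    rms_change_tolerance: float = 1e-5
    trim_fraction: float = 0.1
    max_correspondence_distance: float = np.inf
    sample_count: int | None = None

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.rms_change_tolerance <= 0:
            raise ValueError("rms_change_tolerance must be > 0")
        if not 0.0 <= self.trim_fraction < 1.0:
            raise ValueError("trim_fraction must be in [0, 1)")
        if self.max_correspondence_distance <= 0:
            raise ValueError("max_correspondence_distance must be > 0")
        if self.sample_count is not None and self.sample_count < 3:
            raise ValueError("sample_count must be >= 3")


@dataclass
class RegistrationReport:
    final_transform: RigidTransform
    rms_per_iteration: list[float] = field(default_factory=list)
    iterations_run: int = 0
    converged: bool = False
    correspondences_used: int = 0


def estimate_rigid_transform(
    source_points: np.ndarray,
    target_points: np.ndarray,
    weights: np.ndarray | None = None,
) -> RigidTransform:
    """Closed-form (SVD) weighted least-squares rigid fit source -> target.

    The reflection ambiguity is resolved by flipping the sign of the
    smallest singular vector so the determinant is +1.
    """
    src = np.asarray(source_points, dtype=np.float64)
    tgt = np.asarray(target_points, dtype=np.float64)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("source and target must be matching (n, 3) arrays")
    n = len(src)
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 point pairs, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    cs = w @ src
    ct = w @ tgt
    X = src - cs
    Y = tgt - ct
    # rank check on the source configuration (collinear/coincident points)
    s_cfg = np.linalg.svd(X * np.sqrt(w)[:, None], compute_uv=False)
    if s_cfg[1] <= 1e-12 * max(s_cfg[0], 1e-300):
        raise DegenerateGeometryError(
            "point configuration is (near-)collinear; rigid fit is underdetermined"
        )
    H = (w[:, None] * X).T @ Y
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, ct - R @ cs)


def _principal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centroid, descending eigenvalues, and proper-rotation eigenbasis."""
    c = points.mean(axis=0)
    cov = np.cov((points - c).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if np.linalg.det(evecs) < 0:
        evecs[:, 2] *= -1.0
    return c, evals, evecs


def initial_alignment(
    source_points: np.ndarray, target_points: np.ndarray
) -> RigidTransform:
    """Coarse alignment by centroids and principal axes.

    Among the four proper-rotation sign assignments of the matched axes the
    one minimizing post-alignment nearest-neighbor RMS is returned. If any
    adjacent pair of covariance eigenvalues is within a factor 1.05 the axes
    are unreliable (near-isotropy); a warning is issued and only centroids
    are aligned.
    """
    src = np.asarray(source_points, dtype=np.float64)
    tgt = np.asarray(target_points, dtype=np.float64)
    if len(src) < 3 or len(tgt) < 3:
        raise DegenerateGeometryError("need >= 3 points in each cloud")
    cs, ls, Us = _principal_axes(src)
    ct, lt, Ut = _principal_axes(tgt)
    tiny = 1e-300
    for lam in (ls, lt):
        ratios = lam[:-1] / np.maximum(lam[1:], tiny)
        if np.any(ratios < 1.05):
            warnings.warn(
                "near-isotropic point covariance; falling back to centroid-only "
                "initial alignment",
                stacklevel=2,
            )
            return RigidTransform(np.eye(3), ct - cs)
    tree = cKDTree(tgt)
    best: RigidTransform | None = None
    best_ms = np.inf
    for s0, s1 in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        D = np.diag([s0, s1, s0 * s1])  # det +1 by construction
        R = Ut @ D @ Us.T
        cand = RigidTransform(R, ct - R @ cs)
        d, _ = tree.query(cand.apply(src))
        ms = float(np.mean(d**2))
        if ms < best_ms:
            best_ms = ms
            best = cand
    assert best is not None
    return best


def _closest_on_triangles(
    p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> np.ndarray:
    """Exact closest point on each closed triangle (a,b,c)_i to p_i.

    Vectorized region classification (vertex / edge / interior) following
    the standard real-time collision-detection construction.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def take(mask, values):
        nonlocal done
        m = mask & ~done
        if np.any(m):
            out[m] = values(m)
        done = done | mask

    take((d1 <= 0) & (d2 <= 0), lambda m: a[m])  # vertex A
    take((d3 >= 0) & (d4 <= d3), lambda m: b[m])  # vertex B
    take((d6 >= 0) & (d5 <= d6), lambda m: c[m])  # vertex C
    take(
        (vc <= 0) & (d1 >= 0) & (d3 <= 0),
        lambda m: a[m] + (d1[m] / (d1[m] - d3[m]))[:, None] * ab[m],
    )  # edge AB
    take(
        (vb <= 0) & (d2 >= 0) & (d6 <= 0),
        lambda m: a[m] + (d2[m] / (d2[m] - d6[m]))[:, None] * ac[m],
    )  # edge AC
    take(
        (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
        lambda m: b[m]
        + ((d4[m] - d3[m]) / ((d4[m] - d3[m]) + (d5[m] - d6[m])))[:, None]
        * (c[m] - b[m]),
    )  # edge BC
    take(
        np.ones(len(p), dtype=bool),
        lambda m: a[m]
        + (vb[m] / (va[m] + vb[m] + vc[m]))[:, None] * ab[m]
        + (vc[m] / (va[m] + vb[m] + vc[m]))[:, None] * ac[m],
    )  # interior
    return out


def nearest_point_on_triangle(p, a, b, c) -> tuple[np.ndarray, float]:
    """Exact closest point on the closed triangle (a, b, c) and its distance."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    area2 = np.linalg.norm(np.cross(b - a, c - a))
    scale = max(np.linalg.norm(b - a), np.linalg.norm(c - a), 1e-300)
    if area2 <= 1e-14 * scale**2:
        raise DegenerateGeometryError("degenerate (zero-area) triangle")
    cp = _closest_on_triangles(p[None], a[None], b[None], c[None])[0]
    return cp, float(np.linalg.norm(p - cp))


class MeshProximity:
    """Accelerated exact nearest-point-on-mesh queries.

    A k-d tree over triangle centroids bounds the search: for each query the
    exact distance to the face of the nearest centroid gives an upper bound
    d0, and every face whose centroid lies within d0 + r_max (r_max = the
    largest centroid-to-corner radius) is checked exactly. Ties are broken
    by the lowest face index so results are bitwise reproducible.
    """

    def __init__(self, mesh: TriangleMesh):
        if mesh.n_faces == 0:
            raise DegenerateGeometryError("cannot build proximity index on empty mesh")
        tri = mesh.triangles()
        self.tri = tri
        self.centroids = tri.mean(axis=1)
        self.r_max = float(
            np.linalg.norm(tri - self.centroids[:, None, :], axis=2).max()
        )
        self.tree = cKDTree(self.centroids)

    def query(
        self, points: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Closest surface points, distances and face ids for query points."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        _, seed_face = self.tree.query(pts)
        seed_tri = self.tri[seed_face]
        seed_cp = _closest_on_triangles(
            pts, seed_tri[:, 0], seed_tri[:, 1], seed_tri[:, 2]
        )
        d_up = np.linalg.norm(pts - seed_cp, axis=1)
        radius = d_up + self.r_max + 1e-12
        groups = self.tree.query_ball_point(pts, radius)
        counts = np.fromiter((len(g) for g in groups), dtype=np.int64, count=len(pts))
        flat = np.concatenate([np.sort(g) for g in groups]) if len(pts) else np.empty(0, np.int64)
        flat = flat.astype(np.int64)
        seg = np.repeat(np.arange(len(pts)), counts)
        tri = self.tri[flat]
        cp = _closest_on_triangles(pts[seg], tri[:, 0], tri[:, 1], tri[:, 2])
        dist = np.linalg.norm(pts[seg] - cp, axis=1)
        # per query: min distance, ties -> lowest face id
        order = np.lexsort((flat, dist, seg))
        seg_sorted = seg[order]
        first = np.ones(len(seg_sorted), dtype=bool)
        first[1:] = seg_sorted[1:] != seg_sorted[:-1]
        pick = order[first]
        closest = cp[pick]
        return closest, dist[pick], flat[pick]


def nearest_point_on_mesh(
    p, mesh: TriangleMesh, index: MeshProximity | None = None
) -> tuple[np.ndarray, float, int]:
    """Exact closest point on a mesh, its distance, and the face id.

    Equals the minimum of nearest_point_on_triangle over all faces; ties go
    to the lowest face id.
    """
    if index is None:
        index = MeshProximity(mesh)
    cp, d, fid = index.query(np.asarray(p, dtype=np.float64)[None])
    return cp[0], float(d[0]), int(fid[0])


def icp_refine(
    source_points: np.ndarray,
    target_mesh: TriangleMesh,
    init: RigidTransform | None = None,
    params: ICPParams | None = None,
    seed: int | None = None,
) -> RegistrationReport:
    """Trimmed point-to-mesh ICP refinement of an initial rigid alignment.

    Each iteration: transform the source points, find exact nearest points
    on the target surface, reject pairs beyond max_correspondence_distance,
    drop the worst trim_fraction by distance, solve the rigid least-squares
    fit on the survivors, and compose. Stops when the change in survivor RMS
    falls below rms_change_tolerance or after max_iterations. The reported
    RMS per iteration is evaluated after each fit.
    """
    params = params or ICPParams()
    if init is None:
        init = RigidTransform.identity()
    pts = np.asarray(source_points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise RegistrationError("need an (n>=3, 3) source point array")
    if params.sample_count is not None and params.sample_count < len(pts):
        rng = np.random.default_rng(seed)
        pts = pts[rng.choice(len(pts), params.sample_count, replace=False)]
    prox = MeshProximity(target_mesh)
    transform = init
    rms_history: list[float] = []
    converged = False
    n_used = 0
    n_keep_trim = len(pts) - int(np.floor(params.trim_fraction * len(pts)))
    for _ in range(params.max_iterations):
        moved = transform.apply(pts)
        closest, dist, _ = prox.query(moved)
        if np.isfinite(params.max_correspondence_distance):
            gate = dist <= params.max_correspondence_distance
            if not np.any(gate):
                raise RegistrationError(
                    "all correspondences rejected; increase max_correspondence_distance"
                )
            moved_g, closest_g, dist_g = moved[gate], closest[gate], dist[gate]
        else:
            moved_g, closest_g, dist_g = moved, closest, dist
        n_keep = min(n_keep_trim, len(dist_g))
        if n_keep < 3:
            raise RegistrationError(
                "fewer than 3 surviving correspondences after trimming/gating"
            )
        kept = np.argsort(dist_g, kind="stable")[:n_keep]
        step = estimate_rigid_transform(moved_g[kept], closest_g[kept])
        transform = step.compose(transform)
        resid = step.apply(moved_g[kept]) - closest_g[kept]
        rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
        if not np.isfinite(rms):
            raise RegistrationError("non-finite RMS during ICP")
        rms_history.append(rms)
        n_used = n_keep
        if len(rms_history) >= 2 and abs(rms_history[-2] - rms) < params.rms_change_tolerance:
            converged = True
            break
        if rms < 1e-12:
            converged = True
            break
    return RegistrationReport(
        final_transform=transform,
        rms_per_iteration=rms_history,
        iterations_run=len(rms_history),
        converged=converged,
        correspondences_used=n_used,
    )
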