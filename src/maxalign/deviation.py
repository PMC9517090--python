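"""Point-to-surface deviation of the registered postoperative maxilla.

After the reference-region registration has mapped the postoperative (T1)
mesh into the planned (T0) frame, the measurement-region (ROI2) vertices of
T1 are compared with the planned ROI2 surface: each sample point gets the
exact distance to its nearest point on the reference sub-mesh. The summary
statistics (max, min, mean, RMS) are the study's accuracy metrics; RMS is
the "3D error" and is always computed on distance magnitudes — the clinical
acceptability band of +/-2 mm is symmetric, so sign only matters for the
colormap. Signed mode attributes a sign from the reference face normal at
the closest point (positive = outside the surface per its winding).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DeviationError
from .mesh_io import TriangleMesh, write_colored_ply
from .registration import MeshProximity

__all__ = [
    "DeviationSummary",
    "DeviationResult",
    "surface_deviation",
    "summarize_deviation",
    "classify_acceptability",
    "deviation_colormap",
    "ACCEPTABILITY_THRESHOLD_MM",
]

#: Clinical acceptability band (mm): RMS within +/-2 mm of plan.
ACCEPTABILITY_THRESHOLD_MM = 2.0

# Absolute float guard so a computed RMS of exactly-threshold magnitude is
# not flipped to "not acceptable" by last-ulp rounding; the band is closed.
_BOUNDARY_GUARD = 1e-9


@dataclass(frozen=True)
class DeviationSummary:
    """max / min / mean / RMS of a deviation field (mm)."""

    max_dev: float
    min_dev: float
    mean_dev: float
    rms: float
    n_points: int


@dataclass
class DeviationResult:
    """Per-point distances from sample points to a reference surface."""

    sample_points: np.ndarray
    distances: np.ndarray
    signed: bool
    reference_region: str
    summary: DeviationSummary

    def __post_init__(self) -> None:
        if len(self.distances) != len(self.sample_points):
            raise DeviationError("distance count != sample point count")
        if not self.signed and np.any(self.distances < 0):
            raise DeviationError("unsigned result contains negative distances")

    def consistent(self, rtol: float = 1e-12) -> bool:
        """Check that the stored summary recomputes from the distances."""
        s = summarize_deviation(self.distances)
        return all(
            np.isclose(getattr(s, f), getattr(self.summary, f), rtol=rtol, atol=1e-300)
            for f in ("max_dev", "min_dev", "mean_dev", "rms")
        ) and s.n_points == self.summary.n_points


def summarize_deviation(distances: np.ndarray) -> DeviationSummary:
    """Max, min, arithmetic mean, and RMS = sqrt(mean of squares)."""
    d = np.asarray(distances, dtype=np.float64).ravel()
    if len(d) == 0:
        raise DeviationError("cannot summarize an empty deviation field")
    if not np.all(np.isfinite(d)):
        raise DeviationError("non-finite deviation values")
    return DeviationSummary(
        max_dev=float(d.max()),
        min_dev=float(d.min()),
        mean_dev=float(d.mean()),
        rms=float(np.sqrt(np.mean(d**2))),
        n_points=len(d),
    )


def _winding_consistent(faces: np.ndarray, n_vertices: int) -> bool:
    """True when no interior edge is traversed twice in the same direction."""
    edges = faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    code = edges[:, 0].astype(np.int64) * n_vertices + edges[:, 1]
    _, counts = np.unique(code, return_counts=True)
    return bool(np.all(counts == 1))


def surface_deviation(
    sample_points: np.ndarray,
    reference_mesh: TriangleMesh,
    signed: bool = False,
    reference_region: str = "ROI2",
    index: MeshProximity | None = None,
) -> DeviationResult:
    """Distance from each sample point to its nearest reference-surface point.

    In signed mode the reference mesh must carry face normals and a
    consistent winding; sign = sign of dot(sample - closest, face normal),
    with zero-distance points counted positive.
    """
    pts = np.atleast_2d(np.asarray(sample_points, dtype=np.float64))
    if len(pts) == 0:
        raise DeviationError("no sample points")
    if reference_mesh.n_faces == 0:
        raise DeviationError("reference mesh has no faces")
    if signed:
        if reference_mesh.face_normals is None:
            raise DeviationError(
                "signed deviation requires face normals on the reference mesh; "
                "run compute_normals first"
            )
        if not _winding_consistent(reference_mesh.faces, reference_mesh.n_vertices):
            raise DeviationError(
                "reference mesh winding is inconsistent (adjacent-face normal "
                "flips); use unsigned mode"
            )
    prox = index or MeshProximity(reference_mesh)
    closest, dist, fid = prox.query(pts)
    if signed:
        normals = reference_mesh.face_normals[fid]
        sign = np.sign(np.einsum("ij,ij->i", pts - closest, normals))
        sign[sign == 0] = 1.0
        dist = sign * dist
    return DeviationResult(
        sample_points=pts,
        distances=dist,
        signed=signed,
        reference_region=reference_region,
        summary=summarize_deviation(dist),
    )


def classify_acceptability(
    rms: float, threshold: float = ACCEPTABILITY_THRESHOLD_MM
) -> bool:
    """Clinical acceptability of an RMS 3D error: True iff rms <= threshold.

    The band is closed: an RMS of exactly the threshold is acceptable.
    """
    if rms < 0:
        raise DeviationError("RMS must be non-negative")
    if threshold <= 0:
        raise DeviationError("threshold must be positive")
    return bool(rms <= threshold + _BOUNDARY_GUARD)


def deviation_colormap(
    mesh_region: TriangleMesh,
    result: DeviationResult,
    path: str | Path,
    palette_range: float = ACCEPTABILITY_THRESHOLD_MM,
) -> None:
    """Write the deviation field as a colored PLY over the measured region.

    One distance per region vertex is required; the palette spans
    -palette_range (blue) through 0 (green) to +palette_range (red),
    defaulting to the acceptability threshold.
    """
    if len(result.distances) != mesh_region.n_vertices:
        raise DeviationError(
            f"deviation field has {len(result.distances)} values but region "
            f"mesh has {mesh_region.n_vertices} vertices"
        )
    write_colored_ply(mesh_region, result.distances, path, palette_range)
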