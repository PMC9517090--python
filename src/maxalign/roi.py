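"""Regions of interest on a surface mesh.

The accuracy workflow uses two ROIs defined on the planned (T0) model: a
stable cranial reference (orbital frames, frontal and zygomatic bones;
"ROI1") that registration fits, and the repositioned maxillary region
("ROI2") whose deviation from plan is measured. Manual painting of ROIs in
inspection software is replaced here by explicit index lists or geometric
predicates so every run is reproducible. Membership is vertex-based; a face
belongs to a sub-mesh only when all three of its vertices are selected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ROIError
from .mesh_io import TriangleMesh

__all__ = [
    "ROISelection",
    "AxisAlignedBox",
    "Sphere",
    "HalfSpace",
    "roi_from_indices",
    "roi_from_predicate",
    "roi_from_definition",
    "extract_points",
    "extract_submesh",
    "save_roi_definition",
    "load_roi_definition",
]


@dataclass(frozen=True)
class ROISelection:
    """A named, validated vertex subset of a specific mesh."""

    name: str
    vertex_indices: np.ndarray  # sorted unique int64
    provenance: str  # "explicit-indices" | "spatial-predicate"

    def __len__(self) -> int:
        return len(self.vertex_indices)


@dataclass(frozen=True)
class AxisAlignedBox:
    """Closed axis-aligned box; boundary points are inside."""

    min_corner: tuple[float, float, float]
    max_corner: tuple[float, float, float]

    def contains(self, points: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.min_corner, dtype=float)
        hi = np.asarray(self.max_corner, dtype=float)
        return np.all((points >= lo) & (points <= hi), axis=1)

    def to_dict(self) -> dict:
        return {
            "type": "box",
            "min_corner": list(self.min_corner),
            "max_corner": list(self.max_corner),
        }


@dataclass(frozen=True)
class Sphere:
    """Closed ball of given radius (mm); boundary included."""

    center: tuple[float, float, float]
    radius: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(points - np.asarray(self.center, dtype=float), axis=1)
        return d <= self.radius

    def to_dict(self) -> dict:
        return {"type": "sphere", "center": list(self.center), "radius": self.radius}


@dataclass(frozen=True)
class HalfSpace:
    """Closed half-space of points p with dot(p - point, normal) >= 0."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]

    def contains(self, points: np.ndarray) -> np.ndarray:
        n = np.asarray(self.normal, dtype=float)
        return (points - np.asarray(self.point, dtype=float)) @ n >= 0.0

    def to_dict(self) -> dict:
        return {"type": "halfspace", "point": list(self.point), "normal": list(self.normal)}


_PREDICATES = {"box": AxisAlignedBox, "sphere": Sphere, "halfspace": HalfSpace}


def roi_from_indices(mesh: TriangleMesh, indices, name: str) -> ROISelection:
    """Build a validated ROI from an explicit vertex-index collection."""
    idx = np.unique(np.asarray(list(indices), dtype=np.int64))
    if len(idx) == 0:
        raise ROIError(f"ROI {name!r}: empty index set")
    if idx.min() < 0 or idx.max() >= mesh.n_vertices:
        raise ROIError(
            f"ROI {name!r}: index {int(idx.max() if idx.max() >= mesh.n_vertices else idx.min())} "
            f"outside vertex range [0, {mesh.n_vertices})"
        )
    return ROISelection(name, idx, "explicit-indices")


def roi_from_predicate(mesh: TriangleMesh, predicate, name: str) -> ROISelection:
    """Select exactly the vertices inside a closed spatial region."""
    mask = predicate.contains(mesh.vertices)
    idx = np.flatnonzero(mask).astype(np.int64)
    if len(idx) == 0:
        raise ROIError(f"ROI {name!r}: predicate {predicate} selects no vertices")
    return ROISelection(name, idx, "spatial-predicate")


def extract_points(mesh: TriangleMesh, roi: ROISelection):
    """Coordinates (and normals, if stored) of ROI vertices, ascending index.

    Returns (points,) or (points, normals).
    """
    idx = roi.vertex_indices
    if len(idx) == 0 or idx.max() >= mesh.n_vertices:
        raise ROIError(
            f"ROI {roi.name!r} is stale: index {int(idx.max()) if len(idx) else '-'} "
            f"outside vertex range [0, {mesh.n_vertices})"
        )
    points = mesh.vertices[idx]
    if mesh.vertex_normals is not None:
        return points, mesh.vertex_normals[idx]
    return (points,)


def extract_submesh(mesh: TriangleMesh, roi: ROISelection) -> TriangleMesh:
    """Sub-mesh of faces whose three vertices all lie in the ROI, reindexed."""
    idx = roi.vertex_indices
    if len(idx) == 0:
        raise ROIError(f"ROI {roi.name!r} is empty")
    if idx.max() >= mesh.n_vertices:
        raise ROIError(f"ROI {roi.name!r} is stale for this mesh")
    member = np.zeros(mesh.n_vertices, dtype=bool)
    member[idx] = True
    keep = member[mesh.faces].all(axis=1)
    if not keep.any():
        raise ROIError(f"ROI {roi.name!r}: no face lies entirely inside the ROI")
    faces = mesh.faces[keep]
    referenced = np.zeros(mesh.n_vertices, dtype=bool)
    referenced[faces.ravel()] = True
    # keep all ROI vertices that are referenced, in ascending order
    new_index = np.cumsum(referenced) - 1
    return TriangleMesh(
        mesh.vertices[referenced],
        new_index[faces],
        None if mesh.vertex_normals is None else mesh.vertex_normals[referenced],
        None if mesh.face_normals is None else mesh.face_normals[keep],
    )


def save_roi_definition(definition: dict, path: str | Path) -> None:
    """Write a JSON ROI definition (indices or predicate, mm units)."""
    Path(path).write_text(json.dumps(definition, indent=1))


def load_roi_definition(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def roi_from_definition(mesh: TriangleMesh, definition, name: str | None = None) -> ROISelection:
    """Resolve a JSON-style ROI definition (dict or file path) on a mesh.

    Definitions carry either {"type": "indices", "indices": [...]} or a
    predicate ({"type": "box"|"sphere"|"halfspace", ...parameters in mm}).
    """
    if isinstance(definition, (str, Path)):
        definition = load_roi_definition(definition)
    d = dict(definition)
    roi_name = name or d.pop("name", "ROI")
    kind = d.pop("type", None)
    if kind == "indices":
        return roi_from_indices(mesh, d["indices"], roi_name)
    if kind in _PREDICATES:
        predicate = _PREDICATES[kind](**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})
        return roi_from_predicate(mesh, predicate, roi_name)
    raise ROIError(f"unknown ROI definition type {kind!r}")
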