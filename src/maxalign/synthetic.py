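"""Synthetic skull phantoms with known ground truth.

Real inputs to the accuracy pipeline are patient-specific surfaces that are
not publicly available, so every stage is exercised on schematic phantoms: a
rigid cranial dome (half-ellipsoid shell, standing in for the orbital /
frontal / zygomatic reference region, ROI1) plus a detached maxillary
ellipsoid (ROI2). The postoperative (T1) copy differs from the plan (T0) by
a known rigid residual applied to the maxilla only (the simulated surgical
inaccuracy), a global pose perturbation of the whole mesh (different scan
coordinate frames), Gaussian vertex noise (surface reconstruction error) and
optional large outlier displacements of a fraction of maxillary vertices
(fixation-plate / metal rendering artifacts). Geometry is schematic, not
anatomical: what the phantoms validate is parameter recovery, which does not
require realism.

T0 and T1 share an identical tessellation topology by default; the
registration and deviation stages never exploit this (point-to-surface
correspondences), and vertex jitter can be enabled to emulate independent
remeshing. All randomness flows from the explicit seed in the spec; no
global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .deviation import surface_deviation
from .errors import MaxalignError
from .mesh_io import TriangleMesh, compute_normals, write_stl
from .registration import MeshProximity, RigidTransform
from .roi import ROISelection, extract_submesh, roi_from_indices, save_roi_definition

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "generate_phantom_pair",
    "generate_flat_patch_phantom",
    "generate_cohort",
    "ellipsoid_mesh",
    "dome_mesh",
]


def dome_mesh(
    radii=(80.0, 68.0, 60.0),
    n_rings: int = 12,
    n_segments: int = 24,
    asymmetry: float = 0.12,
) -> TriangleMesh:
    """Open half-ellipsoid shell (z >= 0): pole cap plus latitude rings.

    A smooth low-order radial modulation (`asymmetry`) emulates the
    front-biased prominences (orbital rims, zygomatic arches) of the real
    cranial reference region. It also removes the rotational symmetry of a
    plain ellipsoid dome, without which registration on the reference region
    alone would be geometrically ambiguous — as it would be clinically.
    """
    a, b, c = radii
    if min(radii) <= 0:
        raise MaxalignError("dome radii must be positive")
    thetas = np.linspace(0.0, np.pi / 2.0, n_rings + 1)[1:]
    phis = np.linspace(0.0, 2.0 * np.pi, n_segments, endpoint=False)
    verts = [np.array([0.0, 0.0, c])]
    for th in thetas:
        bump = (
            1.0
            + asymmetry * np.sin(th) ** 2 * np.cos(phis - 0.6)
            + 0.5 * asymmetry * np.sin(th) * np.sin(2.0 * phis + 0.3)
        )
        ring = np.stack(
            [
                a * np.sin(th) * np.cos(phis),
                b * np.sin(th) * np.sin(phis),
                np.full(n_segments, c * np.cos(th)),
            ],
            axis=1,
        ) * bump[:, None]
        verts.append(ring)
    vertices = np.vstack([verts[0][None]] + verts[1:])
    faces = []
    for i in range(n_segments):
        faces.append([0, 1 + i, 1 + (i + 1) % n_segments])
    for j in range(n_rings - 1):
        base0 = 1 + j * n_segments
        base1 = base0 + n_segments
        for i in range(n_segments):
            i2 = (i + 1) % n_segments
            faces.append([base0 + i, base1 + i, base1 + i2])
            faces.append([base0 + i, base1 + i2, base0 + i2])
    return TriangleMesh(vertices, np.asarray(faces, dtype=np.int64))


def ellipsoid_mesh(
    radii=(25.0, 18.0, 12.0),
    center=(0.0, 0.0, 0.0),
    n_rings: int = 9,
    n_segments: int = 20,
) -> TriangleMesh:
    """Closed UV-tessellated ellipsoid."""
    a, b, c = radii
    if min(radii) <= 0:
        raise MaxalignError("ellipsoid radii must be positive")
    thetas = np.linspace(0.0, np.pi, n_rings + 2)[1:-1]
    phis = np.linspace(0.0, 2.0 * np.pi, n_segments, endpoint=False)
    top = np.array([0.0, 0.0, c])
    bottom = np.array([0.0, 0.0, -c])
    rings = [
        np.stack(
            [
                a * np.sin(th) * np.cos(phis),
                b * np.sin(th) * np.sin(phis),
                np.full(n_segments, c * np.cos(th)),
            ],
            axis=1,
        )
        for th in thetas
    ]
    vertices = np.vstack([top[None]] + rings + [bottom[None]]) + np.asarray(center)
    n_vert = len(vertices)
    faces = []
    for i in range(n_segments):
        faces.append([0, 1 + i, 1 + (i + 1) % n_segments])
    for j in range(n_rings - 1):
        base0 = 1 + j * n_segments
        base1 = base0 + n_segments
        for i in range(n_segments):
            i2 = (i + 1) % n_segments
            faces.append([base0 + i, base1 + i, base1 + i2])
            faces.append([base0 + i, base1 + i2, base0 + i2])
    last = 1 + (n_rings - 1) * n_segments
    for i in range(n_segments):
        faces.append([n_vert - 1, last + (i + 1) % n_segments, last + i])
    return TriangleMesh(vertices, np.asarray(faces, dtype=np.int64))


@dataclass(frozen=True)
class PhantomSpec:
    """Everything that defines one T0/T1 phantom pair."""

    cranial_radii: tuple = (80.0, 68.0, 60.0)
    cranial_rings: int = 12
    cranial_segments: int = 24
    maxilla_radii: tuple = (25.0, 18.0, 12.0)
    maxilla_center: tuple = (0.0, 55.0, -25.0)
    maxilla_rings: int = 9
    maxilla_segments: int = 20
    true_residual_transform: RigidTransform = field(
        default_factory=RigidTransform.identity
    )
    global_pose_perturbation: RigidTransform = field(
        default_factory=RigidTransform.identity
    )
    noise_sd: float = 0.0  # mm, per-vertex Gaussian displacement on T1
    noise_along_normals: bool = False
    artifact_fraction: float = 0.0  # fraction of ROI2 vertices made outliers
    tessellation_jitter: float = 0.0  # mm tangential T1 vertex jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cranial_radii) <= 0 or min(self.maxilla_radii) <= 0:
            raise MaxalignError("phantom radii must be positive")
        if self.noise_sd < 0:
            raise MaxalignError("noise_sd must be >= 0")
        if not 0.0 <= self.artifact_fraction <= 0.3:
            raise MaxalignError("artifact_fraction must be in [0, 0.3]")


@dataclass
class PhantomGroundTruth:
    spec: PhantomSpec
    roi1: ROISelection
    roi2: ROISelection
    expected_rms_noise_floor: float
    residual_transform: RigidTransform
    residual_center: np.ndarray  # rotation pivot of the maxillary residual
    pose_perturbation: RigidTransform


def generate_phantom_pair(
    spec: PhantomSpec,
) -> tuple[TriangleMesh, TriangleMesh, PhantomGroundTruth]:
    """Build the (T0, T1) pair and its ground truth from a spec.

    T0 holds cranium + maxilla in planned position; T1 applies, in order,
    the maxillary residual (about the maxilla centroid), artifact outliers
    along maxillary normals, the global pose perturbation, and Gaussian
    noise. Bitwise reproducible from spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    cranium = dome_mesh(spec.cranial_radii, spec.cranial_rings, spec.cranial_segments)
    maxilla = ellipsoid_mesh(
        spec.maxilla_radii, spec.maxilla_center, spec.maxilla_rings, spec.maxilla_segments
    )
    n1 = cranium.n_vertices
    vertices = np.vstack([cranium.vertices, maxilla.vertices])
    faces = np.vstack([cranium.faces, maxilla.faces + n1])
    t0 = TriangleMesh(vertices, faces)
    roi1 = roi_from_indices(t0, np.arange(n1), "ROI1")
    roi2 = roi_from_indices(t0, np.arange(n1, t0.n_vertices), "ROI2")

    v1 = t0.vertices.copy()
    # maxillary residual, rotating about the maxilla centroid; written as an
    # increment so an identity residual leaves the vertices bitwise unchanged
    center = maxilla.vertices.mean(axis=0)
    res = spec.true_residual_transform
    m = v1[n1:]
    v1[n1:] = m + (m - center) @ (res.rotation - np.eye(3)).T + res.translation
    t1 = TriangleMesh(v1, faces.copy())

    if spec.artifact_fraction > 0 or spec.noise_along_normals or spec.tessellation_jitter > 0:
        t1n = compute_normals(t1)
        normals = t1n.vertex_normals
    else:
        normals = None

    if spec.artifact_fraction > 0:
        n2 = t0.n_vertices - n1
        n_art = int(np.floor(spec.artifact_fraction * n2))
        if n_art:
            which = n1 + rng.choice(n2, n_art, replace=False)
            mag = rng.uniform(2.0, 5.0, n_art)
            t1.vertices[which] += mag[:, None] * normals[which]

    if spec.tessellation_jitter > 0:
        # tangential jitter emulating an independent remeshing of T1
        rnd = rng.normal(0.0, spec.tessellation_jitter, (t1.n_vertices, 3))
        rnd -= np.einsum("ij,ij->i", rnd, normals)[:, None] * normals
        t1.vertices += rnd

    pose = spec.global_pose_perturbation
    t1.vertices = pose.apply(t1.vertices)

    if spec.noise_sd > 0:
        if spec.noise_along_normals:
            amp = rng.normal(0.0, spec.noise_sd, t1.n_vertices)
            t1.vertices += amp[:, None] * (normals @ pose.rotation.T)
        else:
            t1.vertices += rng.normal(0.0, spec.noise_sd, (t1.n_vertices, 3))

    truth = PhantomGroundTruth(
        spec=spec,
        roi1=roi1,
        roi2=roi2,
        expected_rms_noise_floor=spec.noise_sd,
        residual_transform=res,
        residual_center=center,
        pose_perturbation=pose,
    )
    return t0, t1, truth


def generate_flat_patch_phantom(
    normal_offset: float,
    patch_halfwidth: float = 20.0,
    patch_z: float = -30.0,
    grid_n: int = 15,
    dome_radii=(80.0, 68.0, 60.0),
) -> tuple[TriangleMesh, TriangleMesh, PhantomGroundTruth]:
    """Phantom whose ROI2 is a flat square patch displaced along its normal.

    Because every displaced vertex projects straight back onto the plane,
    the ground-truth ROI2 RMS equals |normal_offset| exactly — the analytic
    ground truth for the deviation stage.
    """
    cranium = dome_mesh(dome_radii)
    xs = np.linspace(-patch_halfwidth, patch_halfwidth, grid_n)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    patch_v = np.stack([gx.ravel(), gy.ravel(), np.full(grid_n**2, patch_z)], axis=1)
    faces = []
    for i in range(grid_n - 1):
        for j in range(grid_n - 1):
            v00 = i * grid_n + j
            v01 = v00 + 1
            v10 = v00 + grid_n
            v11 = v10 + 1
            faces.append([v00, v10, v11])
            faces.append([v00, v11, v01])
    n1 = cranium.n_vertices
    vertices = np.vstack([cranium.vertices, patch_v])
    all_faces = np.vstack([cranium.faces, np.asarray(faces, dtype=np.int64) + n1])
    t0 = TriangleMesh(vertices, all_faces)
    roi1 = roi_from_indices(t0, np.arange(n1), "ROI1")
    roi2 = roi_from_indices(t0, np.arange(n1, t0.n_vertices), "ROI2")
    v1 = t0.vertices.copy()
    v1[n1:, 2] += normal_offset
    t1 = TriangleMesh(v1, all_faces.copy())
    res = RigidTransform(np.eye(3), np.array([0.0, 0.0, normal_offset]))
    spec = PhantomSpec(true_residual_transform=res)
    truth = PhantomGroundTruth(
        spec=spec,
        roi1=roi1,
        roi2=roi2,
        expected_rms_noise_floor=0.0,
        residual_transform=res,
        residual_center=patch_v.mean(axis=0),
        pose_perturbation=RigidTransform.identity(),
    )
    return t0, t1, truth


def _calibrate_translation_magnitude(
    t0: TriangleMesh, roi2: ROISelection, direction: np.ndarray, target_rms: float
) -> float:
    """Translation magnitude along `direction` whose noiseless ground-truth
    ROI2 RMS equals `target_rms`, found by 1-D root bracketing."""
    if target_rms < 1e-9:
        return 0.0
    ref = extract_submesh(t0, roi2)
    prox = MeshProximity(ref)
    base = t0.vertices[roi2.vertex_indices]

    def f(m: float) -> float:
        res = surface_deviation(base + m * direction, ref, signed=False, index=prox)
        return res.summary.rms - target_rms

    hi = max(2.0 * target_rms, 1.0)
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e3:
            raise MaxalignError("calibration failed to bracket the target RMS")
    return float(brentq(f, 0.0, hi, xtol=1e-10))


def generate_cohort(
    out_dir: str | Path,
    n_per_group: int = 5,
    group_effects: tuple[float, float] = (1.22, 1.63),
    between_patient_sd: float = 0.4,
    noise_sd: float = 0.05,
    seed: int = 0,
    spec_template: PhantomSpec | None = None,
    group_labels: tuple[str, str] = ("splintless", "splint"),
    subgroup_labels: tuple[str, str] = ("monobloc", "segmental"),
    max_pose_rotation_deg: float = 10.0,
    max_pose_translation: float = 10.0,
    stl_dialect: str = "binary",
) -> tuple[pd.DataFrame, list[PhantomGroundTruth]]:
    """Generate a two-group phantom cohort on disk (STL + ROI JSON + manifest).

    Per-case target RMS values are drawn moment-matched: the drawn targets
    in each group have sample mean exactly `group_effects[g]` and sample SD
    exactly `between_patient_sd` (for n >= 2), then each case's maxillary
    residual translation is calibrated by root finding so its noiseless
    ground-truth ROI2 RMS equals its target. Subgroup labels alternate
    within each group. Fully reproducible from `seed`.
    """
    if n_per_group < 1:
        raise MaxalignError("n_per_group must be >= 1")
    if any(e < 0 for e in group_effects) or between_patient_sd < 0:
        raise MaxalignError("effect sizes must be non-negative")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    template = spec_template or PhantomSpec()
    template = replace(template, noise_sd=noise_sd)

    rows = []
    truths: list[PhantomGroundTruth] = []
    for g, (effect, label) in enumerate(zip(group_effects, group_labels)):
        z = rng.standard_normal(n_per_group)
        if n_per_group >= 2:
            z = z - z.mean()
            s = z.std(ddof=1)
            z = z / s if s > 0 else z
        else:
            z = np.zeros(1)
        targets = np.maximum(effect + between_patient_sd * z, 0.0 if effect == 0 else 0.01)
        for k, target in enumerate(targets):
            case_id = f"{label}_{k + 1:02d}"
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            angle = rng.uniform(0.0, max_pose_rotation_deg)
            pose = RigidTransform(
                Rotation.from_rotvec(np.deg2rad(angle) * axis).as_matrix(),
                rng.uniform(-max_pose_translation, max_pose_translation, 3),
            )
            case_seed = int(rng.integers(0, 2**31 - 1))
            probe_spec = replace(
                template,
                true_residual_transform=RigidTransform.identity(),
                global_pose_perturbation=RigidTransform.identity(),
                noise_sd=0.0,
                artifact_fraction=0.0,
                seed=case_seed,
            )
            t0_clean, _, truth_clean = generate_phantom_pair(probe_spec)
            magnitude = _calibrate_translation_magnitude(
                t0_clean, truth_clean.roi2, u, float(target)
            )
            spec = replace(
                template,
                true_residual_transform=RigidTransform(np.eye(3), magnitude * u),
                global_pose_perturbation=pose,
                seed=case_seed,
            )
            t0, t1, truth = generate_phantom_pair(spec)
            truths.append(truth)
            t0_path = out_dir / f"{case_id}_t0.stl"
            t1_path = out_dir / f"{case_id}_t1.stl"
            write_stl(t0, t0_path, dialect=stl_dialect)
            write_stl(t1, t1_path, dialect=stl_dialect)
            roi1_path = out_dir / f"{case_id}_roi1.json"
            roi2_path = out_dir / f"{case_id}_roi2.json"
            save_roi_definition(
                {"type": "indices", "name": "ROI1",
                 "indices": truth.roi1.vertex_indices.tolist()},
                roi1_path,
            )
            save_roi_definition(
                {"type": "indices", "name": "ROI2",
                 "indices": truth.roi2.vertex_indices.tolist()},
                roi2_path,
            )
            rows.append(
                {
                    "case_id": case_id,
                    "group": label,
                    "subgroup": subgroup_labels[k % 2],
                    "t0_path": str(t0_path),
                    "t1_path": str(t1_path),
                    "roi1_def": str(roi1_path),
                    "roi2_def": str(roi2_path),
                    "seed": case_seed,
                    "target_rms_mm": float(target),
                    "residual_translation_mm": magnitude,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest, truths
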