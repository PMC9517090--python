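"""End-to-end orchestration: per-case analysis, operator replicates, cohorts.

Per case the procedure is: load and validate the planned (T0) and
postoperative (T1) surfaces, resolve both ROIs on each, coarsely align the
T1 reference region to T0's (initial alignment), refine with trimmed
point-to-mesh ICP against the T0 reference sub-mesh (optimized alignment),
apply the resulting transform to the whole T1 mesh, measure the deviation
of T1's maxillary vertices against the planned maxillary sub-mesh, and
summarize (max/min/mean/RMS) with the +/-2 mm acceptability call.

The deviation direction is achieved-vs-planned (T1 sample points measured
against the T0 surface); `reverse=True` swaps it. Per-case results from
several operators (replicated, jittered ROI selections) are averaged into
one 3D error per patient; cohorts are compared per contrast (all cases,
monobloc-only, segmental-only) with group summaries and a t-test.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .deviation import (
    ACCEPTABILITY_THRESHOLD_MM,
    DeviationResult,
    classify_acceptability,
    deviation_colormap,
    surface_deviation,
)
from .errors import PipelineError
from .mesh_io import TriangleMesh, read_stl
from .registration import (
    ICPParams,
    RegistrationReport,
    icp_refine,
    initial_alignment,
)
from .roi import (
    ROISelection,
    extract_points,
    extract_submesh,
    roi_from_definition,
    roi_from_indices,
)
from .stats import CaseResult, GroupComparison, average_operators, group_summary, t_test

__all__ = [
    "CaseConfig",
    "CaseOutcome",
    "run_case",
    "run_case_meshes",
    "make_operator_configs",
    "run_operator_replicates",
    "run_cohort",
]


@dataclass(frozen=True)
class CaseConfig:
    """Inputs of one case analysis (paths and parameters)."""

    t0_path: str
    t1_path: str
    roi1_def: str | dict
    roi2_def: str | dict
    icp_params: ICPParams = field(default_factory=ICPParams)
    signed_deviation: bool = False
    acceptability_threshold: float = ACCEPTABILITY_THRESHOLD_MM
    operator_id: str = "op1"
    seed: int = 0
    reverse: bool = False
    roi_jitter_fraction: float = 0.0  # fraction of ROI vertices dropped per operator
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.acceptability_threshold <= 0:
            raise PipelineError("acceptability threshold must be positive")
        if not 0.0 <= self.roi_jitter_fraction < 0.5:
            raise PipelineError("roi_jitter_fraction must be in [0, 0.5)")


@dataclass
class CaseOutcome:
    """Everything one case run produces."""

    rms_3d_error: float
    acceptable: bool
    deviation: DeviationResult
    registration: RegistrationReport
    operator_id: str
    log: list[str] = field(default_factory=list)


def _jitter_roi(roi: ROISelection, mesh: TriangleMesh, fraction: float, seed: int) -> ROISelection:
    """Drop a seeded random fraction of ROI vertices, emulating the
    between-operator variability of a hand-drawn selection boundary."""
    if fraction <= 0:
        return roi
    rng = np.random.default_rng(seed)
    n = len(roi.vertex_indices)
    n_drop = int(np.floor(fraction * n))
    if n_drop == 0 or n - n_drop < 4:
        return roi
    keep = np.sort(rng.choice(n, n - n_drop, replace=False))
    return roi_from_indices(mesh, roi.vertex_indices[keep], roi.name)


def run_case_meshes(
    t0: TriangleMesh,
    t1: TriangleMesh,
    roi1_t0: ROISelection,
    roi2_t0: ROISelection,
    roi1_t1: ROISelection | None = None,
    roi2_t1: ROISelection | None = None,
    icp_params: ICPParams | None = None,
    signed_deviation: bool = False,
    acceptability_threshold: float = ACCEPTABILITY_THRESHOLD_MM,
    reverse: bool = False,
    seed: int = 0,
    operator_id: str = "op1",
    out_dir: str | Path | None = None,
) -> CaseOutcome:
    """Run the per-case procedure on in-memory meshes.

    ROIs are defined on T0; by default the same index sets are used on T1
    (valid whenever both exports share the labeling, as the phantoms do).
    """
    icp_params = icp_params or ICPParams()
    log: list[str] = []
    roi1_t1 = roi1_t1 or roi1_t0
    roi2_t1 = roi2_t1 or roi2_t0

    try:
        src_pts = extract_points(t1, roi1_t1)[0]
        tgt_pts = extract_points(t0, roi1_t0)[0]
        tgt_ref = extract_submesh(t0, roi1_t0)
    except Exception as exc:
        raise PipelineError(f"stage=roi-selection failed: {exc}") from exc
    log.append(f"stage=roi n_roi1_t1={len(src_pts)} n_roi1_t0={len(tgt_pts)}")

    try:
        init = initial_alignment(src_pts, tgt_pts)
    except Exception as exc:
        raise PipelineError(f"stage=initial-alignment failed: {exc}") from exc
    log.append(
        f"stage=initial-alignment rotation_deg={init.rotation_angle_deg():.4f}"
    )

    try:
        report = icp_refine(src_pts, tgt_ref, init=init, params=icp_params, seed=seed)
    except Exception as exc:
        raise PipelineError(f"stage=icp failed: {exc}") from exc
    if not report.converged:
        warnings.warn(
            f"ICP did not converge within {icp_params.max_iterations} iterations",
            stacklevel=2,
        )
    log.append(
        "stage=icp iterations={} converged={} final_rms={:.6g} "
        "correspondences={}".format(
            report.iterations_run,
            report.converged,
            report.rms_per_iteration[-1] if report.rms_per_iteration else float("nan"),
            report.correspondences_used,
        )
    )

    t1_aligned = report.final_transform.apply_mesh(t1)
    try:
        if not reverse:
            samples = extract_points(t1_aligned, roi2_t1)[0]
            reference = extract_submesh(t0, roi2_t0)
        else:
            samples = extract_points(t0, roi2_t0)[0]
            reference = extract_submesh(t1_aligned, roi2_t1)
        dev = surface_deviation(samples, reference, signed=signed_deviation)
    except Exception as exc:
        raise PipelineError(f"stage=deviation failed: {exc}") from exc
    rms = dev.summary.rms
    acceptable = classify_acceptability(rms, acceptability_threshold)
    log.append(
        f"stage=deviation n_points={dev.summary.n_points} rms={rms:.6g} "
        f"mean={dev.summary.mean_dev:.6g} max={dev.summary.max_dev:.6g} "
        f"min={dev.summary.min_dev:.6g} acceptable={acceptable}"
    )

    outcome = CaseOutcome(
        rms_3d_error=rms,
        acceptable=acceptable,
        deviation=dev,
        registration=report,
        operator_id=operator_id,
        log=log,
    )
    if out_dir is not None:
        _write_case_outputs(outcome, t1_aligned, roi2_t1, Path(out_dir), operator_id)
    return outcome


def _write_case_outputs(
    outcome: CaseOutcome,
    t1_aligned: TriangleMesh,
    roi2_t1: ROISelection,
    out_dir: Path,
    tag: str,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    s = outcome.deviation.summary
    pd.DataFrame(
        [
            {
                "max_dev_mm": s.max_dev,
                "min_dev_mm": s.min_dev,
                "mean_dev_mm": s.mean_dev,
                "rms_mm": s.rms,
                "n_points": s.n_points,
                "acceptable": outcome.acceptable,
            }
        ]
    ).to_csv(out_dir / f"{tag}_summary.tsv", sep="\t", index=False)
    pts = outcome.deviation.sample_points
    pd.DataFrame(
        {
            "point_id": np.arange(len(pts)),
            "x_mm": pts[:, 0],
            "y_mm": pts[:, 1],
            "z_mm": pts[:, 2],
            "distance_mm": outcome.deviation.distances,
        }
    ).to_csv(out_dir / f"{tag}_points.tsv", sep="\t", index=False)
    try:
        # the sub-mesh may drop ROI vertices not covered by a fully-interior
        # face; the colormap is only written when the field maps 1:1
        region = extract_submesh(t1_aligned, roi2_t1)
        if region.n_vertices == len(outcome.deviation.distances):
            deviation_colormap(region, outcome.deviation, out_dir / f"{tag}_colormap.ply")
    except Exception:
        pass  # colormap is best-effort decoration
    (out_dir / f"{tag}_log.txt").write_text("\n".join(outcome.log) + "\n")


def run_case(config: CaseConfig) -> CaseOutcome:
    """Run one case from files per its configuration."""
    try:
        t0 = read_stl(config.t0_path)
        t1 = read_stl(config.t1_path)
    except Exception as exc:
        raise PipelineError(f"stage=load failed: {exc}") from exc
    roi1 = roi_from_definition(t0, config.roi1_def, "ROI1")
    roi2 = roi_from_definition(t0, config.roi2_def, "ROI2")
    roi1_t1 = roi_from_definition(t1, config.roi1_def, "ROI1")
    roi2_t1 = roi_from_definition(t1, config.roi2_def, "ROI2")
    if config.roi_jitter_fraction > 0:
        # stable across processes (unlike hash()), keeping runs reproducible
        jseed = config.seed + zlib.crc32(config.operator_id.encode()) % 10_000
        roi1 = _jitter_roi(roi1, t0, config.roi_jitter_fraction, jseed)
        roi1_t1 = _jitter_roi(roi1_t1, t1, config.roi_jitter_fraction, jseed + 1)
    return run_case_meshes(
        t0,
        t1,
        roi1,
        roi2,
        roi1_t1=roi1_t1,
        roi2_t1=roi2_t1,
        icp_params=config.icp_params,
        signed_deviation=config.signed_deviation,
        acceptability_threshold=config.acceptability_threshold,
        reverse=config.reverse,
        seed=config.seed,
        operator_id=config.operator_id,
        out_dir=config.out_dir,
    )


def make_operator_configs(
    base: CaseConfig, n_operators: int = 3, jitter_fraction: float = 0.02
) -> list[CaseConfig]:
    """Replicate a case config for several operators with jittered ROIs."""
    if n_operators < 1:
        raise PipelineError("need at least one operator")
    return [
        replace(
            base,
            operator_id=f"op{i + 1}",
            roi_jitter_fraction=jitter_fraction if i > 0 else 0.0,
            seed=base.seed + 1000 * i,
        )
        for i in range(n_operators)
    ]


def run_operator_replicates(configs: list[CaseConfig]) -> tuple[float, list[CaseOutcome]]:
    """Run each operator replicate and average the RMS 3D errors."""
    if not configs:
        raise PipelineError("no operator replicates supplied")
    outcomes = []
    failures = []
    for cfg in configs:
        try:
            outcomes.append(run_case(cfg))
        except Exception as exc:  # noqa: BLE001 - collected and re-raised
            failures.append((cfg.operator_id, str(exc)))
    if failures:
        raise PipelineError(
            "operator replicate failures: "
            + "; ".join(f"{op}: {msg}" for op, msg in failures)
        )
    mean_rms = average_operators([o.rms_3d_error for o in outcomes])
    return mean_rms, outcomes


def run_cohort(
    manifest: pd.DataFrame | str | Path,
    contrasts: tuple[str, ...] = ("all", "monobloc", "segmental"),
    icp_params: ICPParams | None = None,
    n_operators: int = 1,
    jitter_fraction: float = 0.02,
    alpha: float = 0.05,
    acceptability_threshold: float = ACCEPTABILITY_THRESHOLD_MM,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[str, GroupComparison]]:
    """Run every case of a cohort manifest and the group contrasts.

    The manifest (DataFrame or TSV path) needs columns case_id, group,
    subgroup, t0_path, t1_path, roi1_def, roi2_def and optionally seed.
    Returns the per-case results table and one GroupComparison per contrast;
    contrasts with fewer than two cases in either group are skipped with a
    warning. The group test is the independent-samples pooled t-test — a
    paired test is undefined between arms containing different patients.
    """
    if isinstance(manifest, (str, Path)):
        manifest = pd.read_csv(manifest, sep="\t")
    required = {"case_id", "group", "subgroup", "t0_path", "t1_path", "roi1_def", "roi2_def"}
    missing = required - set(manifest.columns)
    if missing:
        raise PipelineError(f"manifest missing columns: {sorted(missing)}")
    if manifest["case_id"].duplicated().any():
        raise PipelineError("duplicate case_ids in manifest")
    groups = sorted(manifest["group"].unique())
    if len(groups) != 2:
        raise PipelineError(f"cohort needs exactly 2 groups, found {groups}")

    icp_params = icp_params or ICPParams()
    records = []
    for _, row in manifest.iterrows():
        base = CaseConfig(
            t0_path=row["t0_path"],
            t1_path=row["t1_path"],
            roi1_def=row["roi1_def"],
            roi2_def=row["roi2_def"],
            icp_params=icp_params,
            acceptability_threshold=acceptability_threshold,
            seed=int(row.get("seed", 0)),
        )
        if n_operators > 1:
            mean_rms, outcomes = run_operator_replicates(
                make_operator_configs(base, n_operators, jitter_fraction)
            )
            op_values = [o.rms_3d_error for o in outcomes]
        else:
            outcome = run_case(base)
            mean_rms = outcome.rms_3d_error
            op_values = [mean_rms]
        case = CaseResult(
            case_id=str(row["case_id"]),
            group=str(row["group"]),
            subgroup=str(row["subgroup"]),
            operator_values=op_values,
            rms_3d_error=float(np.mean(op_values)),
            acceptable=classify_acceptability(mean_rms, acceptability_threshold),
        )
        records.append(case)

    results = pd.DataFrame(
        [
            {
                "case_id": c.case_id,
                "group": c.group,
                "subgroup": c.subgroup,
                "rms_3d_error_mm": c.rms_3d_error,
                "acceptable": c.acceptable,
                "operator_values": ";".join(f"{v:.6f}" for v in c.operator_values),
            }
            for c in records
        ]
    )

    comparisons: dict[str, GroupComparison] = {}
    for contrast in contrasts:
        sub = results if contrast == "all" else results[results["subgroup"] == contrast]
        vals = {
            g: sub.loc[sub["group"] == g, "rms_3d_error_mm"].to_numpy() for g in groups
        }
        if any(len(v) < 2 for v in vals.values()):
            warnings.warn(
                f"contrast {contrast!r} skipped: fewer than 2 cases per group",
                stacklevel=2,
            )
            continue
        comparisons[contrast] = t_test(
            vals[groups[0]],
            vals[groups[1]],
            mode="independent-pooled",
            alpha=alpha,
            group_labels=(groups[0], groups[1]),
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        results.to_csv(out_dir / "cohort_results.tsv", sep="\t", index=False)
        comp_rows = [
            {
                "contrast": name,
                "group_a": c.group_labels[0],
                "group_b": c.group_labels[1],
                "mean_a_mm": c.means[0],
                "mean_b_mm": c.means[1],
                "sd_a_mm": c.sds[0],
                "sd_b_mm": c.sds[1],
                "n_a": c.n[0],
                "n_b": c.n[1],
                "test": c.test_used,
                "t": c.t_statistic,
                "df": c.degrees_of_freedom,
                "p_value": c.p_value,
                "significant": c.significant,
            }
            for name, c in comparisons.items()
        ]
        pd.DataFrame(comp_rows).to_csv(out_dir / "cohort_contrasts.tsv", sep="\t", index=False)
    return results, comparisons
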