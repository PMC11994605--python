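"""End-to-end orchestration: cohort stats, full analysis runs, manifests.

``run_full_analysis`` chains every stage on synthetic data: cohort
generation -> Procrustes superimposition -> PLS-DA with LOOCV mode
selection and permutation nulls -> group-associated shapes -> thin-plate
spline warps and discrete metrics -> base/perturbed abduction paths ->
fibre solves -> stability summaries and shape comparison. Every artifact
is written as CSV/JSON (meshes as STL) under the output directory along
with a manifest; identical config + seed reproduce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import landmarks as lmio
from .fibres import (
    SphereSurface,
    build_fibre_set,
    check_tension,
    effective_endpoints,
    line_of_action,
    solve_fibre_set,
)
from .kinematics import (
    BodyFrame,
    KinematicPath,
    base_path,
    neutral_pose,
    perturb_path,
    place_humerus,
    scapula_frame,
)
from .landmarks import template_configuration, template_coords
from .plsda import (
    fit_pls,
    group_shape,
    loocv_mode_selection,
    n_modes_for_variance,
    null_model_comparison,
)
from .procrustes import _optimal_rotation, closest_to_mean, gpa
from .scapmetrics import compute_metrics, metrics_to_frame
from .stability import (
    StabilityRecord,
    compare_shapes,
    glenoid_frame,
    records_to_frame,
    stability_ratios,
    summarize,
)
from .synthgen import BoneParams, BoneSet, SynthConfig, generate_bone_geometry, generate_landmark_sample

__all__ = [
    "two_proportion_test",
    "RunConfig",
    "simulate_stability",
    "run_full_analysis",
    "DEFAULT_PERTURBATIONS",
]

_CSV_FLOAT = "%.10g"

# elevation-plane / axial-rotation offsets applied to the FTT-like shape:
# anterior shifts, internal rotations, and both combined
DEFAULT_PERTURBATIONS: tuple[tuple[float, float], ...] = (
    (5.0, 0.0), (10.0, 0.0), (0.0, 5.0), (0.0, 10.0), (5.0, 5.0), (10.0, 10.0),
)


def two_proportion_test(
    x1: int, n1: int, x2: int, n2: int, continuity_correction: bool = True
) -> tuple[float, float]:
    """Two-proportions Z-test (pooled), reported as (chi2, two-sided p).

    With the Yates continuity correction (default) this matches the
    classic chi-squared test on the 2x2 table. A degenerate pooled
    proportion (0 or 1) carries no information: (0, 1) is returned with a
    warning.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1 or not 0 <= x <= n:
            raise ValueError("need 0 <= successes <= total and total >= 1")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("degenerate pooled proportion; test is uninformative", stacklevel=2)
        return 0.0, 1.0
    diff = abs(x1 / n1 - x2 / n2)
    if continuity_correction:
        diff = max(0.0, diff - 0.5 * (1.0 / n1 + 1.0 / n2))
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = diff / se
    return z * z, 2.0 * float(norm.sf(z))


# ---------------------------------------------------------------------------
# stability simulation for one bone set along one kinematic path


def simulate_stability(
    bones: BoneSet,
    path: KinematicPath,
    gap: float = 1.0,
    coherence_weight: float = 0.1,
    contact_tol: float | None = None,
    check_placement: bool = False,
) -> tuple[list[StabilityRecord], np.ndarray]:
    """Fibre stability records along a kinematic path.

    At each pose the humerus is placed, all 50 fibre paths are solved with
    humeral-head wrapping and lateral coherence, effective endpoints and
    lines-of-action are extracted, and the SI/AP stability ratios are
    resolved in the glenoid principal-axes frame. Returns the records and
    the (n_poses, n_fibres) path-length matrix (for tension reporting).
    The contact tolerance defaults to 0.5% of the head radius.
    """
    tol = 0.005 * bones.head_radius if contact_tol is None else contact_tol
    fibre_set = build_fibre_set(bones.fossa_origin_perimeter, bones.insertion_perimeter)
    sframe = BodyFrame(origin=bones.glenoid_center, axes=np.eye(3))
    gframe = glenoid_frame(bones.glenoid_rim, sframe)

    records: list[StabilityRecord] = []
    lengths = np.zeros((len(path), len(fibre_set)))
    for pi, pose in enumerate(path):
        T = place_humerus(bones, pose, gap=gap, check=check_placement)
        head_world = T[:3, 3]
        sphere = (head_world, bones.head_radius)
        paths = solve_fibre_set(
            fibre_set, sphere=sphere, humerus_transform=T,
            coherence_weight=coherence_weight,
        )
        humerus_surface = SphereSurface(head_world, bones.head_radius)
        for f, p in zip(fibre_set.fibres, paths):
            lengths[pi, f.fibre_id] = p.length
            effective_endpoints(p, None, humerus_surface, tol)
            loa = line_of_action(p)
            si, ap, f_comp = stability_ratios(loa, gframe)
            records.append(StabilityRecord(
                fibre_id=f.fibre_id, sheet=f.sheet, subregion=f.subregion,
                pose_index=pi, abduction=pose.abduction,
                si_ratio=si, ap_ratio=ap, f_comp=f_comp,
                destabilizing=not (f_comp > 0.0),
            ))
    return records, lengths


# ---------------------------------------------------------------------------
# full analysis


@dataclass
class RunConfig:
    """Configuration of a full analysis run. The seed is mandatory."""

    seed: int
    synth: SynthConfig | None = None
    variance_fraction: float = 0.70
    m_cap: int | None = None
    n_null: int = 20
    control_bones: BoneParams = field(default_factory=BoneParams)
    ftt_bones: BoneParams = field(
        default_factory=lambda: BoneParams(
            version_deg=6.0, inclination_deg=2.0, fossa_width_factor=0.8)
    )
    perturbations: tuple[tuple[float, float], ...] = DEFAULT_PERTURBATIONS
    gap: float = 1.0
    coherence_weight: float = 0.1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.synth is None:
            self.synth = SynthConfig(seed=self.seed)


def _similarity_to_template(mean_shape: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Similarity transform mapping unit-size Procrustes coords to template units."""
    tpl = template_coords()
    tpl_c = tpl - tpl.mean(axis=0)
    R = _optimal_rotation(mean_shape, tpl_c)
    rotated = mean_shape @ R
    scale = float(np.sum(rotated * tpl_c) / np.sum(rotated * rotated))
    return scale, R, tpl.mean(axis=0)


def _to_template_space(shape: np.ndarray, scale: float, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return scale * (shape @ R) + t


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def run_full_analysis(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the whole pipeline and write all artifacts under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "outputs": [], "stages": []}

    def emit_csv(name: str, df: pd.DataFrame) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format=_CSV_FLOAT)
        manifest["outputs"].append(name)

    def stage(name):
        manifest["stages"].append(name)

    # --- cohort -----------------------------------------------------------
    stage("synthgen")
    sample = generate_landmark_sample(config.synth)
    lmio.write_csv(sample, out / "landmarks.csv")
    manifest["outputs"].append("landmarks.csv")
    digest = hashlib.sha256((out / "landmarks.csv").read_bytes()).hexdigest()
    manifest["landmarks_sha256"] = digest

    # --- shape model ------------------------------------------------------
    stage("gpa")
    aligned = gpa(sample)
    X = aligned.flat()
    y = aligned.groups.astype(float)
    template_idx = closest_to_mean(aligned)
    manifest["template_specimen"] = aligned.specimen_ids[template_idx]

    stage("plsda")
    m_max = n_modes_for_variance(X, y, config.variance_fraction)
    if config.m_cap is not None:
        m_max = min(m_max, config.m_cap)
    table, best_m, _ = loocv_mode_selection(X, y, m_max)
    emit_csv("loocv_metrics.csv", table)
    nullcmp = null_model_comparison(
        X, y, n_null=config.n_null, seed=config.seed,
        fraction=config.variance_fraction, m_cap=config.m_cap,
    )
    emit_csv("null_metrics.csv", nullcmp.null_table)
    _write_json(out / "null_comparison.json", {
        "m_max": m_max, "optimal_m": best_m,
        "true_metrics": nullcmp.true_report.as_dict(),
        "z_scores": nullcmp.z_scores, "p_values": nullcmp.p_values,
    })
    manifest["outputs"].append("null_comparison.json")

    model = fit_pls(X, y, best_m)
    model.to_json(out / "pls_model.json")
    manifest["outputs"].append("pls_model.json")
    shape_ctrl = group_shape(model, 0)
    shape_ftt = group_shape(model, 1)

    # --- warps and metrics -------------------------------------------------
    stage("tps+metrics")
    scale, R, t = _similarity_to_template(aligned.mean_shape)
    targets = {
        "control": _to_template_space(shape_ctrl, scale, R, t),
        "ftt": _to_template_space(shape_ftt, scale, R, t),
    }
    metric_rows = {}
    for name, target in targets.items():
        cfg = lmio.LandmarkConfiguration(target, specimen_id=f"{name}_associated")
        frame = scapula_frame(cfg)
        metric_rows[name] = compute_metrics(cfg, frame)
    mt = metrics_to_frame(metric_rows).reset_index(names="shape")
    emit_csv("discrete_metrics.csv", mt)

    from .tps import warp_mesh  # noqa: PLC0415

    tpl_mesh = generate_bone_geometry(config.control_bones).scapula_mesh
    tpl_lm = template_coords()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, target in targets.items():
            mesh = warp_mesh(tpl_mesh, tpl_lm, target)
            mesh.export(out / f"shape_{name}.stl")
            manifest["outputs"].append(f"shape_{name}.stl")

    # --- kinematics + fibres + stability -----------------------------------
    stage("simulate")
    bones = {"control": generate_bone_geometry(config.control_bones),
             "ftt": generate_bone_geometry(config.ftt_bones)}
    neutral = {name: neutral_pose(b, gap=config.gap) for name, b in bones.items()}
    _write_json(out / "neutral_poses.json", {
        name: {"elevation_plane": v[0], "abduction": v[1], "axial_rotation": v[2]}
        for name, v in neutral.items()
    })
    manifest["outputs"].append("neutral_poses.json")

    base = base_path()
    paths: list[tuple[str, str, KinematicPath]] = [
        ("control", "base", base), ("ftt", "base", base)]
    for d_plane, d_axial in config.perturbations:
        paths.append(("ftt", f"dplane{d_plane:+g}_daxial{d_axial:+g}",
                      perturb_path(base, d_plane, d_axial)))
    manifest["n_paths"] = len(paths)

    summaries: dict[tuple[str, str], pd.DataFrame] = {}
    all_records = []
    for shape_name, path_name, kpath in paths:
        records, lengths = simulate_stability(
            bones[shape_name], kpath, gap=config.gap,
            coherence_weight=config.coherence_weight,
        )
        df = records_to_frame(records)
        df.insert(0, "shape", shape_name)
        df.insert(1, "path", path_name)
        all_records.append(df)
        summaries[(shape_name, path_name)] = summarize(records, by="all")
    emit_csv("stability_records.csv", pd.concat(all_records, ignore_index=True))

    summary_frames = []
    for (shape_name, path_name), summ in summaries.items():
        s = summ.copy()
        s.insert(0, "shape", shape_name)
        s.insert(1, "path", path_name)
        summary_frames.append(s)
    emit_csv("stability_summaries.csv", pd.concat(summary_frames, ignore_index=True))

    stage("report")
    comparison = compare_shapes(summaries[("control", "base")], summaries[("ftt", "base")])
    emit_csv("comparison_ftt_vs_control_base.csv", comparison)
    report = {
        "ap_mean_shift_ftt_minus_control": {
            "min": float(comparison["ap_ratio_mean_diff"].min()),
            "max": float(comparison["ap_ratio_mean_diff"].max()),
        },
        "neutral_pose_offset_ftt_minus_control": {
            "elevation_plane": neutral["ftt"][0] - neutral["control"][0],
            "axial_rotation": neutral["ftt"][2] - neutral["control"][2],
        },
        "optimal_m": best_m,
        "balanced_accuracy": nullcmp.true_report.balanced_accuracy,
    }
    _write_json(out / "report.json", report)
    manifest["outputs"].append("report.json")

    _write_json(out / "manifest.json", manifest)
    return out
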