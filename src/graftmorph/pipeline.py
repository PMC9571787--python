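"""End-to-end orchestration: segment -> register -> osteotomy -> place ->
isolate -> measure -> grade, with a machine-readable provenance report.

Every stage's resolved parameters, residuals and outputs are echoed into
the report JSON so that each number is reproducible from the written
intermediates alone. All randomness flows from the single ``seed``.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .errors import ConfigError, GraftMorphError
from .graft_morphometry import (
    AxisFrame,
    GraftPair,
    OsteotomyPlane,
    ZhuGrade,
    cut_mesh,
    fit_osteotomy_plane,
    fit_screws,
    grade_patient,
    isolate_followup_graft,
    mesh_volume,
    place_graft,
    regional_resorption,
)
from .io_formats import CTVolume, read_volume, write_mesh
from .registration import apply_transform, icp_register, initialize_alignment
from .segmentation import SegmentationParams, extract_surface, segment_bone, segment_metal

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Resolved configuration for one patient (or phantom) run."""

    preop_path: str | None = None
    followup_path: str | None = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    osteotomy_plane: OsteotomyPlane | None = None
    osteotomy_landmarks: list | None = None    # >= 3 points, pre-op frame
    coracoid_tip_landmark: list | None = None  # pre-op frame
    glenoid_landmark_preop: list | None = None # pre-op frame; mapped via registration
    axes_preop: AxisFrame = field(default_factory=AxisFrame)
    max_iterations: int = 400
    icp_tolerance_mm: float = 1e-4
    regional_pitch_mm: float = 0.5
    zhu_head_coverage: float = 0.95
    zhu_shaft_coverage: float = 0.95
    zhu_proximity_mm: float = 2.0
    out_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "segmentation" in raw and isinstance(raw["segmentation"], dict):
            raw["segmentation"] = SegmentationParams(**raw["segmentation"])
        if "osteotomy_plane" in raw and isinstance(raw["osteotomy_plane"], dict):
            raw["osteotomy_plane"] = OsteotomyPlane(
                raw["osteotomy_plane"]["point_mm"], raw["osteotomy_plane"]["normal"]
            )
        if "axes_preop" in raw and isinstance(raw["axes_preop"], dict):
            raw["axes_preop"] = AxisFrame(**raw["axes_preop"])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("preop_path", "followup_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} does not exist: {p}")
        if self.osteotomy_plane is None and not self.osteotomy_landmarks:
            raise ConfigError("either osteotomy_plane or >= 3 landmarks required")


def run_pipeline(
    config: PipelineConfig,
    preop: CTVolume | None = None,
    followup: CTVolume | None = None,
) -> dict:
    """Execute the full measurement on one pre-op / follow-up pair.

    Volumes may be passed in-memory; otherwise they are read from the
    configured paths. Returns the report dict; if ``config.out_dir`` is
    set, every intermediate mesh (STL) and the report JSON are written.
    A stage failure writes the partial report with a stage-tagged error
    and re-raises.
    """
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tool": {"name": "graftmorph", "version": __version__},
        "seed": config.seed,
        "parameters": {
            "segmentation": config.segmentation.to_dict(),
            "icp": {
                "max_iterations": config.max_iterations,
                "tolerance_mm": config.icp_tolerance_mm,
            },
            "regional_pitch_mm": config.regional_pitch_mm,
            "zhu": {
                "head_coverage": config.zhu_head_coverage,
                "shaft_coverage": config.zhu_shaft_coverage,
                "proximity_mm": config.zhu_proximity_mm,
            },
        },
        "stages": {},
    }
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def save_mesh(mesh, name):
        if out_dir and len(mesh.faces):
            write_mesh(mesh, out_dir / f"{name}.stl")

    def finish(stage, err=None):
        if err is not None:
            report["error"] = {"stage": stage, "message": str(err)}
        if out_dir:
            with open(out_dir / "report.json", "w") as fh:
                json.dump(report, fh, indent=2, default=_jsonable)

    stage = "config"
    try:
        t_start = time.perf_counter()
        if preop is None or followup is None:
            config.validate()
            if preop is None:
                preop = read_volume(config.preop_path)
            if followup is None:
                followup = read_volume(config.followup_path)

        stage = "segment"
        t0 = time.perf_counter()
        params = config.segmentation
        pre_bone = segment_bone(preop, params)
        fu_bone = segment_bone(followup, params)
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            fu_metal = segment_metal(followup, params)
        pre_mesh = extract_surface(pre_bone, params, provenance="pre-op")
        fu_mesh = extract_surface(fu_bone, params, provenance="follow-up")
        save_mesh(pre_mesh, "preop_scapula")
        save_mesh(fu_mesh, "followup_scapula")
        report["stages"]["segment"] = {
            "preop_bone_voxel_mm3": pre_bone.volume_mm3(),
            "followup_bone_voxel_mm3": fu_bone.volume_mm3(),
            "metal_voxel_mm3": fu_metal.volume_mm3(),
            "seconds": time.perf_counter() - t0,
        }

        stage = "register"
        t0 = time.perf_counter()
        plane = config.osteotomy_plane
        if plane is None:
            plane = fit_osteotomy_plane(
                config.osteotomy_landmarks, orient_toward=pre_mesh.centroid
            )
        init = initialize_alignment(pre_mesh, fu_mesh)
        reg = icp_register(
            pre_mesh, fu_mesh, init,
            max_iterations=config.max_iterations,
            tolerance=config.icp_tolerance_mm,
            seed=config.seed,
        )
        # refinement pass: the harvested coracoid (graft side of the
        # osteotomy plane, plus a margin around the cut) has no counterpart
        # in the follow-up anatomy and is excluded from correspondences
        exclude = plane.signed_distance(pre_mesh.vertices) < 3.0
        reg = icp_register(
            pre_mesh, fu_mesh, reg.transform,
            max_iterations=config.max_iterations,
            tolerance=config.icp_tolerance_mm,
            seed=config.seed,
            exclude_moving=exclude,
        )
        report["stages"]["register"] = reg.to_dict() | {
            "refinement_excluded_vertices": int(exclude.sum()),
            "seconds": time.perf_counter() - t0,
        }

        stage = "osteotomy"
        t0 = time.perf_counter()
        graft0_pre, remainder_pre = cut_mesh(
            pre_mesh, plane, tip_landmark=config.coracoid_tip_landmark
        )
        if len(graft0_pre.faces) == 0:
            raise GraftMorphError("osteotomy produced an empty graft")
        graft0 = apply_transform(graft0_pre, reg.transform)
        remainder = apply_transform(remainder_pre, reg.transform)
        volume_t0 = mesh_volume(graft0)
        save_mesh(graft0, "modeled_graft_t0")
        save_mesh(remainder, "registered_scapula_remainder")
        report["stages"]["osteotomy"] = {
            "plane": plane.to_dict(),
            "volume_t0_mm3": volume_t0,
            "seconds": time.perf_counter() - t0,
        }

        stage = "screws"
        t0 = time.perf_counter()
        screws = fit_screws(fu_metal) if fu_metal.data.any() else []
        report["stages"]["screws"] = {
            "n_screws": len(screws),
            "models": [s.to_dict() for s in screws],
            "seconds": time.perf_counter() - t0,
        }

        stage = "isolate"
        t0 = time.perf_counter()
        glenoid_landmark = None
        if config.glenoid_landmark_preop is not None:
            glenoid_landmark = reg.transform.apply(
                np.asarray(config.glenoid_landmark_preop, dtype=float)
            )
        iso = isolate_followup_graft(
            fu_bone, remainder, fu_metal,
            screw_models=screws,
            glenoid_landmark=glenoid_landmark,
            params=params,
        )
        save_mesh(iso.mesh, "followup_graft")
        volume_fu = mesh_volume(iso.mesh) if len(iso.mesh.faces) else 0.0
        report["stages"]["isolate"] = {
            "volume_followup_mesh_mm3": volume_fu,
            "volume_followup_voxel_mm3": iso.voxel_volume_mm3,
            "grade_iii_candidate": iso.grade_iii_candidate,
            "seconds": time.perf_counter() - t0,
        }

        stage = "measure"
        t0 = time.perf_counter()
        axes = config.axes_preop.rotated(reg.transform.rotation)
        regional = None
        placement = None
        if len(iso.mesh.faces):
            placement = place_graft(
                graft0, remainder, iso.mesh,
                superior_axis=axes.superior, seed=config.seed,
            )
            save_mesh(placement.graft, "modeled_graft_placed")
            regional = regional_resorption(
                placement.graft, iso.mesh, axes, pitch=config.regional_pitch_mm
            )
            pair = GraftPair.from_meshes(placement.graft, iso.mesh)
        else:
            pair = GraftPair(graft0, iso.mesh, volume_t0, 0.0, volume_t0, 100.0)
            regional = {
                k: 100.0 for k in
                ("superior", "inferior", "medial", "lateral", "superficial", "deep")
            }
        report["volumes"] = {
            "t0_mm3": pair.volume_t0,
            "followup_mm3": pair.volume_followup,
            "followup_voxel_mm3": iso.voxel_volume_mm3,
        }
        report["resorption"] = {
            "mm3": pair.resorption_mm3,
            "pct_loss_positive": pair.resorption_pct,
            "pct_signed": -pair.resorption_pct,
        }
        report["regional_resorption_pct"] = regional
        report["stages"]["measure"] = {
            "placement_rms_mm": placement.rms_residual if placement else None,
            "seconds": time.perf_counter() - t0,
        }

        stage = "grade"
        t0 = time.perf_counter()
        if screws:
            ref_graft = placement.graft if placement else graft0
            spans = []
            for s in screws:
                proj = (ref_graft.vertices - s.head_base) @ (-s.axis)
                spans.append(float(np.clip(proj.max(), 2.0, s.length)))
            zhu = grade_patient(
                iso.mesh, screws, shaft_spans=spans,
                head_coverage_threshold=config.zhu_head_coverage,
                shaft_coverage_threshold=config.zhu_shaft_coverage,
                proximity_mm=config.zhu_proximity_mm,
            )
            report["zhu"] = {
                "per_screw": list(zhu.per_screw),
                "overall": zhu.overall,
                "shaft_spans_mm": spans,
            }
        else:
            report["zhu"] = {"per_screw": [], "overall": None, "ungradable": True}
        report["stages"]["grade"] = {"seconds": time.perf_counter() - t0}
        report["total_seconds"] = time.perf_counter() - t_start

        finish(stage)
        return report
    except Exception as exc:
        finish(stage, exc)
        raise


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
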