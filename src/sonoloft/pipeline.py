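"""End-to-end pipeline: simulate/ingest -> segment -> register -> loft -> report.

Configuration is one structured mapping (YAML on disk); every artifact
embeds the seed and a hash of the canonical configuration, so re-running
with the same pair reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import phantom as ph
from .geometry import Contour2D, RigidPose2, resample_contour
from .reconstruction import (
    ScanProtocol, StructureReport, build_stack, structure_report,
    verify_phantom, write_stl,
)
from .registration import apply_view_pose, fit_view_poses, fuse_views
from .segmentation import (
    ContourRecord, SchemaError, SegmentationConfig, SliceRecord,
    default_class_config, export_contours, extract_layer_contours,
    smooth_contour,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (reported before any stage runs)."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class RunConfig:
    """Everything one reproducible run needs.

    ``phantom_kind`` selects the synthetic object ("spindle" or "layered");
    ``segmentation_mode`` chooses between the exact analytic contours
    ("exact") and automatic extraction from rendered B-mode images
    ("bmode").  ``assignment`` maps each structure to the view in which it
    is seen entire.
    """

    seed: int = 0
    outdir: str = "run_out"
    protocol: ScanProtocol = dataclasses.field(default_factory=ScanProtocol)
    phantom_kind: str = "spindle"
    segmentation_mode: str = "exact"
    shared_label: str = "muscle"
    assignment: Dict[str, float] = dataclasses.field(
        default_factory=lambda: {"muscle": 45.0})
    n_calibration: int = 5
    min_calibration_area_mm2: float = 25.0
    n_ring: int = 128
    min_csa_mm2: float = 1.0
    pixel_spacing_mm: float = 0.2
    image_shape_px: Tuple[int, int] = (500, 550)
    smooth_window: int = 5
    smooth_resample_n: int = 256  # densify traced contours before smoothing
    position_noise_mm: float = 0.1
    write_images: bool = False
    write_stl_files: bool = True
    view_poses: Optional[Dict[float, RigidPose2]] = None  # simulation truth

    def validate(self) -> None:
        if self.phantom_kind not in ("spindle", "layered"):
            raise ConfigError(f"unknown phantom_kind {self.phantom_kind!r}")
        if self.segmentation_mode not in ("exact", "bmode"):
            raise ConfigError(f"unknown segmentation_mode {self.segmentation_mode!r}")
        if self.protocol.base_view_angle_deg not in self.protocol.view_angles_deg:
            raise ConfigError("base view missing from protocol view angles")
        for label, view in self.assignment.items():
            if float(view) not in [float(a) for a in self.protocol.view_angles_deg]:
                raise ConfigError(f"assignment of {label!r} to unknown view {view}")

    # -- serialization ------------------------------------------------------
    def to_json_obj(self) -> dict:
        obj = dataclasses.asdict(self)
        obj["protocol"] = dataclasses.asdict(self.protocol)
        obj["image_shape_px"] = list(self.image_shape_px)
        if self.view_poses is not None:
            obj["view_poses"] = {
                str(a): {"theta_deg": p.theta_deg, "anchor_mm": list(p.anchor)}
                for a, p in sorted(self.view_poses.items())
            }
        return obj

    @classmethod
    def from_json_obj(cls, obj: dict) -> "RunConfig":
        obj = dict(obj)
        if "protocol" in obj:
            proto = dict(obj["protocol"])
            if "view_angles_deg" in proto:
                proto["view_angles_deg"] = tuple(float(a) for a in proto["view_angles_deg"])
            obj["protocol"] = ScanProtocol(**proto)
        if "image_shape_px" in obj:
            obj["image_shape_px"] = tuple(obj["image_shape_px"])
        if obj.get("view_poses") is not None:
            obj["view_poses"] = {
                float(a): RigidPose2(v["theta_deg"], tuple(v["anchor_mm"]))
                for a, v in obj["view_poses"].items()
            }
        if "assignment" in obj:
            obj["assignment"] = {k: float(v) for k, v in obj["assignment"].items()}
        try:
            return cls(**obj)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text())
        if not isinstance(obj, dict):
            raise ConfigError(f"{path}: expected a mapping")
        return cls.from_json_obj(obj)

    def config_hash(self) -> str:
        """Hash of the computational configuration (output locations and
        write toggles excluded: they do not affect any computed value)."""
        obj = self.to_json_obj()
        for key in ("outdir", "write_images", "write_stl_files"):
            obj.pop(key, None)
        canon = json.dumps(obj, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def spindle_config(seed: int = 0, outdir: str = "run_out",
                   segmentation_mode: str = "exact") -> RunConfig:
    """Three-view 44-step 5 mm scan of the default muscle spindle."""
    return RunConfig(seed=seed, outdir=outdir,
                     segmentation_mode=segmentation_mode)


def layered_config(seed: int = 0, outdir: str = "run_out",
                   segmentation_mode: str = "exact",
                   step_mm: float = 1.0) -> RunConfig:
    """Single-view fine-stepped scan of the layered slab phantom."""
    n_steps = int(round(30.0 / step_mm)) + 1
    return RunConfig(
        seed=seed, outdir=outdir, phantom_kind="layered",
        segmentation_mode=segmentation_mode,
        protocol=ScanProtocol(step_mm=step_mm, n_steps=n_steps,
                              view_angles_deg=(26.0,), base_view_angle_deg=26.0),
        shared_label="muscle_layer",
        assignment={"muscle_layer": 26.0, "fat_layer": 26.0, "skin_layer": 26.0},
        image_shape_px=(400, 700),
    )


def default_phantom(cfg: RunConfig) -> ph.PhantomSpec:
    if cfg.phantom_kind == "spindle":
        return ph.make_muscle_spindle()
    return ph.make_layered_phantom(skin_contrast_boost=True)


def default_segmentation_config(spec: ph.PhantomSpec) -> SegmentationConfig:
    classes = {
        p.label: default_class_config(p.echo_class,
                                      bordered=p.border_class == "hyperechoic")
        for p in spec.parts
    }
    return SegmentationConfig(classes=classes)


# ---------------------------------------------------------------------------
# Report I/O
# ---------------------------------------------------------------------------

_REPORT_SCHEMA = {
    "seed": int, "config_sha256": str, "structures": list, "group": dict,
}
_STRUCT_SCHEMA = {"label": str, "volume_mm3": float, "cog_mm": list, "profile": dict}


def write_report(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_report(path) -> dict:
    """Read and validate a report JSON; schema errors carry a JSON pointer."""
    obj = json.loads(Path(path).read_text())
    for key, typ in _REPORT_SCHEMA.items():
        if key not in obj:
            raise SchemaError(f"/{key}: missing")
        if not isinstance(obj[key], typ):
            raise SchemaError(f"/{key}: expected {typ.__name__}, got {type(obj[key]).__name__}")
    for i, s in enumerate(obj["structures"]):
        for key, typ in _STRUCT_SCHEMA.items():
            if key not in s:
                raise SchemaError(f"/structures/{i}/{key}: missing")
            val = s[key]
            if typ is float and isinstance(val, int):
                val = float(val)
            if not isinstance(val, typ):
                raise SchemaError(
                    f"/structures/{i}/{key}: expected {typ.__name__}, "
                    f"got {type(s[key]).__name__}")
    return obj


def _report_obj(cfg: RunConfig, reports: List[StructureReport],
                group: StructureReport) -> dict:
    return {
        "seed": cfg.seed,
        "config_sha256": cfg.config_hash(),
        "structures": [r.to_json_obj() for r in reports],
        "group": {
            "label": group.label,
            "volume_mm3": group.volume_mm3,
            "cog_mm": list(group.cog_mm),
        },
    }


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineResult:
    config: RunConfig
    phantom: ph.PhantomSpec
    scan: ph.ScanResult
    segmented: Dict[float, List[SliceRecord]]
    viewset: object
    fused_by_step: Dict[int, List[Contour2D]]
    reports: List[StructureReport]
    group: StructureReport
    verification: object
    report_obj: dict
    outdir: Optional[Path]


def _segment_records(cfg: RunConfig, spec: ph.PhantomSpec,
                     scan: ph.ScanResult) -> Dict[float, List[SliceRecord]]:
    if cfg.segmentation_mode == "exact":
        return scan.records_by_view
    seg_cfg = default_segmentation_config(spec)
    out: Dict[float, List[SliceRecord]] = {}
    for angle, recs in scan.records_by_view.items():
        new_recs = []
        for r in recs:
            contours: List[Contour2D] = []
            if r.image is not None:
                raw = extract_layer_contours(r.image, seg_cfg)
                # densify before smoothing: averaging a sparse traced polygon
                # would shrink convex boundaries measurably
                contours = [
                    smooth_contour(resample_contour(c, cfg.smooth_resample_n),
                                   cfg.smooth_window)
                    for c in raw
                ]
            new_recs.append(SliceRecord(r.view_angle_deg, r.step_index, r.z_mm,
                                        contours, r.image, r.pixel_spacing_mm))
        out[angle] = new_recs
    return out


def run_pipeline(cfg: RunConfig, write: bool = True) -> PipelineResult:
    """Execute the full reconstruction on a simulated scan.

    Stages: phantom -> scan simulation -> segmentation (exact contours or
    B-mode extraction) -> view-pose fit -> placement in the base frame ->
    per-step fusion -> stacking -> lofting -> morphometry report ->
    phantom verification.  Any stage failure aborts with the stage name.
    """
    cfg.validate()
    outdir = Path(cfg.outdir) if write else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except (ConfigError, StageError):
            raise
        except Exception as exc:
            raise StageError(name, exc) from exc

    spec = stage("phantom", lambda: default_phantom(cfg))
    render = cfg.segmentation_mode == "bmode"
    scan = stage("simulate", lambda: ph.simulate_scan(
        spec, cfg.protocol, cfg.view_poses, seed=cfg.seed, render=render,
        image_shape_px=cfg.image_shape_px, pixel_spacing_mm=cfg.pixel_spacing_mm,
        position_noise_mm=cfg.position_noise_mm))
    segmented = stage("segment", lambda: _segment_records(cfg, spec, scan))
    viewset, _diag = stage("register-fit", lambda: fit_view_poses(
        segmented, cfg.protocol.base_view_angle_deg, cfg.shared_label,
        n_calibration=cfg.n_calibration,
        min_calibration_area_mm2=cfg.min_calibration_area_mm2))

    def _place():
        placed = {a: apply_view_pose(recs, viewset) for a, recs in segmented.items()}
        fused: Dict[int, List[Contour2D]] = {}
        for k in range(cfg.protocol.n_steps):
            at_step = [recs[k] for recs in placed.values() if len(recs) > k]
            fused[k] = fuse_views(at_step, cfg.assignment)
        return fused

    fused_by_step = stage("register-apply", _place)

    def _stacks():
        return [build_stack(label, fused_by_step, cfg.protocol,
                            min_csa_mm2=cfg.min_csa_mm2)
                for label in sorted(cfg.assignment)]

    stacks = stage("stack", _stacks)
    refs = {p.label: spec.declared_volume(p.label) for p in spec.parts}
    reports, group = stage("reconstruct", lambda: structure_report(
        stacks, references=refs, n_ring=cfg.n_ring))
    verification = stage("verify", lambda: verify_phantom(
        reports, spec.declared_table()))
    report_obj = _report_obj(cfg, reports, group)

    if outdir is not None:
        stage("write", lambda: _write_artifacts(
            cfg, outdir, spec, scan, segmented, viewset, stacks, reports,
            report_obj, verification))
    return PipelineResult(cfg, spec, scan, segmented, viewset, fused_by_step,
                          reports, group, verification, report_obj, outdir)


def _write_artifacts(cfg, outdir, spec, scan, segmented, viewset, stacks,
                     reports, report_obj, verification):
    from .reconstruction import loft_mesh
    spec.save(outdir / "phantom.json")
    scan.trajectory.to_csv(outdir / "trajectory.csv", index=False,
                           float_format="%.6f")
    contour_records = []
    for angle in sorted(segmented):
        for r in segmented[angle]:
            for c in r.contours:
                contour_records.append(
                    ContourRecord(c, r.view_angle_deg, r.step_index,
                                  r.pixel_spacing_mm))
    export_contours(outdir / "contours.json", contour_records)
    viewset.save(outdir / "viewset.json")
    for rep in reports:
        rep.profile.to_csv(outdir / f"profile_{rep.label}.csv", index=False,
                           float_format="%.6f")
    verification.to_csv(outdir / "verification.csv", index=False,
                        float_format="%.6f")
    write_report(outdir / "report.json", report_obj)
    meta = {"seed": cfg.seed, "config_sha256": cfg.config_hash(),
            "config": cfg.to_json_obj()}
    (outdir / "run_meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    if cfg.write_images:
        from PIL import Image
        imgdir = outdir / "images"
        imgdir.mkdir(exist_ok=True)
        for angle, recs in sorted(scan.records_by_view.items()):
            for r in recs:
                if r.image is not None:
                    Image.fromarray(r.image.pixels).save(
                        imgdir / f"view{angle:g}_step{r.step_index:03d}.png")
    if cfg.write_stl_files:
        for stack in stacks:
            mesh = loft_mesh(stack, n_ring=cfg.n_ring)
            write_stl(mesh, outdir / f"{stack.label}.stl")
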