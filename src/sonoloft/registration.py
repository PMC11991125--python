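"""Multi-view rigid registration of slice contours.

Each non-base probe view is related to the base view by one fixed rigid
pose (rotation angle + the base-frame position of the image's
characteristic corner).  The pose is estimated by registering the contour
of a structure shared between the two views in a handful of calibration
sections, then averaging: anchors arithmetically, angles circularly.
The same pose is then applied to every slice of that view.

Scaling is never estimated — slice images are assumed pre-scaled to
millimetres.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .geometry import Contour2D, RigidPose2, resample_contour, transform_contour
from .segmentation import SliceRecord

logger = logging.getLogger(__name__)


class RegistrationError(RuntimeError):
    def __init__(self, msg: str, residual: Optional[float] = None):
        super().__init__(msg)
        self.residual = residual


@dataclasses.dataclass(frozen=True)
class RegistrationResult:
    pose: RigidPose2
    rms_residual: float
    n_correspondences: int

    def __post_init__(self):
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be >= 0")


@dataclasses.dataclass
class ICPConfig:
    """Iterative-closest-point settings.

    The metric is point-to-nearest-boundary-point on the fixed contour
    (a point-to-segment distance, since the boundary is a polyline).
    Initialization translates the moving centroid onto the fixed one and
    scans a coarse rotation grid capped at ``max_abs_theta_deg``; near-ties
    (within ``tie_rel_tol`` relative residual) break toward the smallest
    rotation magnitude, so near-symmetric cross-sections resolve to the
    same branch in every calibration section.
    """

    max_iter: int = 100
    tol_mm: float = 1e-6
    reject_factor: float = 3.0        # drop correspondences beyond k x median
    n_samples: int = 128              # moving-contour resampling density
    coarse_step_deg: float = 15.0
    max_abs_theta_deg: float = 90.0
    tie_rel_tol: float = 0.10


def _rigid_fit(src: np.ndarray, dst: np.ndarray) -> Tuple[float, np.ndarray]:
    """Least-squares rotation angle (radians) and translation mapping src->dst."""
    ms, md = src.mean(axis=0), dst.mean(axis=0)
    s, d = src - ms, dst - md
    num = float(np.sum(s[:, 0] * d[:, 1] - s[:, 1] * d[:, 0]))
    den = float(np.sum(s * d))
    theta = math.atan2(num, den)
    c, sn = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -sn], [sn, c]])
    t = md - rot @ ms
    return theta, t


def _project_on_polygon(pts: np.ndarray, poly: np.ndarray):
    """Nearest point on the closed polyline for each query point.

    Returns (projections, outward segment normals, distances); the
    point-to-segment distance is the ICP metric.
    """
    a = poly
    d = np.roll(poly, -1, axis=0) - poly          # (S, 2) segment vectors
    len2 = np.maximum((d**2).sum(axis=1), 1e-300)
    w = pts[:, None, :] - a[None, :, :]           # (M, S, 2)
    t = np.clip((w * d[None]).sum(axis=2) / len2[None], 0.0, 1.0)
    proj = a[None] + t[:, :, None] * d[None]      # (M, S, 2)
    diff = pts[:, None, :] - proj
    dist2 = (diff**2).sum(axis=2)
    idx = np.argmin(dist2, axis=1)
    m = np.arange(len(pts))
    best = proj[m, idx]
    seg = d[idx]
    normals = np.column_stack([seg[:, 1], -seg[:, 0]])
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = normals / np.maximum(norm, 1e-300)
    return best, normals, np.sqrt(dist2[m, idx])


def _find(contours: Iterable[Contour2D], label: str) -> Contour2D:
    for c in contours:
        if c.label == label:
            return c
    raise RegistrationError(f"no contour labeled {label!r}")


def register_slice_pair(
    moving: Sequence[Contour2D],
    fixed: Sequence[Contour2D],
    shared_label: str,
    cfg: Optional[ICPConfig] = None,
) -> RegistrationResult:
    """Rigidly register the shared-structure contour of one section pair.

    Returns the pose of the moving image in the fixed (base) frame: the
    rotation angle and the position the moving image's origin maps to
    (the characteristic-point coordinate).
    """
    cfg = cfg or ICPConfig()
    mov = _find(moving, shared_label)
    fix = _find(fixed, shared_label)
    mpts = resample_contour(mov, cfg.n_samples).points
    fpts = fix.points

    # --- coarse initialization: centroid shift + rotation grid ------------
    mc = mpts.mean(axis=0)
    fc = np.asarray(fix.centroid)
    thetas = np.arange(
        -cfg.max_abs_theta_deg, cfg.max_abs_theta_deg + 1e-9, cfg.coarse_step_deg
    )
    cand = []
    for th in thetas:
        r = math.radians(th)
        rot = np.array([[math.cos(r), -math.sin(r)], [math.sin(r), math.cos(r)]])
        moved = (mpts - mc) @ rot.T + fc
        _, _, d = _project_on_polygon(moved, fpts)
        cand.append((float(np.sqrt(np.mean(d**2))), th, rot))
    best_rms = min(c[0] for c in cand)
    # among near-ties, prefer the smallest rotation magnitude
    rms0, th0, rot0 = min(
        (c for c in cand if c[0] <= best_rms * (1 + cfg.tie_rel_tol) + 1e-12),
        key=lambda c: abs(c[1]),
    )
    cur_rot = rot0
    cur_t = fc - rot0 @ mc

    # --- refinement: point-to-line Gauss-Newton ICP ------------------------
    # minimizing the normal-projected residual instead of the full
    # point-to-point distance removes the slow tangential-sliding tail;
    # near the noise floor the correspondence set can limit-cycle, so the
    # loop keeps the best transform seen and stops once the best residual
    # stalls for a few iterations
    jrot = np.array([[0.0, -1.0], [1.0, 0.0]])
    best = None  # (rms, rot, t, n_keep)
    stall = 0
    converged = False
    rms = rms0
    for _ in range(cfg.max_iter):
        moved = mpts @ cur_rot.T + cur_t
        corr, normals, d = _project_on_polygon(moved, fpts)
        med = float(np.median(d))
        keep = d <= max(cfg.reject_factor * med, 1e-12)
        if keep.sum() < 3:
            keep = np.ones(len(d), dtype=bool)
        rms = float(np.sqrt(np.mean(d[keep] ** 2)))
        if best is None or rms < best[0] - (cfg.tol_mm + 1e-4 * rms):
            best = (rms, cur_rot, cur_t, int(keep.sum()))
            stall = 0
        else:
            stall += 1
            if stall >= 5:
                converged = True
                break
        q, n, c = moved[keep], normals[keep], corr[keep]
        a_col = (n * (q @ jrot.T)).sum(axis=1)
        amat = np.column_stack([a_col, n[:, 0], n[:, 1]])
        rhs = -(n * (q - c)).sum(axis=1)
        try:
            upd, *_ = np.linalg.lstsq(amat, rhs, rcond=None)
        except np.linalg.LinAlgError:  # pragma: no cover
            break
        dth, dx, dy = upd
        cdt, sdt = math.cos(dth), math.sin(dth)
        drot = np.array([[cdt, -sdt], [sdt, cdt]])
        cur_rot = drot @ cur_rot
        cur_t = drot @ cur_t + np.array([dx, dy])
    if not converged:
        raise RegistrationError(
            f"ICP did not converge in {cfg.max_iter} iterations "
            f"(last rms {rms:.6g} mm)",
            residual=rms,
        )
    rms, cur_rot, cur_t, n_keep = best
    theta_deg = math.degrees(math.atan2(cur_rot[1, 0], cur_rot[0, 0]))
    pose = RigidPose2(theta_deg, (float(cur_t[0]), float(cur_t[1])))
    return RegistrationResult(pose=pose, rms_residual=rms, n_correspondences=n_keep)


def estimate_view_pose(results: Sequence[RegistrationResult]) -> RigidPose2:
    """Average per-section registrations into one fixed view pose.

    Anchor coordinates are averaged arithmetically; rotation angles are
    averaged circularly (resultant vector), so angles wrapping around
    +/-180 degrees combine correctly.
    """
    if not results:
        raise RegistrationError("no registration results to average")
    anchors = np.array([r.pose.anchor for r in results], dtype=float)
    th = np.radians([r.pose.theta_deg for r in results])
    theta = math.degrees(math.atan2(np.sin(th).mean(), np.cos(th).mean()))
    ax, ay = anchors.mean(axis=0)
    return RigidPose2(theta, (float(ax), float(ay)))


# ---------------------------------------------------------------------------
# View sets
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ViewSet:
    """Fixed rigid pose of every probe view in the base-view frame."""

    base_view_angle_deg: float
    poses: Dict[float, RigidPose2]

    def __post_init__(self):
        self.poses = {float(k): v for k, v in self.poses.items()}
        base = float(self.base_view_angle_deg)
        if base not in self.poses:
            self.poses[base] = RigidPose2.identity()
        if not self.poses[base].is_identity:
            raise ValueError("base view pose must be the identity")

    @property
    def view_angles_deg(self) -> List[float]:
        return sorted(self.poses)

    def to_json_obj(self) -> dict:
        return {
            "base_view_angle_deg": float(self.base_view_angle_deg),
            "views": [
                {
                    "view_angle_deg": a,
                    "theta_deg": p.theta_deg,
                    "anchor_mm": [p.anchor[0], p.anchor[1]],
                }
                for a, p in sorted(self.poses.items())
            ],
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json_obj(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "ViewSet":
        obj = json.loads(Path(path).read_text())
        poses = {
            float(v["view_angle_deg"]): RigidPose2(v["theta_deg"], tuple(v["anchor_mm"]))
            for v in obj["views"]
        }
        return cls(obj["base_view_angle_deg"], poses)


def select_calibration_steps(available: Sequence[int], n: int = 5) -> List[int]:
    """Evenly spaced, non-adjacent step indices for pose calibration."""
    avail = sorted(set(available))
    if not avail:
        raise RegistrationError("no calibration sections available")
    if len(avail) <= n:
        return avail
    idx = np.unique(np.round(np.linspace(0, len(avail) - 1, n)).astype(int))
    return [avail[i] for i in idx]


def fit_view_poses(
    records_by_view: Dict[float, List[SliceRecord]],
    base_view_angle_deg: float,
    shared_label: str,
    n_calibration: int = 5,
    min_calibration_area_mm2: float = 25.0,
    icp: Optional[ICPConfig] = None,
) -> Tuple[ViewSet, Dict[float, List[RegistrationResult]]]:
    """Estimate every non-base view's pose from calibration sections.

    Calibration sections are steps where the shared structure is present in
    both views with enough area to register reliably; ``n_calibration``
    evenly spaced ones are used (default 5, non-adjacent when possible).
    """
    base = float(base_view_angle_deg)
    if base not in records_by_view:
        raise RegistrationError(f"base view {base} not among records")
    base_by_step = {r.step_index: r for r in records_by_view[base]}
    poses: Dict[float, RigidPose2] = {base: RigidPose2.identity()}
    diagnostics: Dict[float, List[RegistrationResult]] = {}
    for angle, recs in sorted(records_by_view.items()):
        if float(angle) == base:
            continue
        candidates = []
        for r in recs:
            b = base_by_step.get(r.step_index)
            if b is None:
                continue
            mov = next((c for c in r.contours if c.label == shared_label), None)
            fix = next((c for c in b.contours if c.label == shared_label), None)
            if mov is None or fix is None:
                continue
            if min(mov.area, fix.area) < min_calibration_area_mm2:
                continue
            candidates.append(r.step_index)
        steps = select_calibration_steps(candidates, n_calibration)
        results = []
        for k in steps:
            mov_rec = next(r for r in recs if r.step_index == k)
            results.append(
                register_slice_pair(mov_rec.contours, base_by_step[k].contours,
                                    shared_label, icp)
            )
        poses[float(angle)] = estimate_view_pose(results)
        diagnostics[float(angle)] = results
    return ViewSet(base, poses), diagnostics


def apply_view_pose(slices: Sequence[SliceRecord], vs: ViewSet) -> List[SliceRecord]:
    """Place every slice's contours in the base frame with its view's pose."""
    out: List[SliceRecord] = []
    for rec in slices:
        angle = float(rec.view_angle_deg)
        if angle not in vs.poses:
            raise RegistrationError(f"no pose for view angle {angle}")
        pose = vs.poses[angle]
        if pose.is_identity:
            contours = [
                c if c.frame == "base" else c.with_points(c.points, frame="base")
                for c in rec.contours
            ]
        else:
            contours = [transform_contour(c, pose) for c in rec.contours]
        out.append(
            SliceRecord(rec.view_angle_deg, rec.step_index, rec.z_mm, contours,
                        rec.image, rec.pixel_spacing_mm)
        )
    return out


def fuse_views(
    slices_at_step: Sequence[SliceRecord],
    assignment: Dict[str, float],
) -> List[Contour2D]:
    """Per-step fusion: each structure comes only from its designated view.

    Views are chosen so that each structure appears entire in exactly one
    view; partial duplicates seen from other views exist only to drive
    registration and are discarded here.  A structure present in no view at
    this step is omitted with a warning.
    """
    by_view = {float(r.view_angle_deg): r for r in slices_at_step}
    fused: List[Contour2D] = []
    for label in sorted(assignment):
        view = float(assignment[label])
        rec = by_view.get(view)
        contour = None
        if rec is not None:
            contour = next((c for c in rec.contours if c.label == label), None)
        if contour is None:
            logger.warning("structure %r absent at step %s", label,
                           slices_at_step[0].step_index if slices_at_step else "?")
            continue
        if contour.frame != "base":
            raise RegistrationError(
                f"fuse_views expects base-frame contours (got {contour.frame!r})"
            )
        fused.append(contour)
    return fused
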