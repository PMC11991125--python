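"""Per-slice containers and labeled-contour acquisition.

Contours enter the pipeline either by import of expert-drawn boundaries
(JSON, the clinical mode) or by automatic extraction from synthetic B-mode
renderings of a phantom, where the tissue classes are separable by
intensity.  Automatic extraction is only validated on synthetic data; it is
not a clinical segmenter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import shapely
from scipy import ndimage
from skimage import measure, morphology

from .geometry import Contour2D, InvalidContourError

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Contour/report file does not match the expected schema."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SliceImage:
    """One grayscale B-mode slice with its acquisition metadata."""

    pixels: np.ndarray            # (H, W) uint8
    pixel_spacing_mm: float       # isotropic mm per pixel
    view_angle_deg: float         # probe angle label
    step_index: int

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("SliceImage.pixels must be 2-D")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.step_index < 0:
            raise ValueError("step_index must be >= 0")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclasses.dataclass
class SliceRecord:
    """One acquisition: a probe view at one step, with its contours."""

    view_angle_deg: float
    step_index: int
    z_mm: float
    contours: List[Contour2D]
    image: Optional[SliceImage] = None
    pixel_spacing_mm: float = 0.2


# ---------------------------------------------------------------------------
# Contour JSON schema (shared repo-wide)
# ---------------------------------------------------------------------------
#
# {"label": str, "view_angle_deg": float, "step_index": int,
#  "frame": "image"|"base", "pixel_spacing_mm": float,
#  "points_mm": [[x, y], ...]}
#
# A record may instead carry "points_px" (+ "image_height_px"), in which case
# pixel coordinates are converted to mm (y flipped to upward) on import.

@dataclasses.dataclass
class ContourRecord:
    contour: Contour2D
    view_angle_deg: float
    step_index: int
    pixel_spacing_mm: float

    def to_json_obj(self) -> dict:
        return {
            "label": self.contour.label,
            "view_angle_deg": float(self.view_angle_deg),
            "step_index": int(self.step_index),
            "frame": self.contour.frame,
            "pixel_spacing_mm": float(self.pixel_spacing_mm),
            "points_mm": np.asarray(self.contour.points).tolist(),
        }


def _record_from_obj(obj: dict, idx: int) -> ContourRecord:
    where = f"record {idx}"
    for key in ("label", "view_angle_deg", "step_index", "frame", "pixel_spacing_mm"):
        if key not in obj:
            raise SchemaError(f"{where}: missing field {key!r}")
    frame = obj["frame"]
    if frame not in ("image", "base"):
        raise SchemaError(f"{where}: unknown frame {frame!r}")
    spacing = float(obj["pixel_spacing_mm"])
    if "points_mm" in obj:
        pts = np.asarray(obj["points_mm"], dtype=float)
    elif "points_px" in obj:
        if "image_height_px" not in obj:
            raise SchemaError(f"{where}: points_px requires image_height_px")
        px = np.asarray(obj["points_px"], dtype=float)
        if px.ndim != 2 or px.shape[1] != 2:
            raise SchemaError(f"{where}: points_px must be (N, 2)")
        h = float(obj["image_height_px"])
        # pixel (col, row), y-down -> mm, y-up
        pts = np.column_stack([px[:, 0] * spacing, (h - 1.0 - px[:, 1]) * spacing])
    else:
        raise SchemaError(f"{where}: needs points_mm or points_px")
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise SchemaError(f"{where} ({obj['label']!r}): needs >=3 [x, y] points")
    try:
        contour = Contour2D(str(obj["label"]), pts, frame)
    except InvalidContourError as exc:
        raise SchemaError(f"{where} ({obj['label']!r}): {exc}") from exc
    return ContourRecord(contour, float(obj["view_angle_deg"]), int(obj["step_index"]), spacing)


def import_contours(path) -> List[ContourRecord]:
    """Read labeled contours from a JSON file (schema above).

    Malformed records raise :class:`SchemaError` naming the offending record.
    An empty contour list is returned as-is, with a warning.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: malformed JSON: {exc}") from exc
    if isinstance(data, dict):
        data = data.get("contours")
    if not isinstance(data, list):
        raise SchemaError(f"{path}: expected a list of contour records")
    if not data:
        logger.warning("%s: empty contour list", path)
        return []
    return [_record_from_obj(obj, i) for i, obj in enumerate(data)]


def export_contours(path, records: Sequence[ContourRecord]) -> None:
    """Write contour records to JSON (lossless round-trip with import)."""
    objs = [r.to_json_obj() for r in records]
    Path(path).write_text(json.dumps(objs, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Automatic extraction from synthetic B-mode images
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ClassConfig:
    """Extraction parameters for one tissue/echo class.

    ``band`` is the accepted intensity interval on the speckle-smoothed
    image.  ``grow_mm`` offsets the traced outline outward (shapely buffer)
    to undo the known inward bias of banded thresholding: thresholding a
    blurred edge lands slightly inside the true boundary, and structures
    rendered with a hyperechoic internal rim additionally lose the rim
    width, since only their dark interior falls in the band.
    """

    band: Tuple[float, float]
    min_area_mm2: float = 5.0
    open_radius_px: int = 3
    close_radius_px: int = 2
    grow_mm: float = 0.0


@dataclasses.dataclass
class SegmentationConfig:
    classes: Dict[str, ClassConfig]
    smooth_sigma_px: float = 1.5
    approx_tol_px: float = 0.8


# Intensity bands sit near the midpoints between the renderer's class
# levels (anechoic 5, hypoechoic 55, speckle_mid 120, hyperechoic 210; see
# phantom.ECHO_LEVELS), with the hyperechoic floor lowered to allow for the
# clipping-induced mean shift of the brightest class.
DEFAULT_BANDS: Dict[str, Tuple[float, float]] = {
    "anechoic": (0.0, 30.0),
    "hypoechoic": (30.0, 88.0),
    "speckle_mid": (88.0, 160.0),
    "hyperechoic": (150.0, 255.0),
}

# Outward boundary compensation at the default 0.2 mm/px rendering:
# ~0.1 mm threshold shift for a blurred edge, plus the 2 px (0.4 mm)
# internal rim for bordered structures.
DEFAULT_GROW_MM: Dict[str, float] = {
    "anechoic": 0.0,
    "hypoechoic": 0.2,
    "speckle_mid": 0.2,
    "hyperechoic": 0.15,
}
BORDERED_GROW_MM = 0.5


def default_class_config(echo_class: str, bordered: bool = False) -> ClassConfig:
    """Default extraction settings for one echo class (0.2 mm/px rendering)."""
    band = DEFAULT_BANDS[echo_class]
    grow = BORDERED_GROW_MM if bordered else DEFAULT_GROW_MM[echo_class]
    open_r = 2 if echo_class == "hyperechoic" else 3
    return ClassConfig(band=band, grow_mm=grow, open_radius_px=open_r)


def _trace_component(mask: np.ndarray, spacing: float, tol_px: float) -> Optional[np.ndarray]:
    """Outer boundary of a binary component as (N, 2) mm coordinates (y-up)."""
    padded = np.pad(mask, 1)
    contours = measure.find_contours(padded.astype(float), 0.5)
    if not contours:
        return None
    coords = max(contours, key=len) - 1.0  # unpad; (row, col), subpixel
    if tol_px > 0:
        coords = measure.approximate_polygon(coords, tolerance=tol_px)
    if np.allclose(coords[0], coords[-1]):
        coords = coords[:-1]
    if len(coords) < 3:
        return None
    h = mask.shape[0]
    pts = np.column_stack([coords[:, 1] * spacing, (h - 1.0 - coords[:, 0]) * spacing])
    poly = shapely.Polygon(pts)
    if not poly.is_valid:
        # tracing artifacts (pixel-level pinches) are repaired before the
        # contour is built; imported contours are never repaired this way
        poly = poly.buffer(0)
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
        if poly.is_empty:
            return None
        pts = np.asarray(poly.exterior.coords)[:-1]
    return pts


def extract_layer_contours(img: SliceImage, cfg: SegmentationConfig) -> List[Contour2D]:
    """Extract one outer contour per connected component of each echo class.

    Pipeline: Gaussian speckle smoothing -> per-class intensity banding ->
    morphological opening/closing -> hole filling -> 8-connected component
    labeling -> small-component rejection -> optional dilation (border
    compensation) -> outer-boundary tracing to an mm-frame polygon.

    Only the outer boundary of each component is kept (no holes).  A class
    with no component above its minimum area yields no contours (not an
    error).  Deterministic for a fixed image and configuration.
    """
    if img.pixels.size == 0:
        raise ValueError("empty image")
    spacing = img.pixel_spacing_mm
    smoothed = ndimage.gaussian_filter(img.pixels.astype(float), cfg.smooth_sigma_px)
    out: List[Contour2D] = []
    min_px_area_scale = spacing * spacing
    for label in sorted(cfg.classes):
        c = cfg.classes[label]
        lo, hi = c.band
        mask = (smoothed >= lo) & (smoothed <= hi)
        if c.open_radius_px > 0:
            mask = morphology.opening(mask, morphology.disk(c.open_radius_px))
        if c.close_radius_px > 0:
            mask = morphology.closing(mask, morphology.disk(c.close_radius_px))
        mask = ndimage.binary_fill_holes(mask)
        labeled, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        for comp_id in range(1, n + 1):
            comp = labeled == comp_id
            if comp.sum() * min_px_area_scale < c.min_area_mm2:
                continue
            pts = _trace_component(comp, spacing, cfg.approx_tol_px)
            if pts is None:
                continue
            if c.grow_mm != 0.0:
                grown = shapely.Polygon(pts).buffer(c.grow_mm, quad_segs=4)
                if grown.is_empty:
                    continue
                if grown.geom_type == "MultiPolygon":
                    grown = max(grown.geoms, key=lambda g: g.area)
                pts = np.asarray(grown.exterior.coords)[:-1]
            try:
                out.append(Contour2D(label, pts, frame="image"))
            except InvalidContourError:
                logger.warning("dropping untraceable %s component in view %s step %d",
                               label, img.view_angle_deg, img.step_index)
    return out


def smooth_contour(c: Contour2D, window: int) -> Contour2D:
    """Circular moving average of vertex coordinates (window must be odd).

    ``window=1`` is the identity.  Small windows round pixel-level jitter
    while changing enclosed area by well under a percent on dense contours.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window == 1:
        return c
    pts = c.points
    k = window // 2
    idx = np.arange(-k, k + 1)
    acc = np.zeros_like(pts)
    for off in idx:
        acc += np.roll(pts, off, axis=0)
    return c.with_points(acc / window)


# ---------------------------------------------------------------------------
# Region rasterization (shared by tests and verification)
# ---------------------------------------------------------------------------

def rasterize_region(c: Contour2D, shape_px: Tuple[int, int], pixel_spacing_mm: float) -> np.ndarray:
    """Boolean mask of the contour's enclosed region on an image grid (y-up)."""
    h = shape_px[0]
    rows = h - 1.0 - c.points[:, 1] / pixel_spacing_mm
    cols = c.points[:, 0] / pixel_spacing_mm
    from skimage.draw import polygon2mask
    return polygon2mask(shape_px, np.column_stack([rows, cols]))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(a, b).sum()) / float(denom)
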