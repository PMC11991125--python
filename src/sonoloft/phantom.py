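"""Synthetic tissue-mimicking phantoms and scan simulation.

Two phantom families with closed-form geometry serve as ground truth for
the whole pipeline:

* a layered slab phantom — rectangular plates mimicking skin (hyperechoic),
  subcutaneous fat (mid-level speckle, as with a graphite admixture) and
  muscle (hypoechoic with a hyperechoic fascia-like rim), stacked 1-2 mm
  apart;
* an analytic muscle spindle — an elliptical cross-section whose semi-axes
  follow piecewise-polynomial profiles along the scan axis, with volume and
  center of gravity integrable exactly.

The scan simulator emulates the robotic protocol: for each probe view and
each 5 mm step it produces the exact cross-section contours (expressed in
that view's image frame via the inverse of the view's true pose) and,
optionally, a speckled B-mode-like rendering, together with a per-step
trajectory and probe-force log.  Probe pressure does not deform the
phantom; force is logged metadata only.  All randomness flows from a single
seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from skimage import morphology
from skimage.draw import polygon2mask

from .geometry import Contour2D, RigidPose2
from .reconstruction import ScanProtocol
from .segmentation import SliceImage, SliceRecord


class PhantomError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Semi-axis profiles
# ---------------------------------------------------------------------------

class Profile:
    """Piecewise-polynomial radius profile r(s) on [0, L], millimetres.

    Supports exact integration of products of two profiles (optionally
    weighted by powers of s), which is what closed-form spindle volumes and
    centers of gravity require.
    """

    def __init__(self, breaks: Sequence[float], polys: Sequence[Polynomial]):
        self.breaks = np.asarray(breaks, dtype=float)
        if len(self.breaks) != len(polys) + 1 or np.any(np.diff(self.breaks) <= 0):
            raise PhantomError("breaks must be increasing and bracket each piece")
        self.polys = [Polynomial(np.asarray(p.coef, dtype=float)) for p in polys]
        self._validate_nonnegative()

    @property
    def length(self) -> float:
        return float(self.breaks[-1] - self.breaks[0])

    def _validate_nonnegative(self):
        s = np.linspace(self.breaks[0], self.breaks[-1], 2001)
        v = self(s)
        if np.any(v < -1e-9):
            raise PhantomError("profile must be non-negative on its support")
        if np.all(v[1:-1] <= 1e-12):
            raise PhantomError("profile must be positive in the interior")

    # -- constructors -------------------------------------------------------
    @classmethod
    def constant(cls, value: float, length: float) -> "Profile":
        return cls([0.0, length], [Polynomial([value])])

    @classmethod
    def linear(cls, v0: float, v1: float, length: float) -> "Profile":
        return cls([0.0, length], [Polynomial([v0, (v1 - v0) / length])])

    @classmethod
    def quadratic(cls, v0: float, vmid: float, v1: float, length: float) -> "Profile":
        """Quadratic through (0, v0), (L/2, vmid), (L, v1)."""
        L = float(length)
        c = v0
        a = 2.0 * (v0 + v1 - 2.0 * vmid) / (L * L)
        b = (v1 - v0) / L - a * L
        return cls([0.0, L], [Polynomial([c, b, a])])

    @classmethod
    def piecewise_linear(cls, s_points: Sequence[float], values: Sequence[float]) -> "Profile":
        s = np.asarray(s_points, dtype=float)
        v = np.asarray(values, dtype=float)
        polys = []
        for i in range(len(s) - 1):
            ds = s[i + 1] - s[i]
            polys.append(Polynomial([v[i], (v[i + 1] - v[i]) / ds]))
        return cls(s, polys)

    # -- evaluation ---------------------------------------------------------
    def __call__(self, s):
        s = np.asarray(s, dtype=float)
        out = np.zeros_like(s)
        idx = np.clip(np.searchsorted(self.breaks, s, side="right") - 1, 0,
                      len(self.polys) - 1)
        for i, p in enumerate(self.polys):
            m = idx == i
            if np.any(m):
                out[m] = p(s[m] - self.breaks[i])
        return out if out.ndim else float(out)

    def max_value(self) -> float:
        s = np.linspace(self.breaks[0], self.breaks[-1], 2001)
        return float(np.max(self(s)))

    def _piece_on(self, u0: float, i: int) -> Polynomial:
        """This profile's polynomial re-expressed in u = s - u0."""
        delta = u0 - self.breaks[i]
        return self.polys[i](Polynomial([delta, 1.0]))

    def integral_product(self, other: "Profile", weight_power: int = 0) -> float:
        """Exact integral of s^w * self(s) * other(s) over the common support."""
        breaks = np.unique(np.concatenate([self.breaks, other.breaks]))
        total = 0.0
        for u0, u1 in zip(breaks[:-1], breaks[1:]):
            i = min(np.searchsorted(self.breaks, u0, side="right") - 1, len(self.polys) - 1)
            j = min(np.searchsorted(other.breaks, u0, side="right") - 1, len(other.polys) - 1)
            q = self._piece_on(u0, i) * other._piece_on(u0, j)
            if weight_power:
                q = q * Polynomial([u0, 1.0]) ** weight_power
            anti = q.integ()
            total += float(anti(u1 - u0) - anti(0.0))
        return total

    # -- serialization ------------------------------------------------------
    def to_json_obj(self) -> dict:
        return {
            "breaks": self.breaks.tolist(),
            "coeffs": [p.coef.tolist() for p in self.polys],
        }

    @classmethod
    def from_json_obj(cls, obj: dict) -> "Profile":
        return cls(obj["breaks"], [Polynomial(c) for c in obj["coeffs"]])


# ---------------------------------------------------------------------------
# Phantom parts
# ---------------------------------------------------------------------------

ECHO_CLASSES = ("hyperechoic", "speckle_mid", "hypoechoic", "anechoic")


@dataclasses.dataclass
class BoxPart:
    """Rectangular plate: width (x) x height (y) x length (scan axis)."""

    label: str
    width_mm: float
    height_mm: float
    length_mm: float
    offset: Tuple[float, float, float]  # (x0, y0, axial0)
    echo_class: str = "speckle_mid"
    border_class: str = "none"
    render_gain: float = 1.0

    def __post_init__(self):
        if min(self.width_mm, self.height_mm, self.length_mm) <= 0:
            raise PhantomError(f"{self.label}: box dimensions must be positive")
        if self.echo_class not in ECHO_CLASSES:
            raise PhantomError(f"{self.label}: unknown echo class {self.echo_class!r}")

    @property
    def declared_volume_mm3(self) -> float:
        return self.width_mm * self.height_mm * self.length_mm

    def declared_cog(self) -> Tuple[float, float, float]:
        x0, y0, s0 = self.offset
        return (x0 + self.width_mm / 2, y0 + self.height_mm / 2, s0 + self.length_mm / 2)

    def bbox(self) -> Tuple[float, float, float, float, float, float]:
        x0, y0, s0 = self.offset
        return (x0, x0 + self.width_mm, y0, y0 + self.height_mm, s0, s0 + self.length_mm)

    def cross_section(self, axial_mm: float) -> Optional[np.ndarray]:
        x0, y0, s0 = self.offset
        if not (s0 <= axial_mm <= s0 + self.length_mm):
            return None
        w, h = self.width_mm, self.height_mm
        return np.array([[x0, y0], [x0 + w, y0], [x0 + w, y0 + h], [x0, y0 + h]])


@dataclasses.dataclass
class SpindlePart:
    """Muscle-like solid: elliptical cross-section with semi-axes a(s), b(s)."""

    label: str
    a: Profile
    b: Profile
    center_xy: Tuple[float, float] = (0.0, 0.0)
    axial0: float = 0.0
    echo_class: str = "hypoechoic"
    border_class: str = "hyperechoic"
    render_gain: float = 1.0
    n_boundary: int = 256

    def __post_init__(self):
        if abs(self.a.length - self.b.length) > 1e-9:
            raise PhantomError(f"{self.label}: a and b profiles must share support")
        if self.echo_class not in ECHO_CLASSES:
            raise PhantomError(f"{self.label}: unknown echo class {self.echo_class!r}")

    @property
    def length_mm(self) -> float:
        return self.a.length

    @property
    def declared_volume_mm3(self) -> float:
        return math.pi * self.a.integral_product(self.b)

    def declared_cog(self) -> Tuple[float, float, float]:
        v = self.a.integral_product(self.b)
        s_bar = self.a.integral_product(self.b, weight_power=1) / v
        return (self.center_xy[0], self.center_xy[1], self.axial0 + s_bar)

    def bbox(self) -> Tuple[float, float, float, float, float, float]:
        cx, cy = self.center_xy
        amax, bmax = self.a.max_value(), self.b.max_value()
        return (cx - amax, cx + amax, cy - bmax, cy + bmax,
                self.axial0, self.axial0 + self.length_mm)

    def cross_section(self, axial_mm: float) -> Optional[np.ndarray]:
        s = axial_mm - self.axial0
        if not (0.0 <= s <= self.length_mm):
            return None
        a, b = float(self.a(s)), float(self.b(s))
        if a < 1e-3 or b < 1e-3:
            return None
        phi = 2 * np.pi * np.arange(self.n_boundary) / self.n_boundary
        cx, cy = self.center_xy
        return np.column_stack([cx + a * np.cos(phi), cy + b * np.sin(phi)])


Part = Union[BoxPart, SpindlePart]


@dataclasses.dataclass
class PhantomSpec:
    """Declared phantom geometry: the ground truth for verification."""

    name: str
    parts: List[Part]

    def __post_init__(self):
        labels = [p.label for p in self.parts]
        if len(set(labels)) != len(labels):
            raise PhantomError(f"duplicate part labels: {labels}")
        for i, p in enumerate(self.parts):
            for q in self.parts[i + 1:]:
                if _bbox_overlap(p.bbox(), q.bbox()):
                    raise PhantomError(f"parts {p.label!r} and {q.label!r} overlap")

    def part(self, label: str) -> Part:
        for p in self.parts:
            if p.label == label:
                return p
        raise KeyError(label)

    def declared_volume(self, label: str) -> float:
        return self.part(label).declared_volume_mm3

    def declared_cog(self, label: str, scan_axis_sign: int = -1) -> Tuple[float, float, float]:
        x, y, s = self.part(label).declared_cog()
        return (x, y, scan_axis_sign * s)

    def declared_table(self) -> Dict[str, dict]:
        """Per-label declared quantities in the form verify_phantom expects."""
        out: Dict[str, dict] = {}
        for p in self.parts:
            d = {"volume_mm3": p.declared_volume_mm3}
            if isinstance(p, BoxPart):
                d["box_dims_mm"] = (p.width_mm, p.height_mm, p.length_mm)
            out[p.label] = d
        return out

    def axial_extent(self) -> Tuple[float, float]:
        lo = min(p.bbox()[4] for p in self.parts)
        hi = max(p.bbox()[5] for p in self.parts)
        return lo, hi

    # -- serialization ------------------------------------------------------
    def to_json_obj(self) -> dict:
        parts = []
        for p in self.parts:
            if isinstance(p, BoxPart):
                parts.append({
                    "kind": "box", "label": p.label,
                    "width_mm": p.width_mm, "height_mm": p.height_mm,
                    "length_mm": p.length_mm, "offset": list(p.offset),
                    "echo_class": p.echo_class, "border_class": p.border_class,
                    "render_gain": p.render_gain,
                })
            else:
                parts.append({
                    "kind": "spindle", "label": p.label,
                    "a": p.a.to_json_obj(), "b": p.b.to_json_obj(),
                    "center_xy": list(p.center_xy), "axial0": p.axial0,
                    "echo_class": p.echo_class, "border_class": p.border_class,
                    "render_gain": p.render_gain,
                })
        return {"name": self.name, "parts": parts}

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json_obj(), indent=1, sort_keys=True))

    @classmethod
    def from_json_obj(cls, obj: dict) -> "PhantomSpec":
        parts: List[Part] = []
        for p in obj["parts"]:
            if p["kind"] == "box":
                parts.append(BoxPart(p["label"], p["width_mm"], p["height_mm"],
                                     p["length_mm"], tuple(p["offset"]),
                                     p["echo_class"], p["border_class"],
                                     p.get("render_gain", 1.0)))
            else:
                parts.append(SpindlePart(p["label"], Profile.from_json_obj(p["a"]),
                                         Profile.from_json_obj(p["b"]),
                                         tuple(p["center_xy"]), p["axial0"],
                                         p["echo_class"], p["border_class"],
                                         p.get("render_gain", 1.0)))
        return cls(obj["name"], parts)

    @classmethod
    def load(cls, path) -> "PhantomSpec":
        return cls.from_json_obj(json.loads(Path(path).read_text()))


def _bbox_overlap(a, b) -> bool:
    return (a[0] < b[1] and b[0] < a[1] and
            a[2] < b[3] and b[2] < a[3] and
            a[4] < b[5] and b[4] < a[5])


# ---------------------------------------------------------------------------
# Phantom factories
# ---------------------------------------------------------------------------

def make_layered_phantom(
    width_mm: float = 85.0,
    skin_mm: float = 1.5,
    fat_mm: float = 7.0,
    muscle_mm: float = 15.0,
    length_mm: float = 30.0,
    gap_mm: float = 1.5,
    x0_mm: float = 45.0,
    muscle_y0_mm: float = 40.0,
    axial0_mm: float = 0.0,
    skin_contrast_boost: bool = False,
) -> PhantomSpec:
    """Three stacked plates mimicking skin, subcutaneous fat and muscle.

    Skin sits on top, fat in the middle, muscle at the bottom, spaced
    ``gap_mm`` apart (1-2 mm is the physical arrangement being mimicked;
    zero or negative gaps are an error because the layers would touch).
    By default the skin plate renders faintly — its real counterpart was
    poorly visible — which ``skin_contrast_boost`` overrides.
    """
    if gap_mm <= 0:
        raise PhantomError("layers must not touch: gap_mm must be positive")
    muscle = BoxPart("muscle_layer", width_mm, muscle_mm, length_mm,
                     (x0_mm, muscle_y0_mm, axial0_mm),
                     echo_class="hypoechoic", border_class="hyperechoic")
    fat_y0 = muscle_y0_mm + muscle_mm + gap_mm
    fat = BoxPart("fat_layer", width_mm, fat_mm, length_mm,
                  (x0_mm, fat_y0, axial0_mm), echo_class="speckle_mid")
    skin_y0 = fat_y0 + fat_mm + gap_mm
    skin = BoxPart("skin_layer", width_mm, skin_mm, length_mm,
                   (x0_mm, skin_y0, axial0_mm), echo_class="hyperechoic",
                   render_gain=1.0 if skin_contrast_boost else 0.62)
    return PhantomSpec("layered_slab", [skin, fat, muscle])


def make_muscle_spindle(
    length_mm: float = 200.0,
    a_profile: Optional[Profile] = None,
    b_profile: Optional[Profile] = None,
    center_xy: Tuple[float, float] = (90.0, 80.0),
    axial0_mm: float = 0.0,
    label: str = "muscle",
) -> PhantomSpec:
    """Analytic muscle-like spindle phantom.

    Defaults: a 200 mm spindle with quadratic semi-axis profiles vanishing
    at the ends and peaking at 15 mm (x) by 10 mm (y) mid-belly — a
    forearm-extensor-sized solid with closed-form volume and COG.
    """
    a = a_profile or Profile.quadratic(0.0, 15.0, 0.0, length_mm)
    b = b_profile or Profile.quadratic(0.0, 10.0, 0.0, length_mm)
    spindle = SpindlePart(label, a, b, center_xy, axial0_mm)
    return PhantomSpec("muscle_spindle", [spindle])


# ---------------------------------------------------------------------------
# Cross-sections and rendering
# ---------------------------------------------------------------------------

def exact_cross_section(
    spec: PhantomSpec,
    axial_mm: float,
    view_pose: Optional[RigidPose2] = None,
) -> List[Contour2D]:
    """Analytic slice of every part at one axial position.

    Contours are returned in the querying view's image frame: the true view
    pose maps image to base coordinates, so its inverse is applied here.
    An empty list is returned where nothing intersects the plane.
    """
    inv = view_pose.inverse() if view_pose is not None and not view_pose.is_identity else None
    out: List[Contour2D] = []
    for p in spec.parts:
        pts = p.cross_section(axial_mm)
        if pts is None:
            continue
        if inv is not None:
            pts = inv.apply(pts)
        out.append(Contour2D(p.label, pts, frame="image"))
    return out


ECHO_LEVELS: Dict[str, float] = {
    "anechoic": 5.0,
    "hypoechoic": 55.0,
    "speckle_mid": 120.0,
    "hyperechoic": 210.0,
}
BORDER_PX = 2  # hyperechoic rim width drawn just inside a bordered outline


@dataclasses.dataclass
class RenderRegion:
    contour: Contour2D
    echo_class: str
    border_class: str = "none"
    gain: float = 1.0


def render_bmode(
    regions: Sequence[RenderRegion],
    shape_px: Tuple[int, int],
    pixel_spacing_mm: float,
    seed: Union[int, np.random.Generator] = 0,
    levels: Optional[Dict[str, float]] = None,
    speckle_contrast: float = 0.6,
) -> np.ndarray:
    """Render labeled regions as a speckled B-mode-like 8-bit image.

    Regions are rasterized at their class mean intensity (hyperechoic >
    speckle_mid > hypoechoic > anechoic background); bordered regions get a
    2 px hyperechoic rim just inside their outline.  Multiplicative
    partially-developed speckle is applied on top: each pixel is scaled by
    ``1 - w + w * R`` with ``R`` unit-mean Rayleigh and ``w`` the speckle
    contrast, preserving class means while keeping the classes separable
    on screen.  Deterministic for a fixed seed.
    """
    if pixel_spacing_mm <= 0:
        raise ValueError("pixel_spacing_mm must be positive")
    lv = levels or ECHO_LEVELS
    h = shape_px[0]
    base = np.full(shape_px, lv["anechoic"], dtype=float)
    for reg in regions:
        pts = reg.contour.points
        rows = h - 1.0 - pts[:, 1] / pixel_spacing_mm
        cols = pts[:, 0] / pixel_spacing_mm
        mask = polygon2mask(shape_px, np.column_stack([rows, cols]))
        base[mask] = lv[reg.echo_class] * reg.gain
        if reg.border_class == "hyperechoic":
            rim = mask & ~morphology.erosion(mask, morphology.disk(BORDER_PX))
            base[rim] = lv["hyperechoic"]
    rng = np.random.default_rng(seed)
    rayleigh = rng.rayleigh(scale=math.sqrt(2.0 / math.pi), size=shape_px)
    speckle = 1.0 - speckle_contrast + speckle_contrast * rayleigh
    return np.clip(base * speckle, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Scan simulation
# ---------------------------------------------------------------------------

# True poses used by the simulator for the default three-view protocol:
# the base view is the identity; the non-base views sit at small rotations
# with characteristic-corner anchors inside the base image.
DEFAULT_VIEW_POSES: Dict[float, RigidPose2] = {
    26.0: RigidPose2.identity(),
    45.0: RigidPose2(19.0, (26.899, 33.883)),
    354.0: RigidPose2(32.0, (91.57, 25.25)),
}

TRAJECTORY_COLUMNS = ["step_index", "x_mm", "y_mm", "z_mm",
                      "rx_deg", "ry_deg", "rz_deg", "force_N"]


@dataclasses.dataclass
class ScanResult:
    records_by_view: Dict[float, List[SliceRecord]]
    trajectory: pd.DataFrame


def simulate_scan(
    spec: PhantomSpec,
    protocol: ScanProtocol,
    view_poses: Optional[Dict[float, RigidPose2]] = None,
    seed: int = 0,
    render: bool = False,
    image_shape_px: Tuple[int, int] = (500, 550),
    pixel_spacing_mm: float = 0.2,
    position_noise_mm: float = 0.1,
    force_mean_n: float = 5.0,
    force_noise_n: float = 0.2,
) -> ScanResult:
    """Simulate the stepped multi-view scan of a phantom.

    For every view and step the exact cross-section contours are produced in
    that view's image frame (optionally rendered to a speckled B-mode
    image), and a trajectory row is logged: commanded coordinates plus
    seeded positioning noise (default sigma 0.1 mm, the robot's stated
    accuracy) and a probe force (constant plus noise at the force sensor's
    accuracy).  One record and one log row per view per step.
    """
    poses = dict(DEFAULT_VIEW_POSES) if view_poses is None else dict(view_poses)
    for angle in protocol.view_angles_deg:
        poses.setdefault(float(angle), RigidPose2.identity())
    records: Dict[float, List[SliceRecord]] = {}
    rows = []
    for vi, angle in enumerate(protocol.view_angles_deg):
        angle = float(angle)
        pose = poses[angle]
        recs: List[SliceRecord] = []
        for k in range(protocol.n_steps):
            s = protocol.step_mm * k
            contours = exact_cross_section(spec, s, pose)
            image = None
            if render:
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=seed, spawn_key=(vi, k))
                )
                regions = []
                for c in contours:
                    p = spec.part(c.label)
                    regions.append(RenderRegion(c, p.echo_class, p.border_class,
                                                p.render_gain))
                pixels = render_bmode(regions, image_shape_px, pixel_spacing_mm, rng)
                image = SliceImage(pixels, pixel_spacing_mm, angle, k)
            recs.append(SliceRecord(angle, k, protocol.z_of_step(k), contours,
                                    image, pixel_spacing_mm))
            rng_log = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(1000 + vi, k))
            )
            nx, ny, nz = (rng_log.normal(0.0, position_noise_mm, size=3)
                          if position_noise_mm > 0 else (0.0, 0.0, 0.0))
            force = force_mean_n + (rng_log.normal(0.0, force_noise_n)
                                    if force_noise_n > 0 else 0.0)
            rows.append((k, nx, ny, protocol.step_mm * k + nz, 0.0, 0.0, angle,
                         max(force, 0.0)))
        records[angle] = recs
    trajectory = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    return ScanResult(records, trajectory)
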