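import numpy as np
import pytest

from sonoloft.geometry import Contour2D


def star_polygon(rng: np.random.Generator, n: int = 12,
                 r_lo: float = 5.0, r_hi: float = 20.0,
                 center=(0.0, 0.0)) -> np.ndarray:
    """Random star-shaped (hence simple) polygon around a center."""
    phi = np.sort(rng.uniform(0, 2 * np.pi, n))
    # guard against coincident angles producing duplicate vertices
    while np.any(np.diff(phi) < 1e-3):
        phi = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = rng.uniform(r_lo, r_hi, n)
    return np.column_stack([center[0] + r * np.cos(phi),
                            center[1] + r * np.sin(phi)])


def bean_contour(n: int = 96, scale: float = 22.0,
                 center=(45.0, 40.0), label: str = "muscle") -> Contour2D:
    """Asymmetric muscle-like test contour (no rotational symmetry)."""
    phi = 2 * np.pi * np.arange(n) / n
    r = scale * (1 + 0.25 * np.cos(phi) + 0.15 * np.sin(2 * phi))
    pts = np.column_stack([center[0] + r * np.cos(phi),
                           center[1] + r * np.sin(phi)])
    return Contour2D(label, pts)


def ellipse_contour(a: float, b: float, center=(0.0, 0.0), n: int = 128,
                    label: str = "c", frame: str = "image") -> Contour2D:
    phi = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack([center[0] + a * np.cos(phi),
                           center[1] + b * np.sin(phi)])
    return Contour2D(label, pts, frame)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
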