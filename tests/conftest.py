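"""Shared fixtures: hand-constructed patches and small phantoms."""

import math

import numpy as np
import pytest

from pathocell import PhantomSpec, RGBPatch, generate_phantom

STROMA = (230, 160, 200)
NUCLEUS = (45, 35, 105)
WHITE = (255, 255, 255)


def solid_patch(color, size=32) -> RGBPatch:
    """Uniform-colour patch."""
    arr = np.empty((size, size, 3), dtype=np.uint8)
    arr[:] = color
    return RGBPatch(arr)


def draw_discs(centers, radius, size=128, bg=STROMA, fg=NUCLEUS) -> RGBPatch:
    """Stroma-coloured patch with nucleus-coloured discs painted on it."""
    arr = np.empty((size, size, 3), dtype=np.uint8)
    arr[:] = bg
    yy, xx = np.mgrid[0:size, 0:size]
    for cy, cx in centers:
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        arr[disc] = fg
    return RGBPatch(arr)


def draw_ellipse_mask(a, b, theta_deg, size=101) -> np.ndarray:
    """Rasterised ellipse (semi-axes a >= b, theta from the x axis)."""
    theta = math.radians(theta_deg)
    half = size // 2
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    xr = math.cos(theta) * xx + math.sin(theta) * yy
    yr = -math.sin(theta) * xx + math.cos(theta) * yy
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic 256 px phantom with both classes present."""
    return generate_phantom(
        PhantomSpec(size=256, seed=11, n_malignant=10, n_benign=25)
    )


@pytest.fixture(scope="session")
def three_color_patch() -> RGBPatch:
    """Patch of three solid blocks: pink stroma, blue nuclei, white background."""
    arr = np.empty((64, 64, 3), dtype=np.uint8)
    arr[:] = WHITE
    arr[:, :32] = STROMA  # left half pink
    arr[:32, 32:] = NUCLEUS  # top-right quarter blue
    return RGBPatch(arr)
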