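"""Colour separation of H&E patches.

An H&E patch is dominated by three colour families: eosin-pink stroma, the
hematoxylin-blue nuclei, and the near-white background (fat, lumen, glass).
This module converts a patch to HSV and splits it into those three component
images with K-means clustering on the HSV triples, and provides a configurable
pink filter that measures the stroma fraction of a patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.color import rgb2hsv
from sklearn.cluster import KMeans

from .errors import (
    ConfigurationError,
    DegenerateClusteringError,
    DimensionMismatchError,
)

#: hue (in [0,1]) that the eosin-pink cluster is expected to sit near;
#: pink lives at the red end of the hue circle, so distances are circular.
PINK_HUE = 0.95

_MIN_SIDE = 32


@dataclass
class RGBPatch:
    """One H&E image patch on an 8-bit RGB pixel grid.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` array of 8-bit intensities.
    pixel_size
        Physical pixel pitch in micrometres per pixel. The nominal
        acquisition scale is 20x magnification, ~0.5 um/px.
    """

    pixels: np.ndarray
    pixel_size: float = 0.5

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise DimensionMismatchError(
                f"expected an (H, W, 3) RGB array, got shape {arr.shape}"
            )
        if arr.shape[0] < _MIN_SIDE or arr.shape[1] < _MIN_SIDE:
            raise DimensionMismatchError(
                f"patch must be at least {_MIN_SIDE}x{_MIN_SIDE} px, got {arr.shape[:2]}"
            )
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        self.pixels = arr.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @classmethod
    def from_file(cls, path: str | Path, pixel_size: float = 0.5) -> "RGBPatch":
        """Read a PNG/TIFF patch from disk (alpha channel dropped if present)."""
        arr = iio.imread(path)
        if arr.ndim == 3 and arr.shape[2] == 4:
            arr = arr[:, :, :3]
        return cls(arr, pixel_size=pixel_size)


@dataclass
class HSVImage:
    """HSV channels of a patch, each scaled to [0, 1]."""

    h: np.ndarray
    s: np.ndarray
    v: np.ndarray

    @property
    def stacked(self) -> np.ndarray:
        return np.dstack([self.h, self.s, self.v])


@dataclass
class ColorPlaneSet:
    """The three role-labelled colour component images of a patch.

    ``ip`` is the pink/stroma plane, ``ib`` the blue/nuclei plane and
    ``iba`` the background plane. The masks are pairwise disjoint and
    together cover every pixel.
    """

    ip_image: np.ndarray
    ib_image: np.ndarray
    iba_image: np.ndarray
    ip_mask: np.ndarray
    ib_mask: np.ndarray
    iba_mask: np.ndarray
    cluster_centers: dict = field(default_factory=dict)


@dataclass
class PinkFilterConfig:
    """HSV interval defining "pink" for the stroma filter.

    ``h_lo > h_hi`` denotes a wrap-around hue interval
    ``[h_lo, 1] u [0, h_hi]`` (the default: pink straddles hue 0).
    """

    h_lo: float = 0.85
    h_hi: float = 0.05
    s_lo: float = 0.05
    s_hi: float = 0.6
    v_lo: float = 0.5
    v_hi: float = 1.0

    def __post_init__(self) -> None:
        for name in ("h_lo", "h_hi", "s_lo", "s_hi", "v_lo", "v_hi"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"{name}={val} outside [0, 1]")
        if self.s_lo > self.s_hi or self.v_lo > self.v_hi:
            raise ConfigurationError("empty saturation or value interval")


def _pixels(patch) -> np.ndarray:
    return patch.pixels if isinstance(patch, RGBPatch) else np.asarray(patch)


def to_hsv(patch: RGBPatch | np.ndarray) -> HSVImage:
    """Convert an RGB patch to HSV with every channel in [0, 1]."""
    arr = _pixels(patch)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise DimensionMismatchError(
            f"expected an (H, W, 3) RGB array, got shape {arr.shape}"
        )
    hsv = rgb2hsv(arr)
    return HSVImage(h=hsv[:, :, 0], s=hsv[:, :, 1], v=hsv[:, :, 2])


def cluster_hsv_pixels(
    patch: RGBPatch | np.ndarray, k: int = 3, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """K-means clustering of HSV pixel triples.

    Returns
    -------
    label_image : (H, W) int array of cluster indices in 0..k-1
    centers : (k, 3) HSV cluster centroids
    """
    hsv = to_hsv(patch).stacked
    flat = hsv.reshape(-1, 3)
    n_distinct = np.unique(flat, axis=0).shape[0]
    if n_distinct < k:
        raise DegenerateClusteringError(
            f"patch has {n_distinct} distinct colours, fewer than k={k}"
        )
    km = KMeans(n_clusters=k, n_init=4, random_state=seed)
    labels = km.fit_predict(flat)
    return labels.reshape(hsv.shape[:2]), km.cluster_centers_


def _hue_distance(h: np.ndarray | float, target: float) -> np.ndarray | float:
    """Circular distance between hues on the unit hue circle."""
    d = np.abs(np.asarray(h, dtype=float) - target)
    return np.minimum(d, 1.0 - d)


def kmeans_color_separation(
    patch: RGBPatch | np.ndarray, k: int = 3, seed: int = 0
) -> ColorPlaneSet:
    """Split a patch into pink (Ip), blue (Ib) and background (Iba) planes.

    Pixels are clustered on their HSV triples and the three clusters are
    relabelled deterministically: the centroid with the highest value and
    lowest saturation becomes the background, of the remaining two the one
    whose hue is circularly closest to pink becomes the stroma plane, and
    the last one the nuclei plane.
    """
    if k != 3:
        raise ConfigurationError(
            "role labelling (pink/blue/background) is defined for k=3 only; "
            "use cluster_hsv_pixels for other k"
        )
    label_image, centers = cluster_hsv_pixels(patch, k=k, seed=seed)
    arr = _pixels(patch)

    # background: brightest, least saturated centroid
    bg_score = centers[:, 2] - centers[:, 1]
    iba_idx = int(np.argmax(bg_score))
    rest = [i for i in range(3) if i != iba_idx]
    pink_dist = [_hue_distance(centers[i, 0], PINK_HUE) for i in rest]
    ip_idx = rest[int(np.argmin(pink_dist))]
    ib_idx = rest[1 - int(np.argmin(pink_dist))]

    def plane(idx: int) -> tuple[np.ndarray, np.ndarray]:
        mask = label_image == idx
        img = np.where(mask[:, :, None], arr, 0).astype(np.uint8)
        return img, mask

    ip_image, ip_mask = plane(ip_idx)
    ib_image, ib_mask = plane(ib_idx)
    iba_image, iba_mask = plane(iba_idx)
    return ColorPlaneSet(
        ip_image=ip_image,
        ib_image=ib_image,
        iba_image=iba_image,
        ip_mask=ip_mask,
        ib_mask=ib_mask,
        iba_mask=iba_mask,
        cluster_centers={
            "pink": centers[ip_idx],
            "blue": centers[ib_idx],
            "background": centers[iba_idx],
        },
    )


def stroma_pink_filter(
    patch: RGBPatch | np.ndarray, thresholds: PinkFilterConfig | None = None
) -> tuple[np.ndarray, float]:
    """Pink colour filter: stroma mask plus its mean concentration.

    Returns the boolean mask of pixels whose HSV triple falls in the
    configured pink interval and the fraction of such pixels in the patch.
    """
    cfg = thresholds or PinkFilterConfig()
    hsv = to_hsv(patch)
    if cfg.h_lo <= cfg.h_hi:
        h_in = (hsv.h >= cfg.h_lo) & (hsv.h <= cfg.h_hi)
    else:  # wrap-around interval
        h_in = (hsv.h >= cfg.h_lo) | (hsv.h <= cfg.h_hi)
    mask = (
        h_in
        & (hsv.s >= cfg.s_lo)
        & (hsv.s <= cfg.s_hi)
        & (hsv.v >= cfg.v_lo)
        & (hsv.v <= cfg.v_hi)
    )
    return mask, float(mask.mean())
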