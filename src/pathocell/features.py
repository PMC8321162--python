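"""Three-level morphological feature extraction.

Features are computed at three scales and gathered into one tidy table with
a row per segmented nucleus:

* **nucleus** — geometry from the labelled region (area, perimeter,
  roundness 4*pi*A/P^2, equivalent-ellipse axes/eccentricity/orientation,
  centroid) plus co-occurrence texture and mean HSV inside an eroded
  sub-region of the nucleus body;
* **regional** — square windows of side 30/60/90/120 px centred on the
  nucleus centroid: the concentration R = TW/TP of each colour plane
  (stroma, background, nuclei, and a dilated-nuclei epithelium proxy),
  per-channel HSV means and 4-bin HSV histograms;
* **global** — whole-patch plane concentrations, HSV means and the pink
  stroma-filter mean; duct/cluster morphometrics are attached to the
  nuclei they contain.

Windows are axis-aligned, half-open, cropped at the image border (TP counts
only in-image pixels). Coordinates are 0-based with x = column, y = row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import label as cc_label
from skimage.measure import perimeter as region_perimeter
from skimage.measure import regionprops

from .color import (
    ColorPlaneSet,
    HSVImage,
    PinkFilterConfig,
    RGBPatch,
    _pixels,
    kmeans_color_separation,
    stroma_pink_filter,
    to_hsv,
)
from .errors import CoordinateError, MissingLabelError
from .segmentation import (
    EnhancementParams,
    NucleiLabelMap,
    enhance_nuclei,
    segment_nuclei,
)

WINDOW_SIZES: tuple[int, ...] = (30, 60, 90, 120)

NUCLEUS_FEATURE_COLUMNS = [
    "area",
    "perimeter",
    "roundness",
    "eccentricity",
    "centroid_x",
    "centroid_y",
    "major_axis",
    "minor_axis",
    "orientation",
    "texture_contrast_1",
    "texture_contrast_2",
    "texture_homogeneity_1",
    "texture_homogeneity_2",
    "mean_h",
    "mean_s",
    "mean_v",
]

CLUSTER_FEATURE_COLUMNS = [
    "cluster_id",
    "cluster_area",
    "cluster_roundness",
    "cluster_n_cells",
    "cluster_mean_dist",
]

GLOBAL_FEATURE_COLUMNS = [
    "global_conc_stroma",
    "global_conc_background",
    "global_conc_nuclei",
    "global_mean_h",
    "global_mean_s",
    "global_mean_v",
    "stroma_filter_mean",
]


def regional_feature_columns(window: int) -> list[str]:
    """Ordered regional column names for one window size."""
    cols = [
        f"w{window}_conc_stroma",
        f"w{window}_conc_background",
        f"w{window}_conc_nuclei",
        f"w{window}_conc_epithelial",
        f"w{window}_mean_h",
        f"w{window}_mean_s",
        f"w{window}_mean_v",
    ]
    for ch in "hsv":
        cols += [f"w{window}_hist_{ch}_{b}" for b in range(1, 5)]
    return cols


def feature_columns(windows: tuple[int, ...] = WINDOW_SIZES) -> list[str]:
    """The fixed, ordered feature-column schema of a FeatureTable."""
    cols = list(NUCLEUS_FEATURE_COLUMNS)
    for w in windows:
        cols += regional_feature_columns(w)
    cols += CLUSTER_FEATURE_COLUMNS
    cols += GLOBAL_FEATURE_COLUMNS
    return cols


@dataclass
class FeatureConfig:
    """Tunable knobs of the feature extractors (all sizes in pixels)."""

    windows: tuple[int, ...] = WINDOW_SIZES
    texture_levels: int = 8
    erosion_radius: int = 1
    epithelial_dilation_radius: int = 10
    cluster_close_radius: int = 7
    cluster_open_radius: int = 3
    min_cluster_area: int = 2000
    min_cluster_cells: int = 5


@dataclass
class ClusterFeatures:
    """Morphometrics of one detected duct/cluster region."""

    cluster_id: int
    cluster_area: float
    cluster_roundness: float
    n_cells_inside: int
    mean_cell_to_centroid_distance: float
    member_labels: list = field(default_factory=list)


@dataclass
class GlobalFeatures:
    """Whole-patch concentrations and colour summary."""

    global_conc_stroma: float
    global_conc_background: float
    global_conc_nuclei: float
    global_mean_h: float
    global_mean_s: float
    global_mean_v: float
    stroma_filter_mean: float


# ---------------------------------------------------------------------------
# binary morphology with exact Euclidean discs (footprint = {d <= r})


def disc_dilate(mask: np.ndarray, radius: float) -> np.ndarray:
    """Dilate a boolean mask by a Euclidean disc of the given radius."""
    mask = np.asarray(mask, dtype=bool)
    if radius <= 0 or not mask.any():
        return mask.copy()
    return ndi.distance_transform_edt(~mask) <= radius


def disc_erode(mask: np.ndarray, radius: float) -> np.ndarray:
    """Erode a boolean mask by a Euclidean disc of the given radius."""
    mask = np.asarray(mask, dtype=bool)
    if radius <= 0 or not mask.any():
        return mask.copy()
    return ndi.distance_transform_edt(mask) > radius


# ---------------------------------------------------------------------------
# per-nucleus features


def _region_for_label(labels: NucleiLabelMap, label: int):
    mask = labels.labels == label
    if not mask.any():
        raise MissingLabelError(f"label {label} not present in label map")
    return mask


def _geometry_from_regionprops(rp) -> dict:
    per = rp.perimeter
    area = float(rp.area)
    roundness = 4.0 * np.pi * area / per**2 if per > 0 else 0.0
    cy, cx = rp.centroid
    return {
        "area": area,
        "perimeter": float(per),
        "roundness": float(roundness),
        "eccentricity": float(rp.eccentricity),
        "centroid_x": float(cx),
        "centroid_y": float(cy),
        "major_axis": float(rp.axis_major_length),
        "minor_axis": float(rp.axis_minor_length),
        "orientation": float(np.degrees(rp.orientation)),
    }


def nucleus_morphology(labels: NucleiLabelMap, label: int) -> dict:
    """Geometry features of one labelled nucleus."""
    mask = _region_for_label(labels, label)
    rp = regionprops(mask.astype(np.uint8))[0]
    return _geometry_from_regionprops(rp)


def masked_cooccurrence_stats(
    gray: np.ndarray,
    mask: np.ndarray,
    levels: int = 8,
    offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 0)),
) -> list[tuple[float, float]]:
    """Symmetric, normalised co-occurrence contrast/homogeneity inside a mask.

    Gray values in [0, 1] are quantised to ``levels`` bins; only pixel pairs
    with both members inside the mask are counted. Returns one
    ``(contrast, homogeneity)`` pair per offset; a region with no valid
    pairs reports the constant-image limit (0, 1).
    """
    gray = np.asarray(gray, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    lv = np.minimum((gray * levels).astype(int), levels - 1)
    ii, jj = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    diff2 = (ii - jj) ** 2
    out = []
    for dy, dx in offsets:
        h, w = mask.shape
        src = (slice(0, h - dy), slice(0, w - dx))
        dst = (slice(dy, h), slice(dx, w))
        valid = mask[src] & mask[dst]
        if not valid.any():
            out.append((0.0, 1.0))
            continue
        pairs = lv[src][valid] * levels + lv[dst][valid]
        counts = np.bincount(pairs, minlength=levels * levels).reshape(levels, levels)
        counts = counts + counts.T  # symmetric
        p = counts / counts.sum()
        contrast = float((p * diff2).sum())
        homogeneity = float((p / (1.0 + diff2)).sum())
        out.append((contrast, homogeneity))
    return out


def nucleus_texture_hsv(
    patch: RGBPatch | np.ndarray,
    labels: NucleiLabelMap,
    label: int,
    config: FeatureConfig | None = None,
    _gray: np.ndarray | None = None,
    _hsv: HSVImage | None = None,
) -> dict:
    """Texture and mean-HSV features inside one nucleus body.

    Statistics are taken over an eroded sub-region of the nucleus so the
    boundary mix of nuclear and stromal colour does not contaminate them;
    if erosion empties the region the full nucleus mask is used instead.
    """
    cfg = config or FeatureConfig()
    mask = _region_for_label(labels, label)
    gray = _gray if _gray is not None else enhance_nuclei(patch).io_pixels
    hsv = _hsv if _hsv is not None else to_hsv(patch)

    sub = disc_erode(mask, cfg.erosion_radius)
    if not sub.any():
        sub = mask

    # crop to the bounding box; co-occurrence counting is local
    ys, xs = np.nonzero(sub)
    y0, y1, x0, x1 = ys.min(), ys.max() + 1, xs.min(), xs.max() + 1
    stats = masked_cooccurrence_stats(
        gray[y0:y1, x0:x1], sub[y0:y1, x0:x1], levels=cfg.texture_levels
    )
    return {
        "texture_contrast_1": stats[0][0],
        "texture_contrast_2": stats[1][0],
        "texture_homogeneity_1": stats[0][1],
        "texture_homogeneity_2": stats[1][1],
        "mean_h": float(hsv.h[sub].mean()),
        "mean_s": float(hsv.s[sub].mean()),
        "mean_v": float(hsv.v[sub].mean()),
    }


# ---------------------------------------------------------------------------
# regional (windowed) features


def _window_bounds(
    shape: tuple[int, int], center: tuple[float, float], window: int
) -> tuple[int, int, int, int]:
    h, w = shape
    cx, cy = int(round(center[0])), int(round(center[1]))
    if not (0 <= cx < w and 0 <= cy < h):
        raise CoordinateError(f"center {center} outside image of shape {shape}")
    x0 = max(cx - window // 2, 0)
    y0 = max(cy - window // 2, 0)
    x1 = min(cx - window // 2 + window, w)
    y1 = min(cy - window // 2 + window, h)
    return y0, y1, x0, x1


def regional_concentration(
    plane_mask: np.ndarray, center: tuple[float, float], window: int
) -> float:
    """Concentration R = TW/TP of a binary plane in a window around a nucleus.

    ``center`` is (x, y); the window is cropped at the image border and TP
    counts only the pixels actually inside the image.
    """
    plane_mask = np.asarray(plane_mask, dtype=bool)
    y0, y1, x0, x1 = _window_bounds(plane_mask.shape, center, window)
    sub = plane_mask[y0:y1, x0:x1]
    return float(sub.mean())


def regional_hsv_histograms(
    hsv: HSVImage, center: tuple[float, float], window: int
) -> dict:
    """4-bin HSV histograms (equal-width bins on [0,1], normalised) and means."""
    y0, y1, x0, x1 = _window_bounds(hsv.h.shape, center, window)
    out: dict = {}
    for name, chan in (("h", hsv.h), ("s", hsv.s), ("v", hsv.v)):
        sub = chan[y0:y1, x0:x1].ravel()
        bins = np.clip((sub * 4).astype(int), 0, 3)
        hist = np.bincount(bins, minlength=4) / sub.size
        out[f"hist_{name}"] = hist
        out[f"mean_{name}"] = float(sub.mean())
    return out


# ---------------------------------------------------------------------------
# clusters (ducts) and global features


def detect_clusters(
    patch: RGBPatch | np.ndarray,
    planes: ColorPlaneSet,
    labels: NucleiLabelMap,
    config: FeatureConfig | None = None,
) -> list[ClusterFeatures]:
    """Detect duct-like clusters as dense foreground regions.

    The candidate foreground is the complement of the background plane;
    a morphological closing (merging packed nuclei) followed by an opening
    (dropping thin bridges) leaves compact tissue regions, and those with
    enough area and enough nucleus centroids inside are reported.
    """
    cfg = config or FeatureConfig()
    fg = ~planes.iba_mask
    merged = disc_erode(
        disc_dilate(fg, cfg.cluster_close_radius), cfg.cluster_close_radius
    )
    merged = disc_dilate(
        disc_erode(merged, cfg.cluster_open_radius), cfg.cluster_open_radius
    )
    comp = cc_label(merged, connectivity=2)

    centroids: dict[int, tuple[float, float]] = {}
    for rp in regionprops(labels.labels):
        cy, cx = rp.centroid
        centroids[rp.label] = (cx, cy)

    clusters: list[ClusterFeatures] = []
    for rp in regionprops(comp):
        if rp.area < cfg.min_cluster_area:
            continue
        region = comp == rp.label
        members = [
            lab
            for lab, (cx, cy) in centroids.items()
            if region[int(round(cy)), int(round(cx))]
        ]
        if len(members) < cfg.min_cluster_cells:
            continue
        ccy, ccx = rp.centroid
        dists = [
            float(np.hypot(centroids[lab][0] - ccx, centroids[lab][1] - ccy))
            for lab in members
        ]
        per = rp.perimeter
        clusters.append(
            ClusterFeatures(
                cluster_id=len(clusters) + 1,
                cluster_area=float(rp.area),
                cluster_roundness=4.0 * np.pi * rp.area / per**2 if per > 0 else 0.0,
                n_cells_inside=len(members),
                mean_cell_to_centroid_distance=float(np.mean(dists)),
                member_labels=members,
            )
        )
    return clusters


def global_features(
    patch: RGBPatch | np.ndarray,
    planes: ColorPlaneSet,
    pink: tuple[np.ndarray, float] | None = None,
    _hsv: HSVImage | None = None,
) -> GlobalFeatures:
    """Whole-patch plane concentrations, HSV means and pink-filter mean."""
    hsv = _hsv if _hsv is not None else to_hsv(patch)
    if pink is None:
        pink = stroma_pink_filter(patch)
    return GlobalFeatures(
        global_conc_stroma=float(planes.ip_mask.mean()),
        global_conc_background=float(planes.iba_mask.mean()),
        global_conc_nuclei=float(planes.ib_mask.mean()),
        global_mean_h=float(hsv.h.mean()),
        global_mean_s=float(hsv.s.mean()),
        global_mean_v=float(hsv.v.mean()),
        stroma_filter_mean=pink[1],
    )


# ---------------------------------------------------------------------------
# the full per-patch table


@dataclass
class PatchAnalysis:
    """Everything computed for one patch by the extraction pipeline."""

    patch: RGBPatch
    hsv: HSVImage
    planes: ColorPlaneSet
    nuclei: NucleiLabelMap
    clusters: list
    globals_: GlobalFeatures
    table: pd.DataFrame


def analyze_patch(
    patch: RGBPatch | np.ndarray,
    *,
    enhancement: EnhancementParams | None = None,
    config: FeatureConfig | None = None,
    kmeans_seed: int = 0,
    pink_thresholds: PinkFilterConfig | None = None,
    min_area: int = 20,
    h_maxima: float = 2.0,
    patch_id: str = "patch",
    tc_label: float | None = None,
) -> PatchAnalysis:
    """Run colour separation, segmentation and all feature extractors.

    Returns the intermediate products alongside the per-nucleus feature
    table; :func:`extract_feature_table` is the table-only convenience
    wrapper.
    """
    cfg = config or FeatureConfig()
    if not isinstance(patch, RGBPatch):
        patch = RGBPatch(patch)

    hsv = to_hsv(patch)
    planes = kmeans_color_separation(patch, seed=kmeans_seed)
    nuclei = segment_nuclei(patch, enhancement, min_area=min_area, h=h_maxima)
    pink = stroma_pink_filter(patch, pink_thresholds)
    glob = global_features(patch, planes, pink, _hsv=hsv)
    clusters = detect_clusters(patch, planes, nuclei, cfg)
    gray = enhance_nuclei(patch, enhancement).io_pixels

    nucleus_cluster: dict[int, ClusterFeatures] = {}
    for cl in clusters:
        for lab in cl.member_labels:
            nucleus_cluster[lab] = cl

    plane_masks = {
        "stroma": planes.ip_mask,
        "background": planes.iba_mask,
        "nuclei": planes.ib_mask,
        "epithelial": disc_dilate(planes.ib_mask, cfg.epithelial_dilation_radius),
    }

    rows = []
    for rp in regionprops(nuclei.labels):
        row: dict = {"patch_id": patch_id, "nucleus_label": rp.label}
        row.update(_geometry_from_regionprops(rp))
        row.update(
            nucleus_texture_hsv(patch, nuclei, rp.label, cfg, _gray=gray, _hsv=hsv)
        )
        center = (row["centroid_x"], row["centroid_y"])
        for w in cfg.windows:
            for plane_name, mask in plane_masks.items():
                row[f"w{w}_conc_{plane_name}"] = regional_concentration(
                    mask, center, w
                )
            hists = regional_hsv_histograms(hsv, center, w)
            for ch in "hsv":
                row[f"w{w}_mean_{ch}"] = hists[f"mean_{ch}"]
                for b in range(4):
                    row[f"w{w}_hist_{ch}_{b + 1}"] = float(hists[f"hist_{ch}"][b])
        cl = nucleus_cluster.get(rp.label)
        row["cluster_id"] = cl.cluster_id if cl else 0
        row["cluster_area"] = cl.cluster_area if cl else 0.0
        row["cluster_roundness"] = cl.cluster_roundness if cl else 0.0
        row["cluster_n_cells"] = cl.n_cells_inside if cl else 0
        row["cluster_mean_dist"] = cl.mean_cell_to_centroid_distance if cl else 0.0
        for col in GLOBAL_FEATURE_COLUMNS:
            row[col] = getattr(glob, col)
        if tc_label is not None:
            row["tc_label"] = float(tc_label)
        rows.append(row)

    columns = ["patch_id", "nucleus_label"] + feature_columns(cfg.windows)
    if tc_label is not None:
        columns.append("tc_label")
    table = pd.DataFrame(rows, columns=columns)
    return PatchAnalysis(
        patch=patch,
        hsv=hsv,
        planes=planes,
        nuclei=nuclei,
        clusters=clusters,
        globals_=glob,
        table=table,
    )


def extract_feature_table(
    patch: RGBPatch | np.ndarray,
    *,
    enhancement: EnhancementParams | None = None,
    config: FeatureConfig | None = None,
    kmeans_seed: int = 0,
    pink_thresholds: PinkFilterConfig | None = None,
    patch_id: str = "patch",
    tc_label: float | None = None,
) -> pd.DataFrame:
    """Per-nucleus feature table for one patch (one row per nucleus)."""
    return analyze_patch(
        patch,
        enhancement=enhancement,
        config=config,
        kmeans_seed=kmeans_seed,
        pink_thresholds=pink_thresholds,
        patch_id=patch_id,
        tc_label=tc_label,
    ).table
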