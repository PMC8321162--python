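"""Synthetic H&E-like phantom patches with pixel-exact ground truth.

Phantoms emulate the structure of a breast-tissue H&E patch — eosin-pink
stroma, white fat blobs, hematoxylin-blue elliptical nuclei and optional
duct-like packed clusters — while recording perfect ground truth: every
nucleus mask, its benign/malignant class, and the planted tumour
cellularity (the dilated-coverage fraction of the malignant nuclei).

The malignant phenotype is encoded geometrically (larger, more eccentric,
irregular-boundary nuclei) so that morphology features are genuinely
discriminative on phantoms; that is a modelling choice of the fixture, not
a claim about tumour biology. Rendering is fully deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .cellularity import compute_tc_from_masks
from .color import RGBPatch
from .errors import PlacementError
from .segmentation import NucleiLabelMap

BENIGN = "benign"
MALIGNANT = "malignant"


@dataclass
class PhantomSpec:
    """Recipe for one phantom patch.

    Radii are semi-axis ranges in pixels; colours are RGB triples jittered
    per structure by ``color_jitter_sd``. ``noise_sd`` is the standard
    deviation of the final per-pixel Gaussian intensity noise (8-bit units).
    """

    size: int = 512
    n_benign: int = 40
    n_malignant: int = 15
    benign_radius: tuple[float, float] = (4.0, 6.0)
    malignant_radius: tuple[float, float] = (7.0, 11.0)
    malignant_eccentricity: tuple[float, float] = (0.5, 0.85)
    n_ducts: int = 0
    duct_cells: tuple[int, int] = (8, 15)
    stroma_color: tuple[int, int, int] = (230, 160, 200)
    nucleus_color: tuple[int, int, int] = (45, 35, 105)
    fat_color: tuple[int, int, int] = (245, 245, 245)
    color_jitter_sd: float = 6.0
    fat_fraction: float = 0.05
    noise_sd: float = 5.0
    dilation_radius: float = 10.0
    min_separation: float = 2.0
    seed: int = 0
    max_tries: int = 200

    def __post_init__(self) -> None:
        if min(self.n_benign, self.n_malignant, self.n_ducts) < 0:
            raise ValueError("counts must be >= 0")
        if self.benign_radius[0] < 3 or self.malignant_radius[0] < 3:
            raise ValueError("nucleus radii must be >= 3 px")
        if not 0.0 <= self.fat_fraction <= 1.0:
            raise ValueError("fat_fraction must be in [0, 1]")


@dataclass
class SyntheticPhantom:
    """A rendered phantom plus its ground truth."""

    patch: RGBPatch
    nuclei: NucleiLabelMap
    classes: np.ndarray  # per-nucleus 'benign' | 'malignant', index = label - 1
    duct_labels: np.ndarray
    true_tc: float
    malignant_mask: np.ndarray = field(repr=False)  # planted, pre-dilation
    spec: PhantomSpec | None = None


def _nucleus_mask(
    a: float, b: float, theta: float, irregular: bool, rng: np.random.Generator
) -> np.ndarray:
    """Rasterise one (possibly irregular) ellipse into a tight local mask."""
    amp = rng.uniform(0.08, 0.16) if irregular else 0.0
    k = int(rng.integers(3, 7)) if irregular else 0
    phase = rng.uniform(0, 2 * math.pi)
    half = int(math.ceil(max(a, b) * (1.0 + amp))) + 1
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    xr = math.cos(theta) * xx + math.sin(theta) * yy
    yr = -math.sin(theta) * xx + math.cos(theta) * yy
    rho = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
    if irregular:
        phi = np.arctan2(yr / b, xr / a)
        bound = 1.0 + amp * np.sin(k * phi + phase)
    else:
        bound = 1.0
    return rho <= bound


class _Canvas:
    """Mutable phantom under construction: occupancy, labels, rendering."""

    def __init__(self, spec: PhantomSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        n = spec.size
        self.image = np.empty((n, n, 3), dtype=float)
        self.image[:] = spec.stroma_color
        self.occupied = np.zeros((n, n), dtype=bool)
        self.labels = np.zeros((n, n), dtype=np.int32)
        self.duct_labels = np.zeros((n, n), dtype=np.int32)
        self.classes: list[str] = []

    def paint_fat(self) -> None:
        spec, rng, n = self.spec, self.rng, self.spec.size
        target = spec.fat_fraction * n * n
        fat = np.zeros((n, n), dtype=bool)
        guard = 0
        while fat.sum() < target and guard < 100:
            guard += 1
            cy, cx = rng.integers(0, n, size=2)
            a, b = rng.uniform(n / 16, n / 7, size=2)
            theta = rng.uniform(0, math.pi)
            yy, xx = np.mgrid[0:n, 0:n].astype(float)
            xr = math.cos(theta) * (xx - cx) + math.sin(theta) * (yy - cy)
            yr = -math.sin(theta) * (xx - cx) + math.cos(theta) * (yy - cy)
            fat |= (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        color = np.asarray(spec.fat_color, dtype=float)
        color = color + self.rng.normal(0, self.spec.color_jitter_sd / 4, size=3)
        self.image[fat] = np.clip(color, 0, 255)

    def _try_place(
        self, mask: np.ndarray, cy: int, cx: int
    ) -> tuple[slice, slice, np.ndarray] | None:
        """Check a local mask centred at (cy, cx) against the occupancy map."""
        n = self.spec.size
        half = mask.shape[0] // 2
        y0, y1 = cy - half, cy + half + 1
        x0, x1 = cx - half, cx + half + 1
        my0, mx0 = max(0, -y0), max(0, -x0)
        my1 = mask.shape[0] - max(0, y1 - n)
        mx1 = mask.shape[1] - max(0, x1 - n)
        if my1 <= my0 or mx1 <= mx0:
            return None
        sub = mask[my0:my1, mx0:mx1]
        ys = slice(max(0, y0), min(n, y1))
        xs = slice(max(0, x0), min(n, x1))
        if sub.sum() < 0.5 * mask.sum():  # keep most of the nucleus in-image
            return None
        sep = self.spec.min_separation
        grown = ndi.distance_transform_edt(~sub) <= sep if sep > 0 else sub
        if (grown & self.occupied[ys, xs]).any():
            return None
        return ys, xs, sub

    def place_nucleus(
        self,
        cls: str,
        center: tuple[int, int] | None = None,
        tries: int | None = None,
    ) -> bool:
        """Place one nucleus; returns False if the retry budget runs out."""
        spec, rng = self.spec, self.rng
        budget = tries if tries is not None else spec.max_tries
        for _ in range(budget):
            if cls == MALIGNANT:
                a = rng.uniform(*spec.malignant_radius)
                ecc = rng.uniform(*spec.malignant_eccentricity)
                b = a * math.sqrt(1.0 - ecc**2)
                mask = _nucleus_mask(a, b, rng.uniform(0, math.pi), True, rng)
            else:
                a = rng.uniform(*spec.benign_radius)
                b = a * rng.uniform(0.85, 1.0)
                mask = _nucleus_mask(a, b, rng.uniform(0, math.pi), False, rng)
            if center is None:
                cy = int(rng.integers(0, spec.size))
                cx = int(rng.integers(0, spec.size))
            else:
                jitter = rng.integers(-2, 3, size=2)
                cy, cx = center[0] + int(jitter[0]), center[1] + int(jitter[1])
                cy = int(np.clip(cy, 0, spec.size - 1))
                cx = int(np.clip(cx, 0, spec.size - 1))
            placed = self._try_place(mask, cy, cx)
            if placed is None:
                continue
            ys, xs, sub = placed
            label = len(self.classes) + 1
            self.occupied[ys, xs] |= sub
            self.labels[ys, xs][sub] = label
            self.classes.append(cls)
            # one shared chromatin colour: malignancy is encoded geometrically
            # (size/eccentricity/boundary), keeping the intensity histogram
            # bimodal. Jitter is truncated at 1.5 sd so no nucleus can drift
            # past the advertised contrast margin against the stroma.
            sd = self.spec.color_jitter_sd
            jitter = np.clip(rng.normal(0, sd, size=3), -1.5 * sd, 1.5 * sd)
            color = np.asarray(self.spec.nucleus_color, dtype=float) + jitter
            self.image[ys, xs][sub] = np.clip(color, 0, 255)
            return True
        return False

    def place_duct(self, duct_id: int) -> int:
        """Plant one duct: a packed ring-and-core of benign nuclei."""
        spec, rng = self.spec, self.rng
        n_cells = int(rng.integers(spec.duct_cells[0], spec.duct_cells[1] + 1))
        mean_r = float(np.mean(spec.benign_radius))
        # sized so random sequential placement stays below disc-packing jamming
        duct_radius = mean_r * (1.6 * math.sqrt(n_cells) + 1.5)
        margin = int(duct_radius + 2 * mean_r)
        cy = int(rng.integers(margin, spec.size - margin))
        cx = int(rng.integers(margin, spec.size - margin))
        placed = 0
        for _ in range(n_cells):
            for _ in range(80):  # fresh in-duct position each attempt
                frac = math.sqrt(rng.uniform(0, 1))
                ang = rng.uniform(0, 2 * math.pi)
                py = cy + int(frac * duct_radius * math.sin(ang))
                px = cx + int(frac * duct_radius * math.cos(ang))
                if self.place_nucleus(BENIGN, center=(py, px), tries=2):
                    placed += 1
                    break
        if placed:
            yy, xx = np.mgrid[0 : spec.size, 0 : spec.size].astype(float)
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= duct_radius**2
            self.duct_labels[disc] = duct_id
        return placed

    def finish(self) -> SyntheticPhantom:
        spec = self.spec
        noisy = self.image + self.rng.normal(0, spec.noise_sd, self.image.shape)
        patch = RGBPatch(np.clip(noisy, 0, 255).astype(np.uint8))
        classes = np.asarray(self.classes)
        malignant = (
            np.isin(self.labels, np.nonzero(classes == MALIGNANT)[0] + 1)
            if classes.size
            else np.zeros_like(self.occupied)
        )
        tc, _ = compute_tc_from_masks(malignant, spec.dilation_radius)
        return SyntheticPhantom(
            patch=patch,
            nuclei=NucleiLabelMap(labels=self.labels, n_nuclei=len(self.classes)),
            classes=classes,
            duct_labels=self.duct_labels,
            true_tc=tc,
            malignant_mask=malignant,
            spec=spec,
        )


def generate_phantom(spec: PhantomSpec | None = None, **overrides) -> SyntheticPhantom:
    """Generate one phantom patch from a spec (keyword overrides allowed)."""
    spec = replace(spec, **overrides) if spec is not None else PhantomSpec(**overrides)
    rng = np.random.default_rng(spec.seed)
    canvas = _Canvas(spec, rng)
    canvas.paint_fat()
    for _ in range(spec.n_malignant):
        if not canvas.place_nucleus(MALIGNANT):
            raise PlacementError(
                "could not place all malignant nuclei without overlap; "
                "lower the counts or radii"
            )
    for _ in range(spec.n_benign):
        if not canvas.place_nucleus(BENIGN):
            raise PlacementError(
                "could not place all benign nuclei without overlap; "
                "lower the counts or radii"
            )
    for d in range(spec.n_ducts):
        canvas.place_duct(d + 1)
    return canvas.finish()


def phantom_suite(
    level_grid,
    n_per_level: int = 1,
    seed: int = 0,
    spec: PhantomSpec | None = None,
) -> list[SyntheticPhantom]:
    """Phantoms whose planted TC lands on a grid of target levels.

    For each target, malignant nuclei are added one at a time with an
    oracle coverage check (the exact dilated union is maintained
    incrementally) until the planted TC reaches the target; benign nuclei
    fill the remaining space in proportion to 1 - target. If a target is
    unreachable under the spec (packing saturates first) the best
    achievable phantom is returned, its ``true_tc`` reporting the coverage
    actually reached.
    """
    template = spec or PhantomSpec(size=256)
    targets = [float(t) for t in level_grid]
    if any(t < 0 or t > 1 for t in targets):
        raise ValueError("target TC levels must lie in [0, 1]")
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(targets) * n_per_level
    ) % (2**31)

    phantoms: list[SyntheticPhantom] = []
    idx = 0
    for target in targets:
        for _ in range(n_per_level):
            child = replace(template, seed=int(child_seeds[idx]))
            idx += 1
            phantoms.append(_coverage_targeted_phantom(child, target))
    return phantoms


def _coverage_targeted_phantom(spec: PhantomSpec, target: float) -> SyntheticPhantom:
    rng = np.random.default_rng(spec.seed)
    canvas = _Canvas(spec, rng)
    canvas.paint_fat()
    n = spec.size
    dilated = np.zeros((n, n), dtype=bool)
    coverage = 0.0
    failures = 0
    r = spec.dilation_radius
    while coverage < target and failures < 25:
        before = len(canvas.classes)
        if not canvas.place_nucleus(MALIGNANT, tries=60):
            failures += 1
            continue
        label = before + 1
        # exact local dilation of the newly placed nucleus, OR-ed into the union
        ys, xs = np.nonzero(canvas.labels == label)
        pad = int(math.ceil(r)) + 1
        y0, y1 = max(0, ys.min() - pad), min(n, ys.max() + 1 + pad)
        x0, x1 = max(0, xs.min() - pad), min(n, xs.max() + 1 + pad)
        local = canvas.labels[y0:y1, x0:x1] == label
        dilated[y0:y1, x0:x1] |= ndi.distance_transform_edt(~local) <= r
        coverage = float(dilated.mean())
    n_benign = int(round(spec.n_benign * (1.0 - target)))
    for _ in range(n_benign):
        if not canvas.place_nucleus(BENIGN, tries=40):
            break  # space exhausted; benign fill is best-effort
    return canvas.finish()


class OracleClassifier:
    """Ground-truth classifier for phantoms.

    Classifies each table row by looking up the planted nucleus nearest to
    the row's centroid (within ``max_distance`` px); rows with no planted
    nucleus nearby are called benign. Used to isolate segmentation/scoring
    behaviour from classifier behaviour in end-to-end checks.
    """

    def __init__(self, phantom: SyntheticPhantom, max_distance: float = 5.0):
        self.phantom = phantom
        self.max_distance = max_distance
        truth = phantom.nuclei.labels
        if truth.max() > 0:
            dist, (iy, ix) = ndi.distance_transform_edt(
                truth == 0, return_indices=True
            )
            self._dist = dist
            self._nearest = truth[iy, ix]
        else:
            self._dist = np.full(truth.shape, np.inf)
            self._nearest = truth

    def predict(self, table) -> np.ndarray:
        out = []
        for _, row in table.iterrows():
            px = int(round(row["centroid_x"]))
            py = int(round(row["centroid_y"]))
            if self._dist[py, px] <= self.max_distance:
                out.append(self.phantom.classes[self._nearest[py, px] - 1])
            else:
                out.append(BENIGN)
        return np.asarray(out)

    def decision_scores(self, table) -> np.ndarray:
        return (self.predict(table) == MALIGNANT).astype(float)
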