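"""Morphology, texture, regional windows, clusters, global features, table."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathocell import (
    FeatureConfig,
    NucleiLabelMap,
    PhantomSpec,
    analyze_patch,
    detect_clusters,
    extract_feature_table,
    feature_columns,
    generate_phantom,
    global_features,
    kmeans_color_separation,
    nucleus_morphology,
    nucleus_texture_hsv,
    regional_concentration,
    regional_hsv_histograms,
    stroma_pink_filter,
    to_hsv,
)
from pathocell.errors import CoordinateError, MissingLabelError
from pathocell.features import masked_cooccurrence_stats

from .conftest import draw_discs, draw_ellipse_mask


def label_map(mask: np.ndarray) -> NucleiLabelMap:
    return NucleiLabelMap(labels=mask.astype(np.int32), n_nuclei=1)


class TestMorphology:
    def test_square_geometry_by_hand(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        feats = nucleus_morphology(label_map(mask), 1)
        assert feats["area"] == 100
        assert feats["perimeter"] == pytest.approx(36.0)
        assert feats["roundness"] == pytest.approx(4 * math.pi * 100 / 36**2)
        assert feats["centroid_x"] == pytest.approx(9.5)
        assert feats["centroid_y"] == pytest.approx(9.5)

    def test_disc_is_round_with_low_eccentricity(self):
        feats = nucleus_morphology(label_map(draw_ellipse_mask(20, 20, 0)), 1)
        assert feats["eccentricity"] < 0.1
        assert feats["roundness"] > 0.9

    def test_thin_bar_is_elongated(self):
        mask = np.zeros((50, 60), dtype=bool)
        mask[23:27, 10:50] = True
        feats = nucleus_morphology(label_map(mask), 1)
        assert feats["eccentricity"] > 0.9
        assert feats["major_axis"] > 5 * feats["minor_axis"]

    @pytest.mark.parametrize(
        "a, b, theta", [(15, 8, 0), (15, 8, 30), (12, 9, 60), (20, 10, 120)]
    )
    def test_rasterised_ellipse_recovers_parameters(self, a, b, theta):
        feats = nucleus_morphology(label_map(draw_ellipse_mask(a, b, theta)), 1)
        assert feats["area"] == pytest.approx(math.pi * a * b, rel=0.05)
        assert feats["major_axis"] == pytest.approx(2 * a, rel=0.05)
        assert feats["minor_axis"] == pytest.approx(2 * b, rel=0.05)
        # regionprops measures from the row axis: orientation = 90 - theta mod 180
        expected = (90.0 - theta) % 180.0
        got = feats["orientation"] % 180.0
        delta = min(abs(got - expected), 180.0 - abs(got - expected))
        assert delta < 5.0

    def test_missing_label_raises(self):
        with pytest.raises(MissingLabelError):
            nucleus_morphology(label_map(np.zeros((10, 10), bool)), 1)


class TestTexture:
    def test_constant_nucleus_has_zero_contrast_unit_homogeneity(self):
        arr = np.full((40, 40, 3), 128, dtype=np.uint8)
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:30, 10:30] = True
        feats = nucleus_texture_hsv(arr, label_map(mask), 1)
        assert feats["texture_contrast_1"] == 0.0
        assert feats["texture_contrast_2"] == 0.0
        assert feats["texture_homogeneity_1"] == 1.0
        assert feats["texture_homogeneity_2"] == 1.0

    def test_checkerboard_is_maximal_contrast_for_its_range(self):
        # alternating extreme levels: every horizontal pair is (0, L-1), so
        # contrast hits its maximum (L-1)^2 and homogeneity its minimum
        gray = np.indices((12, 12)).sum(axis=0) % 2
        mask = np.ones((12, 12), dtype=bool)
        levels = 8
        (c1, h1), (c2, h2) = masked_cooccurrence_stats(
            gray.astype(float), mask, levels=levels
        )
        assert c1 == pytest.approx((levels - 1) ** 2)
        assert c2 == pytest.approx((levels - 1) ** 2)
        assert h1 == pytest.approx(1.0 / (1.0 + (levels - 1) ** 2))

    def test_cooccurrence_matches_hand_counted_matrix(self):
        # 1x3 strip of levels 0,0,7 at offset (0,1): pairs (0,0) and (0,7);
        # symmetric counts: {(0,0):2, (0,7):1, (7,0):1} -> P diag 0.5
        gray = np.array([[0.0, 0.0, 1.0]])
        mask = np.ones((1, 3), dtype=bool)
        (c1, h1), _ = masked_cooccurrence_stats(gray, mask, levels=8)
        assert c1 == pytest.approx(0.5 * 49)  # half the mass at |i-j| = 7
        assert h1 == pytest.approx(0.5 * 1.0 + 0.5 / 50)

    def test_pure_blue_nucleus_mean_hsv(self):
        arr = np.full((40, 40, 3), 255, dtype=np.uint8)
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:30, 10:30] = True
        arr[mask] = (0, 0, 255)
        feats = nucleus_texture_hsv(arr, label_map(mask), 1)
        assert feats["mean_h"] == pytest.approx(2 / 3)
        assert feats["mean_s"] == pytest.approx(1.0)
        assert feats["mean_v"] == pytest.approx(1.0)


class TestRegionalFeatures:
    def test_uniform_masks_hit_the_extremes(self):
        ones = np.ones((64, 64), dtype=bool)
        assert regional_concentration(ones, (32, 32), 30) == 1.0
        assert regional_concentration(~ones, (32, 32), 120) == 0.0

    def test_interior_window_with_known_count(self):
        mask = np.zeros((64, 64), dtype=bool)
        # half of a 30x30 window centred at (32, 32): rows 17..31 of 17..47
        mask[17:32, 17:47] = True
        assert regional_concentration(mask, (32, 32), 30) == pytest.approx(0.5)

    def test_center_outside_image_rejected(self):
        with pytest.raises(CoordinateError):
            regional_concentration(np.ones((32, 32), bool), (40, 10), 30)

    def test_matches_bruteforce_pixel_count(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            mask = rng.random((48, 48)) < rng.random()
            cx, cy = rng.integers(0, 48, size=2)
            w = int(rng.choice([30, 60, 90, 120]))
            got = regional_concentration(mask, (cx, cy), w)
            tw = tp = 0
            for y in range(cy - w // 2, cy - w // 2 + w):
                for x in range(cx - w // 2, cx - w // 2 + w):
                    if 0 <= y < 48 and 0 <= x < 48:
                        tp += 1
                        tw += bool(mask[y, x])
            assert got == pytest.approx(tw / tp)

    def test_uniform_value_lands_in_first_bin(self):
        arr = np.full((64, 64, 3), 26, dtype=np.uint8)  # v ~ 0.102
        hists = regional_hsv_histograms(to_hsv(arr), (32, 32), 30)
        assert np.allclose(hists["hist_v"], [1, 0, 0, 0])

    def test_split_values_fill_two_bins(self):
        arr = np.zeros((64, 64, 3), dtype=np.uint8)
        arr[:32] = 26  # v ~ 0.102 -> bin 1
        arr[32:] = 230  # v ~ 0.902 -> bin 4
        hists = regional_hsv_histograms(to_hsv(arr), (32, 32), 64)
        assert np.allclose(hists["hist_v"], [0.5, 0, 0, 0.5])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_histograms_are_distributions(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.integers(0, 256, size=(48, 48, 3), dtype=np.uint8)
        cx, cy = int(rng.integers(0, 48)), int(rng.integers(0, 48))
        w = int(rng.choice([30, 60, 90, 120]))
        hists = regional_hsv_histograms(to_hsv(arr), (cx, cy), w)
        for ch in "hsv":
            hist = hists[f"hist_{ch}"]
            assert hist.min() >= 0.0
            assert hist.sum() == pytest.approx(1.0, abs=1e-9)


class TestClusters:
    def test_packed_duct_detected_with_cell_count(self):
        ph = generate_phantom(
            PhantomSpec(
                size=256,
                seed=21,
                n_benign=0,
                n_malignant=0,
                n_ducts=1,
                duct_cells=(12, 12),
                fat_fraction=0.05,
            )
        )
        planes = kmeans_color_separation(ph.patch, seed=0)
        clusters = detect_clusters(ph.patch, planes, ph.nuclei)
        assert len(clusters) == 1
        assert clusters[0].n_cells_inside == 12

    def test_stroma_only_phantom_has_no_clusters(self):
        ph = generate_phantom(
            PhantomSpec(size=128, seed=3, n_benign=0, n_malignant=0)
        )
        planes = kmeans_color_separation(ph.patch, seed=0)
        assert detect_clusters(ph.patch, planes, ph.nuclei) == []

    def test_ring_of_nuclei_distance_matches_construction(self):
        # 8 nuclei on a circle of radius 15 at the patch centre; the tissue
        # blob is centred too, so the mean centroid distance tracks the ring
        centers = [
            (64 + int(round(15 * math.sin(t))), 64 + int(round(15 * math.cos(t))))
            for t in np.linspace(0, 2 * math.pi, 8, endpoint=False)
        ]
        patch = draw_discs(centers, radius=4, size=128)
        arr = patch.pixels.copy()
        # symmetric white frame: a third colour for K-means that keeps the
        # tissue blob (and hence the cluster centroid) centred
        arr[:6], arr[-6:], arr[:, :6], arr[:, -6:] = 255, 255, 255, 255
        patch = type(patch)(arr)
        labels = np.zeros((128, 128), dtype=np.int32)
        yy, xx = np.mgrid[0:128, 0:128]
        for i, (cy, cx) in enumerate(centers, start=1):
            labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= 16] = i
        lm = NucleiLabelMap(labels=labels, n_nuclei=8)
        planes = kmeans_color_separation(patch, seed=0)
        clusters = detect_clusters(patch, planes, lm)
        assert len(clusters) == 1
        assert clusters[0].mean_cell_to_centroid_distance == pytest.approx(15, abs=2)


class TestGlobalFeatures:
    def test_concentrations_partition_to_one(self, three_color_patch):
        planes = kmeans_color_separation(three_color_patch, seed=0)
        glob = global_features(three_color_patch, planes)
        total = (
            glob.global_conc_stroma
            + glob.global_conc_background
            + glob.global_conc_nuclei
        )
        assert total == pytest.approx(1.0)

    def test_quarter_blue_patch_concentration(self, three_color_patch):
        # construction: left half pink, top-right quarter blue, rest white
        planes = kmeans_color_separation(three_color_patch, seed=0)
        glob = global_features(three_color_patch, planes)
        assert glob.global_conc_stroma == pytest.approx(0.5)
        assert glob.global_conc_nuclei == pytest.approx(0.25)
        assert glob.global_conc_background == pytest.approx(0.25)

    def test_pink_filter_mean_passed_through(self, three_color_patch):
        planes = kmeans_color_separation(three_color_patch, seed=0)
        pink = stroma_pink_filter(three_color_patch)
        glob = global_features(three_color_patch, planes, pink)
        assert glob.stroma_filter_mean == pink[1]


class TestFeatureTable:
    def test_schema_has_expected_width(self):
        cols = feature_columns()
        assert len(cols) >= 102
        assert len(cols) == len(set(cols))

    def test_one_row_per_ground_truth_nucleus(self, small_phantom):
        analysis = analyze_patch(small_phantom.patch, patch_id="ph")
        assert len(analysis.table) == analysis.nuclei.n_nuclei
        assert analysis.nuclei.n_nuclei > 0
        assert list(analysis.table.columns[:2]) == ["patch_id", "nucleus_label"]
        # no missing values anywhere (edge-window and no-cluster policies fill)
        assert not analysis.table.isna().any().any()

    def test_blank_phantom_yields_empty_table_with_schema(self):
        ph = generate_phantom(
            PhantomSpec(size=128, seed=4, n_benign=0, n_malignant=0)
        )
        table = extract_feature_table(ph.patch, patch_id="blank")
        assert len(table) == 0
        assert set(feature_columns()).issubset(table.columns)

    def test_tc_label_column_attached_when_given(self, small_phantom):
        table = extract_feature_table(
            small_phantom.patch, patch_id="ph", tc_label=0.4
        )
        assert (table["tc_label"] == 0.4).all()
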