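"""Segmentation and feature extraction against constructed oracles."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.segmentation import watershed

from virtustain.profiling import (ProfilingConfig, SegmentationParams,
                                  extract_features, identify_primary,
                                  identify_secondary, profile_image,
                                  segment_droplets)


def disk_image(centres, radius, shape=(96, 96), value=1.0, bg=0.0):
    img = np.full(shape, bg)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for cy, cx in centres:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2] = value
    return img


GLOBAL = dict(threshold_strategy="global")


class TestIdentifyPrimary:
    def test_disjoint_disks_counted(self):
        img = disk_image([(20, 20), (20, 70), (70, 45)], 10)
        labels = identify_primary(img, SegmentationParams(
            diameter_range=(10, 30), **GLOBAL))
        assert labels.max() == 3

    def test_dumbbell_split_by_shape_matches_edt_oracle(self):
        # two equal disks overlapping at a neck
        img = disk_image([(40, 30), (40, 54)], 14, shape=(80, 84))
        params = SegmentationParams(diameter_range=(15, 40), declump="shape",
                                    **GLOBAL)
        labels = identify_primary(img, params)
        assert labels.max() == 2
        # oracle: watershed on the exact EDT seeded at the true centres
        mask = img > 0.5
        edt = ndi.distance_transform_edt(mask)
        markers = np.zeros_like(labels)
        markers[40, 30], markers[40, 54] = 1, 2
        oracle = watershed(-edt, markers, mask=mask)
        # same split up to label permutation: compare region sizes
        assert sorted(np.bincount(labels.ravel())[1:]) == pytest.approx(
            sorted(np.bincount(oracle.ravel())[1:]), rel=0.05)

    def test_twin_peak_disk_split_by_intensity(self):
        yy, xx = np.mgrid[0:80, 0:80]
        mask = (yy - 40) ** 2 + (xx - 40) ** 2 <= 26 ** 2
        img = np.zeros((80, 80))
        for cx in (30, 50):
            img += np.exp(-((yy - 40) ** 2 + (xx - cx) ** 2) / (2 * 8 ** 2))
        img = np.where(mask, 0.3 + 0.7 * img / img.max(), 0.0)
        params = SegmentationParams(diameter_range=(20, 60),
                                    declump="intensity", **GLOBAL)
        labels = identify_primary(img, params)
        assert labels.max() == 2
        # oracle: watershed seeded at the two constructed peaks
        markers = np.zeros((80, 80), dtype=np.int32)
        markers[40, 30], markers[40, 50] = 1, 2
        oracle = watershed(-img, markers, mask=mask)
        assert (labels > 0).sum() == pytest.approx(mask.sum(), rel=0.05)
        assert sorted(np.bincount(labels.ravel())[1:]) == pytest.approx(
            sorted(np.bincount(oracle.ravel())[1:]), rel=0.1)

    def test_constant_image_adaptive_warns_and_is_empty(self):
        params = SegmentationParams(diameter_range=(5, 20),
                                    threshold_strategy="adaptive",
                                    adaptive_window=32)
        with pytest.warns(UserWarning, match="constant"):
            labels = identify_primary(np.ones((64, 64)), params)
        assert labels.max() == 0

    def test_size_filter_drops_out_of_range_objects(self):
        img = disk_image([(20, 20)], 4) + disk_image([(70, 70)], 16)
        labels = identify_primary(img, SegmentationParams(
            diameter_range=(12, 40), **GLOBAL))
        assert labels.max() == 1  # only the large disk survives


class TestIdentifySecondary:
    def test_single_blob_single_seed(self):
        img = disk_image([(40, 40)], 20)
        seeds = np.zeros((96, 96), dtype=np.int32)
        seeds[38:43, 38:43] = 1
        params = SegmentationParams(diameter_range=(10, 60), **GLOBAL)
        labels = identify_secondary(img, seeds, params)
        assert labels.max() == 1
        assert ((labels > 0) == (img > 0.5)).mean() > 0.98

    def test_two_seeds_partition_one_blob(self):
        img = np.zeros((60, 100))
        img[20:40, 10:90] = 1.0  # one symmetric bar
        seeds = np.zeros_like(img, dtype=np.int32)
        seeds[29:32, 29:32] = 1
        seeds[29:32, 69:72] = 2
        params = SegmentationParams(diameter_range=(10, 80), **GLOBAL)
        labels = identify_secondary(img, seeds, params)
        assert set(np.unique(labels)) == {0, 1, 2}
        union = labels > 0
        assert np.array_equal(union, img > 0.5)
        # symmetric fixture: partition line near the midpoint
        sizes = np.bincount(labels.ravel())[1:]
        assert abs(sizes[0] - sizes[1]) / sizes.sum() < 0.1

    def test_count_always_equals_seed_count(self, rng):
        img = rng.random((64, 64))
        seeds = np.zeros((64, 64), dtype=np.int32)
        for i, (y, x) in enumerate([(10, 10), (30, 40), (55, 20)], 1):
            seeds[y, x] = i
        params = SegmentationParams(diameter_range=(5, 40), **GLOBAL)
        labels = identify_secondary(img, seeds, params)
        assert set(np.unique(labels)) - {0} == {1, 2, 3}
        for lb in (1, 2, 3):
            assert ((labels == lb) & (seeds == lb)).sum() > 0  # superset

    def test_empty_seeds_empty_output(self):
        params = SegmentationParams(diameter_range=(5, 40), **GLOBAL)
        out = identify_secondary(np.ones((32, 32)),
                                 np.zeros((32, 32), dtype=np.int32), params)
        assert out.max() == 0

    def test_shape_mismatch_rejected(self):
        params = SegmentationParams(diameter_range=(5, 40), **GLOBAL)
        with pytest.raises(ValueError, match="mismatch"):
            identify_secondary(np.ones((32, 32)),
                               np.zeros((16, 16), dtype=np.int32), params)


SMALL = SegmentationParams(diameter_range=(4, 14), declump="intensity",
                           **GLOBAL)
LARGE = SegmentationParams(diameter_range=(14, 40), declump="intensity",
                           smoothing_sigma=3.0, **GLOBAL)


class TestSegmentDroplets:
    def test_two_populations_counted_once_each(self, rng):
        small_centres = [(12 + 18 * i, 12) for i in range(5)] + \
                        [(12 + 18 * i, 30) for i in range(5)]
        large_centres = [(15 + 22 * i, 70) for i in range(4)] + [(90, 50)]
        img = (disk_image(small_centres, 4, (108, 96))
               + disk_image(large_centres, 9, (108, 96)))
        labels = segment_droplets(np.clip(img, 0, 1), SMALL, LARGE)
        # brute-force oracle: connected components of the union mask
        true_n = ndi.label(img > 0.5)[0].max()
        assert labels.max() == true_n == 15

    def test_merge_is_idempotent_for_identical_params(self):
        img = disk_image([(20, 20), (20, 60), (60, 40)], 6, (80, 80))
        params = SegmentationParams(diameter_range=(6, 20),
                                    declump="intensity", **GLOBAL)
        merged = segment_droplets(img, params, params)
        single = identify_primary(img, params)
        assert merged.max() == single.max()
        assert np.array_equal(merged > 0, single > 0)

    def test_empty_image_gives_empty_map(self):
        labels = segment_droplets(np.zeros((64, 64)), SMALL, LARGE)
        assert labels.max() == 0

    def test_requires_global_intensity_params(self):
        bad = SegmentationParams(diameter_range=(4, 14), declump="shape",
                                 **GLOBAL)
        with pytest.raises(ValueError, match="intensity"):
            segment_droplets(np.zeros((32, 32)), bad, LARGE)


class TestExtractFeatures:
    def test_uniform_disk_closed_form(self):
        labels = disk_image([(20, 20)], 8, (48, 48)).astype(np.int32)
        area = labels.sum()
        feats = extract_features(labels, 0.4 * labels.astype(float))
        assert feats["count"] == 1
        assert feats["mean_area"] == area
        assert feats["integrated_intensity"] == pytest.approx(0.4 * area)
        assert feats["mean_intensity"] == pytest.approx(0.4)
        assert feats["std_intensity"] == 0.0

    def test_two_disks_population_std(self):
        labels = np.zeros((48, 96), dtype=np.int32)
        labels[10:20, 10:20] = 1
        labels[10:20, 60:70] = 2
        intensity = np.where(labels == 1, 0.2, np.where(labels == 2, 0.4, 0.0))
        feats = extract_features(labels, intensity)
        assert feats["mean_intensity"] == pytest.approx(0.3)
        assert feats["std_intensity"] == pytest.approx(np.std([0.2, 0.4]))

    def test_integrated_intensity_additive_over_objects(self, rng):
        labels, _ = ndi.label(rng.random((64, 64)) > 0.7)
        intensity = rng.random((64, 64))
        feats = extract_features(labels, intensity)
        per_object = [intensity[labels == lb].sum()
                      for lb in range(1, labels.max() + 1)]
        assert feats["integrated_intensity"] == pytest.approx(sum(per_object))

    def test_empty_labels_yield_nan_markers(self):
        feats = extract_features(np.zeros((16, 16), dtype=np.int32),
                                 np.ones((16, 16)))
        assert feats["count"] == 0
        assert np.isnan(feats["mean_area"])


def test_profile_image_produces_one_row_per_structure(default_field):
    img = default_field["fluor"].astype(np.float64) / 65535.0
    labels, table = profile_image(img, ProfilingConfig(), image_id="f0")
    assert set(table["structure"]) == {"droplets", "cytoplasm", "nuclei"}
    cyto_count = int(table.loc[table.structure == "cytoplasm", "count"].iloc[0])
    nuc_count = int(table.loc[table.structure == "nuclei", "count"].iloc[0])
    assert cyto_count == nuc_count


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SegmentationParams(diameter_range=(10, 5))
    with pytest.raises(ValueError):
        SegmentationParams(diameter_range=(5, 10), declump="wibble")
    with pytest.warns(UserWarning, match="window"):
        SegmentationParams(diameter_range=(5, 60),
                           threshold_strategy="adaptive", adaptive_window=40)
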