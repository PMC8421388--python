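import numpy as np
import pytest

from gedipipe import (
    FrameImage,
    SegmentationParams,
    align_timepoints,
    extract_features,
    quantify_masked_area,
    roi_ratio,
    segment,
    stitch_montage,
    subtract_background,
)

from conftest import disk_image


def brute_force_label(binary):
    """4/8-connectivity flood-fill labeling, independent of scikit-image."""
    h, w = binary.shape
    labels = np.zeros((h, w), dtype=int)
    current = 0
    for sy in range(h):
        for sx in range(w):
            if binary[sy, sx] and labels[sy, sx] == 0:
                current += 1
                stack = [(sy, sx)]
                labels[sy, sx] = current
                while stack:
                    y, x = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if 0 <= ny < h and 0 <= nx < w and binary[ny, nx] and labels[ny, nx] == 0:
                                labels[ny, nx] = current
                                stack.append((ny, nx))
    return labels, current


class TestSubtractBackground:
    def test_constant_image_zeroed(self):
        out = subtract_background(FrameImage(np.full((10, 10), 42.0)))
        assert np.all(out.pixels == 0)

    def test_zero_median_unchanged(self):
        img = np.zeros((2, 2))
        img[0, 0] = 100.0
        out = subtract_background(FrameImage(img))
        assert np.array_equal(out.pixels, img)

    def test_pixels_above_median_reduced_by_median(self, rng):
        img = rng.uniform(0, 100, (50, 50))
        med = np.median(img)
        out = subtract_background(FrameImage(img))
        above = img >= med
        assert np.allclose(out.pixels[above], img[above] - med)

    def test_idempotent_on_zero_median(self, rng):
        img = rng.uniform(0, 100, (31, 31))
        once = subtract_background(FrameImage(img))
        twice = subtract_background(once)
        if np.median(once.pixels) == 0:
            assert np.array_equal(once.pixels, twice.pixels)


class TestStitchMontage:
    def test_identity_1x1(self, rng):
        img = rng.uniform(0, 10, (20, 20))
        tile = FrameImage(img, tile=(0, 0))
        out = stitch_montage([tile], (1, 1))
        assert np.array_equal(out.pixels, img)

    def test_2x2_dimensions_no_overlap(self):
        tiles = [
            FrameImage(np.full((100, 100), float(i)), tile=(r, c))
            for i, (r, c) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)])
        ]
        out = stitch_montage(tiles, (2, 2))
        assert out.pixels.shape == (200, 200)
        assert out.pixels[0, 0] == 0.0 and out.pixels[150, 150] == 3.0

    def test_overlap_strip_averaged(self):
        a = FrameImage(np.full((10, 10), 2.0), tile=(0, 0))
        b = FrameImage(np.full((10, 10), 6.0), tile=(0, 1))
        out = stitch_montage([a, b], (1, 2), overlap_px=4)
        assert out.pixels.shape == (10, 16)
        assert np.all(out.pixels[:, 6:10] == 4.0)
        assert np.all(out.pixels[:, :6] == 2.0)
        assert np.all(out.pixels[:, 10:] == 6.0)

    def test_missing_tile_names_gap(self):
        a = FrameImage(np.zeros((5, 5)), tile=(0, 0))
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            stitch_montage([a], (1, 2))


class TestAlignTimepoints:
    def test_identical_frames_zero_shift(self, rng):
        img = rng.uniform(0, 100, (64, 64))
        frames = [FrameImage(img, timepoint=float(t)) for t in range(3)]
        assert align_timepoints(frames) == [(0, 0), (0, 0), (0, 0)]

    def test_recovers_programmed_integer_shift(self, rng):
        base = disk_image((80, 80), [(30, 40, 6, 500.0), (60, 20, 5, 300.0)])
        shifted = np.roll(np.roll(base, 3, axis=1), -2, axis=0)  # dx=3, dy=-2
        shifts = align_timepoints([FrameImage(base), FrameImage(shifted, timepoint=1.0)])
        assert shifts[1] == (3, -2)

    def test_noisy_shift_within_one_px(self, rng):
        base = disk_image((80, 80), [(30, 40, 6, 500.0), (60, 20, 5, 300.0)])
        shifted = np.roll(np.roll(base, -4, axis=1), 5, axis=0)
        noisy0 = base + rng.normal(0, 50.0, base.shape)
        noisy1 = shifted + rng.normal(0, 50.0, base.shape)
        shifts = align_timepoints([FrameImage(noisy0), FrameImage(np.clip(noisy1, 0, None))])
        assert abs(shifts[1][0] + 4) <= 1 and abs(shifts[1][1] - 5) <= 1

    def test_featureless_frame_warns_zero(self):
        a = FrameImage(disk_image((40, 40), [(20, 20, 5, 100.0)]))
        b = FrameImage(np.zeros((40, 40)) + 1.0, timepoint=1.0)
        with pytest.warns(UserWarning, match="featureless"):
            shifts = align_timepoints([a, b])
        assert shifts[1] == (0, 0)

    def test_shift_beyond_cap_clamped(self):
        base = disk_image((100, 100), [(20, 20, 6, 500.0)])
        shifted = np.roll(base, 40, axis=1)
        with pytest.warns(UserWarning, match="exceeds cap"):
            shifts = align_timepoints([FrameImage(base), FrameImage(shifted, timepoint=1.0)],
                                      max_shift_px=10)
        assert shifts[1] == (10, 0)


class TestSegment:
    def test_empty_image_no_objects(self):
        labels, objs = segment(FrameImage(np.zeros((50, 50))))
        assert objs == [] and labels.max() == 0

    def test_min_size_boundary(self):
        """A ~150 px disk passes the 100 px floor; a ~50 px disk does not."""
        img = disk_image((120, 120), [(30, 30, 7, 1000.0), (90, 90, 4, 1000.0)])
        labels, objs = segment(FrameImage(img), SegmentationParams(smooth_sigma=0.0))
        assert len(objs) == 1
        assert objs[0].area_px >= 100
        cx, cy = objs[0].centroid
        assert (cx, cy) == pytest.approx((30, 30), abs=1.0)

    def test_two_disks_against_brute_force_oracle(self):
        img = disk_image((100, 100), [(25, 25, 8, 800.0), (70, 60, 9, 900.0)])
        labels, objs = segment(FrameImage(img), SegmentationParams(smooth_sigma=0.0))
        oracle_labels, n_oracle = brute_force_label(img > 0)
        # same number of >=100 px components, identical support
        assert len(objs) == n_oracle == 2
        assert np.array_equal(labels > 0, oracle_labels > 0)
        got = sorted(o.centroid for o in objs)
        assert got[0] == pytest.approx((25, 25), abs=1.0)
        assert got[1] == pytest.approx((70, 60), abs=1.0)

    def test_randomized_images_match_oracle(self, rng):
        """Component count and support match brute-force labeling on 100
        random small images (no smoothing, explicit threshold path)."""
        params = SegmentationParams(min_size=5, smooth_sigma=0.0, mad_floor_k=0.0,
                                    soma_area_cap=10**9)
        for _ in range(100):
            img = np.zeros((40, 40))
            for _ in range(int(rng.integers(1, 4))):
                cx, cy = rng.integers(6, 34, size=2)
                r = int(rng.integers(2, 5))
                img += disk_image((40, 40), [(cx, cy, r, 500.0)])
            labels, objs = segment(FrameImage(img), params)
            oracle_labels, _ = brute_force_label(img > np.percentile(img, 0) + 250.0)
            oracle_sizes = sorted(
                int((oracle_labels == k).sum())
                for k in range(1, oracle_labels.max() + 1)
                if (oracle_labels == k).sum() >= 5
            )
            assert sorted(o.area_px for o in objs) == oracle_sizes

    def test_labels_unique_masks_disjoint(self, rng):
        img = np.zeros((120, 120))
        for _ in range(5):
            cx, cy = rng.integers(15, 105, size=2)
            img += disk_image((120, 120), [(cx, cy, 7, 600.0)])
        labels, objs = segment(FrameImage(img), SegmentationParams(smooth_sigma=0.0))
        ids = [o.label for o in objs]
        assert len(ids) == len(set(ids))
        for o in objs:
            assert o.area_px == int((labels == o.label).sum())
            assert o.area_px >= 100

    def test_soma_cap_restricts_to_bright_core(self):
        """A huge dim blob with a bright core is cut back to the core."""
        img = disk_image((200, 200), [(100, 100, 40, 300.0)])
        img += disk_image((200, 200), [(100, 100, 8, 3000.0)])
        labels, objs = segment(
            FrameImage(img),
            SegmentationParams(smooth_sigma=0.0, soma_area_cap=1000),
        )
        assert len(objs) == 1
        assert objs[0].area_px < 5000 / 4  # far below the 40 px-radius blob


class TestExtractFeatures:
    def test_mean_and_peak_within_mask(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[2:4, 2:4] = 1
        img = np.zeros((10, 10))
        img[2:4, 2:4] = [[1.0, 2.0], [3.0, 4.0]]
        from gedipipe import SegmentedObject

        obj = SegmentedObject(1, "w", 0.0, 4, (2.5, 2.5))
        extract_features(labels, [obj], {"gedi": FrameImage(img)})
        assert obj.mean_intensity["gedi"] == pytest.approx(2.5)
        assert obj.peak_intensity["gedi"] == pytest.approx(4.0)

    def test_constant_offset_absorbed_by_median_subtraction(self, rng):
        """Feature means are invariant to adding a constant pre-subtraction."""
        img = disk_image((100, 100), [(50, 50, 8, 900.0)])
        for offset in (0.0, 57.0):
            frame = subtract_background(FrameImage(img + offset))
            labels, objs = segment(frame, SegmentationParams(smooth_sigma=0.0))
            extract_features(labels, objs, {"morphology": frame})
            if offset == 0.0:
                base = objs[0].mean_intensity["morphology"]
            else:
                assert objs[0].mean_intensity["morphology"] == pytest.approx(base)

    def test_shape_mismatch_rejected(self):
        from gedipipe import SegmentedObject

        obj = SegmentedObject(1, "w", 0.0, 4, (1, 1))
        with pytest.raises(ValueError):
            extract_features(np.ones((5, 5), dtype=int), [obj], {"gedi": FrameImage(np.ones((6, 6)))})


class TestMaskedArea:
    def test_identical_frames_all_ones(self):
        img = disk_image((60, 60), [(30, 30, 10, 500.0)])
        series = [FrameImage(img, timepoint=float(t)) for t in range(4)]
        assert np.allclose(quantify_masked_area(series), 1.0)

    def test_half_foreground_removed(self):
        t0 = disk_image((60, 60), [(20, 30, 8, 500.0), (45, 30, 8, 500.0)])
        t1 = disk_image((60, 60), [(20, 30, 8, 500.0)])
        out = quantify_masked_area([FrameImage(t0), FrameImage(t1, timepoint=1.0)])
        assert out[0] == 1.0
        assert out[1] == pytest.approx(0.5, abs=0.02)

    def test_exclusion_mask_applied(self):
        img = disk_image((60, 60), [(20, 30, 8, 500.0), (45, 30, 8, 500.0)])
        mask = np.zeros((60, 60), dtype=bool)
        mask[:, 35:] = True  # hide the second disk
        out = quantify_masked_area([FrameImage(img)] * 2, exclusion_mask=mask)
        assert np.allclose(out, 1.0)

    def test_empty_t0_rejected(self):
        with pytest.raises(ValueError):
            quantify_masked_area([FrameImage(np.zeros((20, 20)))], binarize_threshold=10.0)


class TestRoiRatio:
    def test_equal_channels_unity(self):
        img = disk_image((40, 40), [(20, 20, 6, 400.0)])
        mask = img > 0
        frames = {"gedi": FrameImage(img), "morphology": FrameImage(img.copy())}
        assert roi_ratio(frames, mask) == pytest.approx(1.0)

    def test_zero_gedi_zero_ratio(self):
        img = disk_image((40, 40), [(20, 20, 6, 400.0)])
        mask = img > 0
        frames = {"gedi": FrameImage(np.zeros((40, 40))), "morphology": FrameImage(img)}
        assert roi_ratio(frames, mask) == 0.0

    def test_zero_morphology_rejected(self):
        img = disk_image((40, 40), [(20, 20, 6, 400.0)])
        mask = img > 0
        frames = {"gedi": FrameImage(img), "morphology": FrameImage(np.zeros((40, 40)))}
        with pytest.raises(ValueError):
            roi_ratio(frames, mask)
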