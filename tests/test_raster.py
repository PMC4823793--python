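import numpy as np
import pytest

from ishquant.errors import FormatError, ParameterError
from ishquant.points import SignalPoint
from ishquant.raster import (
    RasterImage,
    TissueMask,
    compute_tissue_mask,
    load_image,
    merge_tile_detections,
    preprocess,
    tile_image,
)


class TestLoadImage:
    def test_rgb_png_identity(self, tmp_path, rng):
        import imageio.v3 as iio

        arr = rng.integers(0, 256, size=(512, 512, 3), dtype=np.uint8)
        p = tmp_path / "img.png"
        iio.imwrite(p, arr)
        img = load_image(p)
        assert (img.width, img.height) == (512, 512)
        np.testing.assert_array_equal(img.pixels, arr)

    def test_grayscale_promoted_to_rgb(self, tmp_path, rng):
        import imageio.v3 as iio

        arr = rng.integers(0, 256, size=(64, 48), dtype=np.uint8)
        p = tmp_path / "gray.tif"
        iio.imwrite(p, arr)
        img = load_image(p)
        assert img.pixels.shape == (64, 48, 3)
        for c in range(3):
            np.testing.assert_array_equal(img.pixels[..., c], arr)

    def test_truncated_file_is_format_error(self, tmp_path):
        p = tmp_path / "broken.png"
        p.write_bytes(b"\x89PNG\r\n\x1a\n truncated")
        with pytest.raises(FormatError, match="broken.png"):
            load_image(p)

    def test_missing_file_is_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            load_image(tmp_path / "nope.png")


class TestPreprocess:
    def test_downscale_to_target(self, rng):
        img = RasterImage(rng.integers(0, 256, (512, 512, 3), dtype=np.uint8))
        out = preprocess(img, target_size=256)
        assert out.shape == (256, 256)

    def test_noop_at_target_size_is_pixel_identical(self, rng):
        px = rng.integers(0, 256, (128, 128, 3), dtype=np.uint8)
        out = preprocess(RasterImage(px), target_size=128)
        np.testing.assert_array_equal(out.pixels, px)

    def test_constant_field_stays_constant_under_bicubic(self):
        px = np.full((256, 256, 3), (120, 40, 200), dtype=np.uint8)
        out = preprocess(RasterImage(px), target_size=512)
        assert out.shape == (512, 512)
        # bicubic interpolation of a constant field is that constant
        np.testing.assert_array_equal(out.pixels, np.full((512, 512, 3), (120, 40, 200)))

    def test_too_small_target_rejected(self, rng):
        img = RasterImage(rng.integers(0, 256, (64, 64, 3), dtype=np.uint8))
        with pytest.raises(ParameterError):
            preprocess(img, target_size=32)

    def test_microns_per_pixel_rescaled(self):
        img = RasterImage(np.zeros((200, 200, 3), dtype=np.uint8), microns_per_pixel=0.11)
        out = preprocess(img, target_size=100)
        assert out.microns_per_pixel == pytest.approx(0.22)


class TestTissueMask:
    def test_pure_white_has_zero_coverage(self):
        img = RasterImage(np.full((128, 128, 3), 255, dtype=np.uint8))
        assert compute_tissue_mask(img).coverage_fraction == 0.0

    def test_planted_disk_coverage_recovered(self):
        # stained disk covering ~25% of the canvas
        h = w = 256
        yy, xx = np.ogrid[:h, :w]
        r = np.sqrt(0.25 * h * w / np.pi)
        disk = (xx - w / 2) ** 2 + (yy - h / 2) ** 2 <= r**2
        px = np.full((h, w, 3), 255, dtype=np.uint8)
        px[disk] = (190, 170, 200)
        cov = compute_tissue_mask(RasterImage(px)).coverage_fraction
        assert 0.20 <= cov <= 0.30

    def test_fully_stained_image(self):
        px = np.full((64, 64, 3), (200, 180, 210), dtype=np.uint8)
        assert compute_tissue_mask(RasterImage(px)).coverage_fraction >= 0.95


class TestTileImage:
    def test_4x4_grid_without_overlap(self):
        grid = tile_image((4096, 4096), 1024, 0)
        assert len(grid) == 16
        assert grid.tiles[0] == (0, 0, 1024, 1024)

    def test_small_image_single_clipped_tile(self):
        grid = tile_image((100, 100), 4096, 0)
        assert grid.tiles == [(0, 0, 100, 100)]

    def test_overlap_count_matches_stride_arithmetic(self):
        grid = tile_image((4096, 4096), 1024, 64)
        stride = 1024 - 64
        starts = [s for s in range(0, 4096, stride)]
        assert len(grid) == len(starts) ** 2

    def test_every_pixel_covered_exactly_once_without_overlap(self):
        h, w = 130, 97
        cover = np.zeros((h, w), dtype=int)
        for (x0, y0, x1, y1) in tile_image((h, w), 48, 0):
            cover[y0:y1, x0:x1] += 1
        np.testing.assert_array_equal(cover, 1)

    def test_overlap_tiles_cover_every_pixel(self):
        h, w = 200, 150
        cover = np.zeros((h, w), dtype=int)
        for (x0, y0, x1, y1) in tile_image((h, w), 64, 16):
            cover[y0:y1, x0:x1] += 1
        assert (cover >= 1).all()

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ParameterError):
            tile_image((100, 100), 32, 32)


def _brute_force_nms(points, min_sep):
    """O(n^2) greedy suppression by (strength desc, x, y) — the oracle."""
    kept = []
    for p in sorted(points, key=lambda q: (-q.strength, q.x, q.y)):
        if all((p.x - k.x) ** 2 + (p.y - k.y) ** 2 >= min_sep**2 for k in kept):
            kept.append(p)
    return kept


class TestMergeTileDetections:
    def test_identical_duplicate_collapses(self):
        p = SignalPoint(10, 10, 4, strength=2.0)
        assert len(merge_tile_detections([[p], [p]], 6.0)) == 1

    def test_distant_points_both_retained(self):
        a = SignalPoint(0, 0, 4, 1.0)
        b = SignalPoint(200, 0, 4, 1.0)
        assert len(merge_tile_detections([[a], [b]], 6.0)) == 2

    def test_matches_brute_force_oracle(self, rng):
        pts = [
            SignalPoint(float(x), float(y), 4.0, float(s))
            for x, y, s in zip(
                rng.uniform(0, 100, 150), rng.uniform(0, 100, 150), rng.uniform(0, 5, 150)
            )
        ]
        # duplicate a third of them with jitter, as overlap zones would
        dups = [p.shifted(rng.uniform(-1, 1), rng.uniform(-1, 1)) for p in pts[:50]]
        got = merge_tile_detections([pts, dups], 6.0)
        want = _brute_force_nms(pts + dups, 6.0)
        assert [(p.x, p.y, p.strength) for p in got] == [
            (p.x, p.y, p.strength) for p in want
        ]

    def test_order_invariance(self, rng):
        pts = [
            SignalPoint(float(x), float(y), 4.0, float(s))
            for x, y, s in zip(
                rng.uniform(0, 50, 80), rng.uniform(0, 50, 80), rng.uniform(0, 5, 80)
            )
        ]
        a = merge_tile_detections([pts], 5.0)
        b = merge_tile_detections([pts[::-1]], 5.0)
        assert [(p.x, p.y) for p in a] == [(p.x, p.y) for p in b]

    def test_no_retained_pair_closer_than_min_separation(self, rng):
        pts = [
            SignalPoint(float(x), float(y), 4.0, float(s))
            for x, y, s in zip(
                rng.uniform(0, 30, 200), rng.uniform(0, 30, 200), rng.uniform(0, 5, 200)
            )
        ]
        kept = merge_tile_detections([pts], 4.0)
        xy = np.array([(p.x, p.y) for p in kept])
        from scipy.spatial.distance import pdist

        assert len(kept) >= 1
        if len(kept) > 1:
            assert pdist(xy).min() >= 4.0
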