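"""Stack preprocessing, calibration, patch grids and heat-map extraction."""

import numpy as np
import pytest

from shgdir.optics import DetectionGeometry
from shgdir.stacks import (
    FLAG_INVALID,
    ImageStackPair,
    apply_calibration,
    compute_patch_grid,
    extract_ratio_heatmaps,
    patch_size_sweep,
    preprocess_stack,
    read_stack_pair,
)
from shgdir.synthetic import render_from_ratio_field


def make_pair(forward, backward, **kw):
    return ImageStackPair(forward=forward, backward=backward, **kw)


class TestPreprocess:
    def test_trims_ten_sections_each_end(self):
        pair = make_pair(np.ones((120, 8, 8)), np.ones((120, 8, 8)))
        out = preprocess_stack(pair, saturation_level=100.0, noise_filter="none")
        assert out.n_sections == 100
        assert out.depth_offset == 10.0

    def test_saturated_pixel_invalid_in_both_channels(self):
        fwd = np.ones((21, 8, 8)) * 5
        bwd = np.ones((21, 8, 8)) * 5
        fwd[10, 3, 3] = 300.0
        pair = make_pair(fwd, bwd)
        out = preprocess_stack(pair, saturation_level=255.0, noise_filter="none")
        assert np.isnan(out.forward[0, 3, 3])
        assert np.isnan(out.backward[0, 3, 3])
        assert np.isfinite(out.forward[0, 2, 2])

    def test_all_zero_stack_survives_trimming(self):
        pair = make_pair(np.zeros((30, 6, 6)), np.zeros((30, 6, 6)))
        out = preprocess_stack(pair, saturation_level=10.0, noise_filter="none", trim_sections=5)
        assert out.n_sections == 20
        assert np.all(out.forward == 0)

    def test_median_denoise_applied_to_both_channels(self):
        fwd = np.ones((25, 9, 9))
        bwd = np.ones((25, 9, 9))
        fwd[12, 4, 4] = 50.0  # isolated spike below saturation
        bwd[12, 4, 4] = 50.0
        pair = make_pair(fwd, bwd)
        out = preprocess_stack(pair, saturation_level=100.0, noise_filter="median3", trim_sections=10)
        assert out.forward[2, 4, 4] == 1.0
        assert out.backward[2, 4, 4] == 1.0

    def test_too_few_sections_rejected(self):
        pair = make_pair(np.ones((15, 4, 4)), np.ones((15, 4, 4)))
        with pytest.raises(ValueError):
            preprocess_stack(pair, saturation_level=10.0)

    def test_bad_saturation_level_rejected(self):
        pair = make_pair(np.ones((30, 4, 4)), np.ones((30, 4, 4)))
        with pytest.raises(ValueError):
            preprocess_stack(pair, saturation_level=0.0)


class TestCalibration:
    def test_identity_factor(self):
        pair = make_pair(np.full((3, 4, 4), 7.0), np.full((3, 4, 4), 2.0))
        out = apply_calibration(pair, DetectionGeometry(calibration_factor=1.0))
        assert np.array_equal(out.forward, pair.forward)

    def test_factor_two_halves_forward(self):
        pair = make_pair(np.full((2, 6, 6), 10.0), np.full((2, 6, 6), 5.0))
        out = apply_calibration(pair, DetectionGeometry(calibration_factor=2.0))
        grid = compute_patch_grid(out.forward[0], out.backward[0], patch_size=3)
        assert np.allclose(grid.measured_fb, 1.0)

    def test_calibration_commutes_with_patch_averaging(self):
        rng = np.random.default_rng(0)
        fwd = rng.poisson(20.0, (2, 30, 30)).astype(float)
        bwd = rng.poisson(10.0, (2, 30, 30)).astype(float)
        pair = make_pair(fwd, bwd)
        geom = DetectionGeometry(calibration_factor=1.7)
        before = compute_patch_grid(
            apply_calibration(pair, geom).forward[0],
            apply_calibration(pair, geom).backward[0],
            patch_size=10,
        ).measured_fb
        after = compute_patch_grid(pair.forward[0], pair.backward[0], 10).measured_fb / 1.7
        assert np.allclose(before, after)


class TestPatchGrid:
    def test_512_image_patch_30_gives_17x17(self):
        img = np.ones((512, 512))
        grid = compute_patch_grid(img * 8, img * 2, patch_size=30)
        assert grid.measured_fb.shape == (17, 17)

    def test_uniform_field_ratio(self):
        img = np.ones((60, 60))
        grid = compute_patch_grid(img * 8, img * 2, patch_size=30)
        assert np.allclose(grid.measured_fb, 4.0)
        assert grid.valid.all()

    def test_zero_backward_tile_invalid(self):
        fwd = np.ones((20, 20))
        bwd = np.ones((20, 20))
        bwd[:10, :10] = 0.0
        grid = compute_patch_grid(fwd, bwd, patch_size=10)
        assert not grid.valid[0, 0]
        assert np.isnan(grid.measured_fb[0, 0])
        assert grid.valid[1, 1]

    def test_low_valid_fraction_invalidates(self):
        fwd = np.ones((10, 10))
        fwd[:, :6] = np.nan
        grid = compute_patch_grid(fwd, np.ones((10, 10)), patch_size=10, min_valid_fraction=0.5)
        assert not grid.valid[0, 0]

    def test_patch_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            compute_patch_grid(np.ones((8, 8)), np.ones((8, 8)), patch_size=30)

    def test_frame_average_equals_patch_weighted_mean(self):
        """On a fully valid section, the frame measured F/B equals the
        patch-count-weighted combination of patch means (averaging
        consistency of the ratio-of-sums estimator)."""
        rng = np.random.default_rng(3)
        fwd = rng.poisson(30.0, (40, 40)).astype(float)
        bwd = rng.poisson(10.0, (40, 40)).astype(float)
        grid = compute_patch_grid(fwd, bwd, patch_size=10)
        frame = fwd.mean() / bwd.mean()
        weighted = grid.mean_forward.mean() / grid.mean_backward.mean()
        assert frame == pytest.approx(weighted, rel=1e-12)


class TestHeatMaps:
    def test_uniform_truth_recovered(self, lut_scatter):
        """A stack forward-rendered from a uniform creation ratio of 5
        inverts back to 5 everywhere, within the grid resolution."""
        field = np.full((90, 90), 5.0)
        depths = lut_scatter.depth_axis[4:8]
        pair = render_from_ratio_field(field, lut_scatter, depths)
        hm = extract_ratio_heatmaps(pair, lut_scatter, patch_size=30)
        assert np.all(hm.flags != FLAG_INVALID)
        assert np.nanmean(hm.ratios) == pytest.approx(5.0, abs=0.3)

    def test_two_region_step_recovered(self, lut_scatter):
        field = np.full((60, 60), 3.0)
        field[:, 30:] = 9.0
        depths = lut_scatter.depth_axis[5:7]
        pair = render_from_ratio_field(field, lut_scatter, depths)
        hm = extract_ratio_heatmaps(pair, lut_scatter, patch_size=30)
        left = hm.ratios[:, :, 0]
        right = hm.ratios[:, :, 1]
        assert np.nanmean(left) == pytest.approx(3.0, abs=0.3)
        assert np.nanmean(right) == pytest.approx(9.0, abs=0.5)

    def test_all_invalid_stack(self, lut_scatter):
        fwd = np.zeros((2, 60, 60))
        bwd = np.zeros((2, 60, 60))
        pair = make_pair(fwd, bwd, depth_offset=float(lut_scatter.depth_axis[4]))
        hm = extract_ratio_heatmaps(pair, lut_scatter, patch_size=30)
        assert np.all(hm.flags == FLAG_INVALID)
        assert np.all(np.isnan(hm.ratios))

    def test_flag_conservation(self, lut_scatter):
        rng = np.random.default_rng(8)
        fwd = rng.poisson(5.0, (3, 90, 90)).astype(float)
        bwd = rng.poisson(2.0, (3, 90, 90)).astype(float)
        bwd[:, :30, :30] = 0.0
        pair = make_pair(fwd, bwd, depth_offset=float(lut_scatter.depth_axis[4]))
        hm = extract_ratio_heatmaps(pair, lut_scatter, patch_size=30)
        counts = hm.flag_counts()
        assert sum(counts.values()) == hm.flags.size

    def test_depth_outside_table_rejected(self, lut_scatter):
        pair = make_pair(np.ones((2, 60, 60)), np.ones((2, 60, 60)), depth_offset=500.0)
        with pytest.raises(ValueError):
            extract_ratio_heatmaps(pair, lut_scatter)


class TestPatchSizeSweep:
    def test_single_pixel_fails_more_than_patch30(self, lut_scatter):
        """Poisson noise prohibits accurate per-pixel fits: the fit-failure
        fraction at patch size 1 exceeds that at 30."""
        field = np.full((90, 90), 5.0)
        depths = lut_scatter.depth_axis[4:6]
        pair = render_from_ratio_field(field, lut_scatter, depths, mean_counts=5.0, seed=4)
        sweep = patch_size_sweep(pair, lut_scatter, sizes=(1, 30))
        assert sweep[1].fit_failure_fraction > sweep[30].fit_failure_fraction

    def test_size_30_matches_direct_extraction(self, lut_scatter):
        field = np.full((60, 60), 4.0)
        depths = lut_scatter.depth_axis[4:6]
        pair = render_from_ratio_field(field, lut_scatter, depths)
        sweep = patch_size_sweep(pair, lut_scatter, sizes=(30,))
        direct = extract_ratio_heatmaps(pair, lut_scatter, patch_size=30)
        assert np.array_equal(
            sweep[30].heatmaps.ratios, direct.ratios, equal_nan=True
        )

    def test_noiseless_uniform_stack_size_invariant(self, lut_scatter):
        field = np.full((60, 60), 6.0)
        depths = lut_scatter.depth_axis[4:6]
        pair = render_from_ratio_field(field, lut_scatter, depths)
        sweep = patch_size_sweep(pair, lut_scatter, sizes=(10, 20, 30))
        means = [np.nanmean(e.heatmaps.ratios) for e in sweep.values()]
        assert np.ptp(means) < 1e-6


def test_tiff_round_trip(tmp_path, lut_scatter):
    import tifffile

    rng = np.random.default_rng(1)
    fwd = rng.poisson(20.0, (3, 32, 32)).astype(np.float32)
    bwd = rng.poisson(10.0, (3, 32, 32)).astype(np.float32)
    tifffile.imwrite(tmp_path / "f.tif", fwd)
    tifffile.imwrite(tmp_path / "b.tif", bwd)
    pair = read_stack_pair(tmp_path / "f.tif", tmp_path / "b.tif", depth_offset=20.0)
    assert pair.n_sections == 3
    assert np.allclose(pair.forward, fwd)
    assert pair.depths[0] == 20.0
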