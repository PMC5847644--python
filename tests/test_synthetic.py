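"""Synthetic tissue generator: presets, fields, dk calibration, rendering."""

import dataclasses

import numpy as np
import pytest

from shgdir.fibers import extract_fiber_widths
from shgdir.phase_matching import DirectionalityMap
from shgdir.stacks import extract_ratio_heatmaps
from shgdir.synthetic import (
    CLASS_ORDER,
    assign_dk_and_ratio,
    calibrate_dk_distribution,
    default_profiles,
    generate_cohort,
    generate_fiber_field,
    generate_volume,
    render_stack,
)

DMAP = DirectionalityMap()
PROFILES = default_profiles(DMAP)


class TestProfiles:
    def test_ratio_moments_match_configured_table(self):
        assert PROFILES["HGS"].ratio_mean == 2.7
        assert PROFILES["HGS"].ratio_sd == 1.7
        assert PROFILES["benign"].ratio_mean == 8.8
        assert PROFILES["normal"].ratio_mean == 4.0
        assert PROFILES["LGS"].ratio_sd == 3.5

    def test_all_presets_valid(self):
        for label in CLASS_ORDER:
            p = PROFILES[label]
            assert 0 < p.fiber_density <= 1
            assert p.width_sd >= 0 and p.dk_sd >= 0
            assert 1.0 <= p.ratio_mean <= 19.9

    def test_dk_calibration_reproduces_ratio_moments(self):
        """Folded-normal dk parameters reproduce each class's target ratio
        mean (tight) and SD (loose) under the directionality map."""
        rng = np.random.default_rng(0)
        z = rng.standard_normal(200_000)
        for label in CLASS_ORDER:
            p = PROFILES[label]
            ratios = DMAP.ratio_of_dk(np.abs(p.dk_center + p.dk_sd * z))
            assert ratios.mean() == pytest.approx(p.ratio_mean, abs=0.1)
            assert ratios.std() == pytest.approx(p.ratio_sd, rel=0.25)

    def test_unreachable_mean_rejected(self):
        with pytest.raises(ValueError):
            calibrate_dk_distribution(25.0, 1.0, DMAP)


class TestFiberField:
    def test_zero_density_empty_field(self):
        profile = dataclasses.replace(PROFILES["normal"], fiber_density=0.0)
        truth = generate_fiber_field(profile, (64, 64), seed=0)
        assert truth.n_fibers == 0
        assert not truth.fiber_labels.any()

    def test_seed_determinism(self):
        a = generate_fiber_field(PROFILES["HGS"], (128, 128), seed=5)
        b = generate_fiber_field(PROFILES["HGS"], (128, 128), seed=5)
        assert np.array_equal(a.fiber_labels, b.fiber_labels)

    def test_density_reached(self):
        truth = generate_fiber_field(PROFILES["HGS"], (128, 128), seed=1)
        assert truth.realized_density >= 0.95 * PROFILES["HGS"].fiber_density

    def test_width_recovery_round_trip(self):
        """The skeleton estimator recovers the configured mean width within
        2 SE over >= 100 fibers accumulated across seeded fields."""
        widths = []
        for seed in range(8):
            truth = generate_fiber_field(PROFILES["normal"], (256, 256), seed=seed)
            records = extract_fiber_widths(
                truth.fiber_labels > 0, pixel_size=170.0 / 512.0
            )
            widths += [r.mean_width for r in records]
        widths = np.asarray(widths)
        assert widths.size >= 100
        se = widths.std(ddof=1) / np.sqrt(widths.size)
        # the estimator sees bundles where fibers overlap; allow 2 SE + half
        # a pixel of rasterization bias
        assert abs(widths.mean() - PROFILES["normal"].width_mean) <= 2 * se + 0.17

    def test_small_field_rejected(self):
        with pytest.raises(ValueError):
            generate_fiber_field(PROFILES["normal"], (32, 32), seed=0)


class TestAssignDk:
    def test_zero_dispersion_constant_field(self):
        profile = dataclasses.replace(PROFILES["normal"], dk_sd=0.0)
        truth = generate_fiber_field(profile, (128, 128), seed=2)
        truth = assign_dk_and_ratio(truth, profile, DMAP, seed=3)
        on = np.isfinite(truth.ratio_field)
        assert np.allclose(truth.ratio_field[on], profile.ratio_mean)

    @pytest.mark.parametrize("label", CLASS_ORDER)
    def test_realized_mean_within_tolerance(self, label):
        """The re-centered dk draw pins the realized (pixel-weighted) mean
        creation ratio of the field to the class target within 0.1."""
        profile = PROFILES[label]
        truth = generate_fiber_field(profile, (192, 192), seed=4)
        truth = assign_dk_and_ratio(truth, profile, DMAP, seed=5)
        assert np.nanmean(truth.ratio_field) == pytest.approx(profile.ratio_mean, abs=0.1)

    def test_lgs_ratio_spread_at_least_hgs(self):
        spreads = {}
        for label in ("LGS", "HGS"):
            truth = generate_fiber_field(PROFILES[label], (256, 256), seed=6)
            truth = assign_dk_and_ratio(truth, PROFILES[label], DMAP, seed=7)
            spreads[label] = np.nanstd(truth.fiber_ratio)
        assert spreads["LGS"] >= spreads["HGS"]

    def test_unreachable_target_rejected(self):
        profile = dataclasses.replace(
            PROFILES["benign"], ratio_mean=19.5, dk_sd=3.0
        )
        truth = generate_fiber_field(profile, (128, 128), seed=8)
        with pytest.raises(ValueError):
            assign_dk_and_ratio(truth, profile, DMAP, seed=9)


class TestRenderStack:
    def test_seed_determinism(self, lut_scatter):
        kwargs = dict(n_sections=4, mean_counts=30.0, seed=11)
        truth = generate_fiber_field(PROFILES["HGS"], (96, 96), seed=10)
        truth = assign_dk_and_ratio(truth, PROFILES["HGS"], DMAP, seed=10)
        a = render_stack(truth, PROFILES["HGS"], lut_scatter, **kwargs)
        b = render_stack(truth, PROFILES["HGS"], lut_scatter, **kwargs)
        assert np.array_equal(a.forward, b.forward)
        assert np.array_equal(a.backward, b.backward)

    def test_noise_free_uniform_ratio_round_trip(self, lut_scatter):
        """Noise off, uniform creation ratio 5: heat maps recover 5.0."""
        profile = dataclasses.replace(
            PROFILES["HGS"], dk_sd=0.0, ratio_mean=5.0, width_sd=0.0
        )
        truth = generate_fiber_field(profile, (90, 90), seed=12)
        truth = assign_dk_and_ratio(truth, profile, DMAP, seed=13)
        pair = render_stack(
            truth, profile, lut_scatter, n_sections=4, mean_counts=100.0,
            seed=14, noise=False, jitter_px=0, dark_fraction=0.0,
        )
        hm = extract_ratio_heatmaps(pair, lut_scatter, patch_size=30)
        assert np.nanmean(hm.valid_ratios()) == pytest.approx(5.0, abs=0.3)

    def test_unassigned_truth_rejected(self, lut_scatter):
        truth = generate_fiber_field(PROFILES["HGS"], (96, 96), seed=15)
        with pytest.raises(ValueError):
            render_stack(truth, PROFILES["HGS"], lut_scatter)

    def test_noise_scaling_reduces_patch_variance(self, lut_scatter):
        """Per-patch ratio variance falls monotonically as the detected
        count budget grows (Poisson contract).  Measured on a uniform
        ground-truth field so shot noise is the only variance source."""
        from shgdir.synthetic import render_from_ratio_field

        field = np.full((90, 90), 5.0)
        depths = lut_scatter.depth_axis[4:10]
        spreads = []
        for counts in (20.0, 200.0, 2000.0):
            pair = render_from_ratio_field(
                field, lut_scatter, depths, mean_counts=counts, seed=18
            )
            hm = extract_ratio_heatmaps(pair, lut_scatter, patch_size=30)
            # per-section variance: within a section every patch shares the
            # same lookup row, so shot noise is the only spread
            per_section = [
                np.var(hm.ratios[k][hm.flags[k] == "ok"])
                for k in range(hm.ratios.shape[0])
            ]
            spreads.append(np.mean(per_section))
        assert spreads[0] > spreads[1] > spreads[2]


class TestCohort:
    def test_counts_and_manifest_determinism(self, lut_scatter, tmp_path):
        profiles = {k: PROFILES[k] for k in ("normal", "HGS")}
        out = tmp_path / "cohort"
        _, m1 = generate_cohort(
            profiles, lut_scatter, DMAP, n_volumes_per_class=2,
            shape=(96, 96), n_sections=3, seed=21, out_dir=out,
        )
        _, m2 = generate_cohort(
            profiles, lut_scatter, DMAP, n_volumes_per_class=2,
            shape=(96, 96), n_sections=3, seed=21,
        )
        assert m1["hash"] == m2["hash"]
        tifs = list(out.glob("*.tif"))
        assert len(tifs) == 2 * 2 * 3  # 2 classes x 2 volumes x (F, B, truth)
        assert (out / "manifest.json").exists()

    def test_volume_generation_composes(self, lut_scatter):
        pair, truth = generate_volume(
            PROFILES["endometrioid"], lut_scatter, DMAP,
            shape=(96, 96), n_sections=3, seed=22,
        )
        assert pair.forward.shape == (3, 96, 96)
        assert truth.fiber_ratio is not None
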