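"""Ratiometric measurement chain: projection, background estimation,
per-cell means, ratios, per-neuromast normalization, label retention,
and aggregation conventions."""

import numpy as np
import pandas as pd
import pytest

from hcmito.errors import ConfigError, UndefinedRatioError
from hcmito.ratiometric import (ChannelStack, RegionSet,
                                aggregate_per_fish,
                                area_normalized_nuclear_intensity,
                                background_square_slices, call_label_retention,
                                cell_mean_intensity, estimate_background,
                                max_project, measure_stack,
                                normalize_to_neuromast_median,
                                percent_of_control, red_green_ratio)
from hcmito.synth import generate_cell_cohort, generate_neuromast_stack


def tiny_stack(red, green):
    return ChannelStack(channels={"red": np.asarray(red, float),
                                  "green": np.asarray(green, float)},
                        pixel_size_xy=1.0, z_step=2.0)


class TestMaxProject:
    def test_elementwise_max(self):
        stack = tiny_stack([[[1, 5], [3, 2]], [[2, 1], [0, 9]]],
                           np.zeros((2, 2, 2)))
        assert np.array_equal(max_project(stack)["red"], [[2, 5], [3, 9]])

    def test_single_plane_identity(self):
        arr = np.arange(6.0).reshape(1, 2, 3)
        stack = tiny_stack(arr, arr)
        assert np.array_equal(max_project(stack)["red"], arr[0])

    def test_invariant_to_z_permutation(self, rng):
        arr = rng.random((5, 4, 4))
        a = max_project(tiny_stack(arr, arr))["red"]
        b = max_project(tiny_stack(arr[::-1], arr[::-1]))["red"]
        assert np.array_equal(a, b)

    def test_mismatched_channel_shapes_rejected(self):
        with pytest.raises(ConfigError):
            tiny_stack(np.zeros((2, 3, 3)), np.zeros((2, 4, 4)))


def region_with_background(labels, bg=(slice(0, 2), slice(0, 2))):
    return RegionSet(cell_labels=np.asarray(labels, dtype=np.int32),
                     background_slices=bg)


class TestBackground:
    def test_uniform_image(self):
        regions = region_with_background(np.zeros((4, 4), int))
        mean, sd = estimate_background(np.full((4, 4), 7.0), regions)
        assert (mean, sd) == (7.0, 0.0)

    def test_two_pixel_sample_sd(self):
        # {4, 6}: mean 5, sample SD (n-1 denominator) sqrt(2)
        regions = RegionSet(cell_labels=np.zeros((1, 2), int),
                            background_slices=(slice(0, 1), slice(0, 2)))
        img = np.array([[4.0, 6.0]])
        mean, sd = estimate_background(img, regions)
        assert mean == 5.0 and sd == pytest.approx(np.sqrt(2))

    def test_region_overlapping_cell_rejected(self):
        labels = np.zeros((4, 4), int)
        labels[0, 0] = 3
        with pytest.raises(ConfigError):
            region_with_background(labels)

    def test_square_side_from_pixel_size(self):
        sl = background_square_slices((100, 100), (0, 0), pixel_size_xy=0.5)
        assert sl[0].stop - sl[0].start == 60  # 30 um / 0.5 um

    def test_square_must_fit(self):
        with pytest.raises(ConfigError):
            background_square_slices((40, 40), (0, 0), pixel_size_xy=0.5)


class TestCellMean:
    def test_background_subtraction(self):
        img = np.full((3, 3), 10.0)
        mask = np.ones((3, 3), bool)
        assert cell_mean_intensity(img, mask, 4.0) == 6.0

    def test_mean_equal_to_background_is_zero(self):
        img = np.full((2, 2), 4.0)
        assert cell_mean_intensity(img, np.ones((2, 2), bool), 4.0) == 0.0

    def test_negative_propagates_unless_clipped(self):
        img = np.full((2, 2), 3.0)
        mask = np.ones((2, 2), bool)
        assert cell_mean_intensity(img, mask, 5.0) == -2.0
        assert cell_mean_intensity(img, mask, 5.0, clip_negative=True) == 0.0

    def test_constant_offset_cancels(self, rng):
        img = rng.random((6, 6))
        mask = np.zeros((6, 6), bool)
        mask[2:4, 2:4] = True
        a = cell_mean_intensity(img, mask, 0.2)
        b = cell_mean_intensity(img + 5.0, mask, 5.2)
        assert a == pytest.approx(b)


class TestRatio:
    def test_basic(self):
        assert red_green_ratio(5.0, 2.5) == 2.0

    def test_zero_red(self):
        assert red_green_ratio(0.0, 2.0) == 0.0

    @pytest.mark.parametrize("green", [0.0, -1.0])
    def test_nonpositive_green_rejected(self, green):
        with pytest.raises(UndefinedRatioError):
            red_green_ratio(1.0, green)


class TestMedianNormalization:
    def test_simple_neuromast(self):
        df = pd.DataFrame({"neuromast_id": ["a"] * 3, "ratio": [2.0, 4.0, 8.0]})
        assert list(normalize_to_neuromast_median(df)) == [0.5, 1.0, 2.0]

    def test_single_cell_self_median(self):
        df = pd.DataFrame({"neuromast_id": ["a"], "ratio": [3.7]})
        assert list(normalize_to_neuromast_median(df)) == [1.0]

    def test_groups_independent_and_order_invariant(self, rng):
        df = pd.DataFrame({
            "neuromast_id": ["a"] * 5 + ["b"] * 7,
            "ratio": rng.lognormal(0, 0.4, 12)})
        out = normalize_to_neuromast_median(df)
        shuffled = df.sample(frac=1, random_state=0)
        out_shuffled = normalize_to_neuromast_median(shuffled).sort_index()
        assert np.allclose(out, out_shuffled)
        for _, grp in df.assign(norm=out).groupby("neuromast_id"):
            assert np.median(grp.norm) == pytest.approx(1.0)

    def test_nonpositive_median_rejected(self):
        df = pd.DataFrame({"neuromast_id": ["a"] * 3,
                           "ratio": [-1.0, 0.0, 0.5]})
        with pytest.raises(ConfigError):
            normalize_to_neuromast_median(df)


class TestLabelRetention:
    @pytest.mark.parametrize("intensity,mean,sd,expect", [
        (10.0, 5.0, 4.0, True),    # 10 > 9
        (9.0, 5.0, 4.0, False),    # strict inequality at the boundary
        (5.1, 5.0, 0.0, True),     # sd 0: anything above the mean retains
    ])
    def test_one_sd_rule(self, intensity, mean, sd, expect):
        assert call_label_retention(intensity, mean, sd) is expect

    def test_negative_sd_rejected(self):
        with pytest.raises(ConfigError):
            call_label_retention(1.0, 0.0, -0.1)


class TestNuclearIntensity:
    def test_area_normalization(self):
        img = np.zeros((4, 4))
        mask = np.zeros((4, 4), bool)
        mask[:2, :2] = True
        img[mask] = 12.0
        norm, raw = area_normalized_nuclear_intensity(img, mask, 0.0)
        assert raw == 12.0 and norm == 3.0

    def test_doubling_area_halves_output(self):
        img = np.full((4, 4), 8.0)
        m1 = np.zeros((4, 4), bool); m1[:1, :2] = True
        m2 = np.zeros((4, 4), bool); m2[:2, :2] = True
        n1, _ = area_normalized_nuclear_intensity(img, m1, 0.0)
        n2, _ = area_normalized_nuclear_intensity(img, m2, 0.0)
        assert n1 == pytest.approx(2 * n2)

    def test_empty_mask_rejected(self):
        with pytest.raises(ConfigError):
            area_normalized_nuclear_intensity(np.zeros((2, 2)),
                                              np.zeros((2, 2), bool), 0.0)


class TestGroupScaling:
    def test_percent_of_control(self):
        out = percent_of_control([0.4, 0.2264], control_mean=0.4)
        assert out == pytest.approx([100.0, 56.6])

    def test_control_group_maps_to_mean_100(self, rng):
        control = rng.random(10) + 0.5
        out = percent_of_control(control, control.mean())
        assert out.mean() == pytest.approx(100.0)

    def test_unit_change_invariance(self, rng):
        vals = rng.random(5) + 0.1
        a = percent_of_control(vals, 0.7)
        b = percent_of_control(vals * 1e3, 0.7e3)
        assert np.allclose(a, b)

    def test_aggregate_per_fish(self):
        df = pd.DataFrame({"fish_id": ["f1"] * 3 + ["f2"],
                           "value": [0.2, 0.3, 0.25, 0.9]})
        out = aggregate_per_fish(df, "value")
        assert out["f1"] == pytest.approx(0.25)
        assert out["f2"] == pytest.approx(0.9)

    def test_per_fish_aggregation_reduces_spread(self, small_cohort_config):
        cohort, _ = generate_cell_cohort(small_cohort_config)
        per_nm = cohort.groupby(["fish_id", "neuromast_id"],
                                as_index=False)["normalized_ratio"].mean()
        per_fish = aggregate_per_fish(per_nm, "normalized_ratio")
        assert per_fish.std() <= per_nm["normalized_ratio"].std() + 1e-12


class TestRenderAndRemeasure:
    def test_noise_free_ratio_closure(self, noise_free_stack_config):
        """Measured per-cell red:green ratios on a noise-free render
        equal the generator's true ratios within 1%."""
        cohort, _ = generate_cell_cohort(noise_free_stack_config)
        stack, regions, truth = generate_neuromast_stack(
            noise_free_stack_config, cohort)
        cells = measure_stack(stack, regions)
        merged = cells.merge(truth.placements, on="cell_id")
        assert len(merged) == len(truth.placements)
        rel = np.abs(merged.ratio / merged.true_ratio - 1.0)
        assert rel.max() < 0.01

    def test_background_estimate_recovers_configured_level(
            self, noise_free_stack_config):
        cohort, _ = generate_cell_cohort(noise_free_stack_config)
        stack, regions, _ = generate_neuromast_stack(
            noise_free_stack_config, cohort)
        proj = max_project(stack)
        mean, sd = estimate_background(proj["green"], regions)
        assert mean == pytest.approx(
            noise_free_stack_config.image_params.background_level)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_channel_offset_cancels_in_ratio(self, noise_free_stack_config):
        """Adding one constant to both channels leaves measured ratios
        unchanged (background subtraction is exact in noise-free data)."""
        cohort, _ = generate_cell_cohort(noise_free_stack_config)
        stack, regions, _ = generate_neuromast_stack(
            noise_free_stack_config, cohort)
        a = measure_stack(stack, regions)
        shifted = ChannelStack(
            channels={ch: arr + 50.0 for ch, arr in stack.channels.items()},
            pixel_size_xy=stack.pixel_size_xy, z_step=stack.z_step)
        b = measure_stack(shifted, regions)
        assert np.allclose(a.ratio, b.ratio)

    def test_hoechst_calls_match_ground_truth(self, noise_free_stack_config):
        cohort, _ = generate_cell_cohort(noise_free_stack_config)
        stack, regions, truth = generate_neuromast_stack(
            noise_free_stack_config, cohort)
        cells = measure_stack(stack, regions)
        merged = cells.merge(truth.placements, on="cell_id",
                             suffixes=("_measured", "_true"))
        assert (merged.hoechst_measured == merged.hoechst_true).all()

    def test_undefined_ratio_accounting(self):
        """Cells whose green mean is non-positive are excluded with a
        logged count; included + excluded = input."""
        red = np.full((1, 80, 80), 5.0)
        green = np.zeros((1, 80, 80))
        labels = np.zeros((80, 80), dtype=np.int32)
        labels[2:6, 2:6] = 1
        labels[10:14, 2:6] = 2
        green[0, 2:6, 2:6] = 4.0   # cell 1 has signal; cell 2 does not
        stack = ChannelStack(channels={"red": red, "green": green},
                             pixel_size_xy=1.0, z_step=1.0)
        regions = RegionSet(cell_labels=labels,
                            background_slices=(slice(40, 70), slice(40, 70)))
        cells = measure_stack(stack, regions)
        n_excl = cells.attrs["n_excluded_undefined_ratio"]
        assert n_excl == 1
        assert cells.ratio.notna().sum() + n_excl == len(cells)
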