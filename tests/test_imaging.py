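"""Grayscale quantification chain on synthetic stacks with known ground truth."""

import numpy as np
import pytest

import telediff as td
from telediff.imaging import (
    annulus_mask,
    center_mean,
    corner_mask,
    estimate_background,
    extract_cross_section,
    find_center,
    normalize_stack,
    pseudocolor_enhance,
    subtract_invert,
)


def synthetic_spot_frame(shape=(101, 101), background=200.0, depth=150.0,
                         sigma_px=12.0, center=None):
    """Gaussian dark spot on a light background, float levels."""
    H, W = shape
    if center is None:
        center = ((H - 1) / 2, (W - 1) / 2)
    rows, cols = np.indices(shape)
    r2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    return background - depth * np.exp(-r2 / (2 * sigma_px**2))


class TestBackground:
    def test_uniform_frame(self):
        frame = np.full((50, 50), 200.0)
        assert estimate_background(frame, corner_mask(frame.shape)) == 200.0

    def test_annulus_excluding_spot(self):
        frame = np.full((101, 101), 200.0)
        frame[40:60, 40:60] = 50.0
        region = annulus_mask(frame.shape, (50, 50), 35, 48)
        assert estimate_background(frame, region) == 200.0

    def test_noisy_estimate_within_three_sigma(self):
        rng = np.random.default_rng(3)
        b, sigma = 180.0, 2.0
        frame = b + rng.normal(0, sigma, (200, 200))
        region = corner_mask(frame.shape, 0.2)
        n = region.sum()
        assert abs(estimate_background(frame, region) - b) < 3 * sigma / np.sqrt(n)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_background(np.ones((4, 4)), np.zeros((4, 4), bool))


class TestSubtractInvert:
    def test_piecewise_behaviour(self):
        frame = np.array([[200.0, 150.0, 210.0]])
        out = subtract_invert(frame, 200.0)
        assert out[0, 0] == 0.0  # at background
        assert out[0, 1] == 50.0  # darker -> positive
        assert out[0, 2] == 0.0  # brighter than background clips


class TestFindCenter:
    def test_symmetric_spot_centroid(self):
        frame = synthetic_spot_frame()
        m = subtract_invert(frame, 200.0)
        row, col = find_center(m)
        assert abs(row - 50.0) < 0.5 and abs(col - 50.0) < 0.5

    def test_translation_equivariance(self):
        m1 = subtract_invert(synthetic_spot_frame(center=(50, 50)), 200.0)
        m2 = subtract_invert(synthetic_spot_frame(center=(55, 47)), 200.0)
        c1, c2 = find_center(m1), find_center(m2)
        assert c2[0] - c1[0] == pytest.approx(5.0, abs=0.5)
        assert c2[1] - c1[1] == pytest.approx(-3.0, abs=0.5)

    def test_uniform_map_gives_geometric_center(self):
        row, col = find_center(np.ones((11, 21)))
        assert (row, col) == pytest.approx((5.0, 10.0))

    def test_all_zero_map_rejected(self):
        with pytest.raises(ValueError):
            find_center(np.zeros((5, 5)))


class TestCrossSection:
    def test_profile_matches_generator_ground_truth(self):
        frame = synthetic_spot_frame()
        m = subtract_invert(frame, 200.0)
        prof = extract_cross_section(m, (50.0, 50.0), pixel_size=0.01, halfwidth=0)
        expected = 150.0 * np.exp(-((np.arange(101) - 50.0) ** 2) / (2 * 12.0**2))
        assert np.max(np.abs(prof.values - expected)) <= 1.0
        assert prof.positions[50] == pytest.approx(0.0)

    def test_axisymmetric_map_gives_symmetric_profile(self, ic):
        spec = td.AcquisitionSpec(pixel_size=0.05, frame_shape=(200, 200),
                                  noise_sigma=0.0, duration=30.0)
        stack, _ = td.synth_image_stack(td.TransportParams(4e-5, 1.0, 1.5e-4), ic, spec)
        m = subtract_invert(stack.frames[0], 200.0)
        prof = extract_cross_section(m, (99.5, 99.5), stack.pixel_size)
        # mirror about the inter-pixel center: |P(x) - P(-x)| within quantization
        assert np.max(np.abs(prof.values - prof.values[::-1])) <= 2.0

    def test_all_zero_map_yields_zero_profile(self):
        prof = extract_cross_section(np.zeros((11, 11)), (5, 5), 0.01)
        assert np.all(prof.values == 0.0)

    def test_center_outside_frame_rejected(self):
        with pytest.raises(ValueError):
            extract_cross_section(np.ones((10, 10)), (20, 5), 0.01)


class TestCenterMean:
    def test_uniform_map(self):
        assert center_mean(np.full((30, 30), 7.0), (15, 15), 238) == 7.0

    def test_single_pixel_is_center_value(self):
        m = np.zeros((11, 11))
        m[5, 5] = 3.0
        assert center_mean(m, (5, 5), 1) == 3.0

    def test_radially_decreasing_map_bounds(self):
        m = subtract_invert(synthetic_spot_frame(), 200.0)
        assert center_mean(m, (50, 50), 238) <= m[50, 50]

    def test_oversized_disk_rejected(self):
        with pytest.raises(ValueError):
            center_mean(np.ones((5, 5)), (2, 2), 26)


class TestNormalization:
    def test_reference_frame_normalizes_to_unity(self, stack_bundle):
        _stack, _gt, quant = stack_bundle
        assert quant.trace.values[0] == pytest.approx(1.0)

    def test_gain_invariance(self):
        maps = [np.full((8, 8), 30.0), np.full((8, 8), 15.0)]
        centers = [30.0, 15.0]
        _n1, t1 = normalize_stack(maps, centers)
        _n2, t2 = normalize_stack([2 * m for m in maps], [2 * c for c in centers])
        assert np.allclose(t1, t2)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_stack([np.zeros((4, 4))], [0.0])


class TestPseudocolor:
    def test_background_maps_to_zero_darkest_to_one(self):
        frame = np.array([[200.0, 0.0, 100.0]])
        out = pseudocolor_enhance(frame, 200.0)
        assert out[0, 0] == 0.0
        assert out[0, 1] == 1.0
        assert 0.0 < out[0, 2] < 1.0

    def test_monotone_in_darkness(self):
        levels = np.linspace(0, 200, 50)[None, :]
        out = pseudocolor_enhance(levels, 200.0)
        assert np.all(np.diff(out[0]) <= 0)


class TestRoundTrip:
    def test_center_trace_recovered_within_tolerance(self, stack_bundle):
        _stack, gt, quant = stack_bundle
        truth = td.ground_truth_center_trace(gt)
        assert np.max(np.abs(quant.trace.values - truth.values)) < 0.02

    def test_radial_profile_recovered_within_tolerance(self, stack_bundle):
        # apply the same cross-section operator to the noiseless ground truth
        _stack, gt, quant = stack_bundle
        prof = quant.profiles[0]
        row = int(round(quant.center[0]))
        truth_rows = gt.conc_frames[0][row - 1 : row + 2].mean(axis=0)
        H, W = gt.conc_frames[0].shape
        ref = center_mean(gt.conc_frames[0], ((H - 1) / 2, (W - 1) / 2), 238)
        assert np.max(np.abs(prof.values - truth_rows / ref)) < 0.03

    def test_contrast_rescaling_leaves_normalized_trace_unchanged(self, ic):
        spec_a = td.AcquisitionSpec(pixel_size=0.05, frame_shape=(200, 200),
                                    noise_sigma=0.0, contrast=150.0, duration=60.0)
        spec_b = td.AcquisitionSpec(pixel_size=0.05, frame_shape=(200, 200),
                                    noise_sigma=0.0, contrast=100.0, duration=60.0)
        p = td.TransportParams(4e-5, 1.0, 1.5e-4)
        qa = td.quantify(td.synth_image_stack(p, ic, spec_a)[0])
        qb = td.quantify(td.synth_image_stack(p, ic, spec_b)[0])
        assert np.max(np.abs(qa.trace.values - qb.trace.values)) < 0.02
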