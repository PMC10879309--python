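import dataclasses

import numpy as np
import pytest

from synergidca import (ExtractionConfig, ImageStack, SceneConfig, clean,
                        compute_ratio_trace, estimate_and_correct_drift,
                        extract_traces, render_stack, subtract_pollen)
from synergidca.errors import ConfigError, ContractError


def flat_stack(t=3, h=12, w=12, cfp=100.0, yfp=200.0, red=0.0):
    pixels = np.zeros((t, 3, h, w))
    pixels[:, 0] = cfp
    pixels[:, 1] = yfp
    pixels[:, 2] = red
    return ImageStack(pixels=pixels)


SQUARE = np.array([[2.0, 2.0], [9.0, 2.0], [9.0, 9.0], [2.0, 9.0]])


class TestSubtractPollen:
    def test_unit_coefficient_arithmetic(self):
        stack = flat_stack(yfp=150.0, red=50.0)
        out = subtract_pollen(stack, ExtractionConfig(bleed_coefficient=1.0))
        assert np.all(out.channel("YFP") == 100.0)
        assert np.all(out.channel("CFP") == 50.0)
        assert np.all(out.channel("RED") == 50.0)   # RED untouched

    def test_zero_red_leaves_stack_unchanged(self):
        stack = flat_stack(red=0.0)
        out = subtract_pollen(stack, ExtractionConfig())
        assert np.array_equal(out.pixels, stack.pixels)

    def test_result_clipped_at_zero(self):
        stack = flat_stack(cfp=10.0, red=50.0)
        out = subtract_pollen(stack, ExtractionConfig(bleed_coefficient=1.0))
        assert out.channel("CFP").min() == 0.0

    def test_negative_coefficient_rejected(self):
        with pytest.raises(ConfigError):
            ExtractionConfig(bleed_coefficient=-0.1)


class TestClean:
    def test_single_hot_pixel_replaced_by_neighbourhood_median(self):
        stack = flat_stack(cfp=100.0)
        stack.pixels[1, 0, 6, 6] = 10000.0
        out = clean(stack, ExtractionConfig(outlier_threshold=50.0))
        assert out.pixels[1, 0, 6, 6] == 100.0

    def test_flat_field_is_a_fixed_point(self):
        stack = flat_stack()
        out = clean(stack, ExtractionConfig())
        assert np.array_equal(out.pixels, stack.pixels)
        again = clean(out, ExtractionConfig())
        assert np.array_equal(again.pixels, out.pixels)

    def test_dim_pixels_are_not_touched_by_outlier_pass(self):
        stack = flat_stack(cfp=100.0)
        stack.pixels[0, 0, 4, 4] = 0.0     # dark speckle: outlier pass skips,
        out = clean(stack, ExtractionConfig())
        assert out.pixels[0, 0, 4, 4] == 100.0   # despeckle removes it


class TestRatioTrace:
    def test_constant_channels_give_constant_ratio(self):
        stack = flat_stack(cfp=100.0, yfp=200.0)
        trace = compute_ratio_trace(stack, SQUARE, ExtractionConfig())
        assert np.allclose(trace.ratio, 2.0)

    def test_common_gain_invariance(self):
        stack = flat_stack(cfp=100.0, yfp=170.0)
        scaled = ImageStack(pixels=stack.pixels.copy())
        scaled.pixels[:, :2] *= 3.7
        cfg = ExtractionConfig()
        t1 = compute_ratio_trace(stack, SQUARE, cfg)
        t2 = compute_ratio_trace(scaled, SQUARE, cfg)
        assert np.allclose(t1.ratio, t2.ratio)

    def test_contact_frame_sets_time_zero(self):
        stack = flat_stack(t=5)
        trace = compute_ratio_trace(stack, SQUARE, ExtractionConfig(),
                                    contact_frame=2)
        assert trace.time_s[2] == 0.0
        assert trace.time_s[0] == -2 * stack.frame_interval_s

    def test_empty_roi_rejected(self):
        stack = flat_stack()
        tiny = np.array([[0.1, 0.1], [0.2, 0.1], [0.2, 0.2]])
        with pytest.raises(ContractError):
            compute_ratio_trace(stack, tiny, ExtractionConfig())

    def test_low_signal_frames_flagged(self):
        stack = flat_stack(cfp=0.5, yfp=10.0)   # CFP below the floor everywhere
        with pytest.warns(UserWarning, match="low-signal"):
            trace = compute_ratio_trace(stack, SQUARE, ExtractionConfig())
        assert trace.low_signal.all()


class TestDriftCorrection:
    @pytest.fixture()
    def drifting_scene(self, wt_pair, noiseless_scene):
        left, right, _, _ = wt_pair
        scene = dataclasses.replace(noiseless_scene,
                                    drift_per_frame=(1.0, 0.0))
        return left, right, scene

    def test_known_integer_drift_recovered(self, drifting_scene):
        left, right, scene = drifting_scene
        stack, _, truth = render_stack(left, right, scene, seed=11)
        corrected, offsets = estimate_and_correct_drift(stack)
        assert np.all(np.abs(offsets + truth.drift_track) <= 0.5)

    def test_driftless_stack_yields_zero_offsets(self, wt_pair, noiseless_scene):
        left, right, _, _ = wt_pair
        stack, _, _ = render_stack(left, right, noiseless_scene, seed=11)
        _, offsets = estimate_and_correct_drift(stack)
        assert np.all(offsets == 0.0)

    def test_correction_improves_trace_recovery(self, drifting_scene):
        left, right, scene = drifting_scene
        stack, rois, _ = render_stack(left, right, scene, seed=11)
        cfg_on = ExtractionConfig(bleed_coefficient=0.0, drift_correction=True)
        cfg_off = dataclasses.replace(cfg_on, drift_correction=False)
        on, _ = extract_traces(stack, rois, cfg_on, contact_frame=6)
        off, _ = extract_traces(stack, rois, cfg_off, contact_frame=6)
        rmse = lambda t, ref: np.sqrt(np.mean((t.ratio - ref.ratio) ** 2))
        assert rmse(on["left"], left) < rmse(off["left"], left)

    def test_all_zero_stack_warns_and_applies_zero_offset(self):
        stack = ImageStack(pixels=np.zeros((3, 3, 8, 8)))
        with pytest.warns(UserWarning, match="zero"):
            _, offsets = estimate_and_correct_drift(stack)
        assert np.all(offsets == 0.0)


class TestGeneratorRoundTrip:
    def test_noiseless_render_recovers_input_traces(self, wt_pair,
                                                    noiseless_scene):
        left, right, _, _ = wt_pair
        stack, rois, _ = render_stack(left, right, noiseless_scene, seed=11)
        cfg = ExtractionConfig(bleed_coefficient=0.0, drift_correction=False)
        traces, _ = extract_traces(stack, rois, cfg, contact_frame=6)
        for label, ref in (("left", left), ("right", right)):
            rel = np.abs(traces[label].ratio - ref.ratio) / np.abs(ref.ratio)
            assert rel.max() < 1e-6

    def test_bleed_subtraction_recovers_contaminated_trace(self, wt_pair,
                                                           noiseless_scene):
        left, right, _, _ = wt_pair
        over_left = tuple(np.mean(noiseless_scene.synergid_polygons["left"],
                                  axis=0))
        scene = dataclasses.replace(noiseless_scene, bleed_fraction=0.2,
                                    red_path_end=over_left)
        stack, rois, _ = render_stack(left, right, scene, seed=11)
        corrected, _ = extract_traces(
            stack, rois, ExtractionConfig(bleed_coefficient=0.2,
                                          drift_correction=False),
            contact_frame=6)
        uncorrected, _ = extract_traces(
            stack, rois, ExtractionConfig(bleed_coefficient=0.0,
                                          drift_correction=False),
            contact_frame=6)
        rmse = lambda t: np.sqrt(np.mean((t.ratio - left.ratio) ** 2))
        assert rmse(uncorrected["left"]) > 5 * rmse(corrected["left"])

    def test_speckle_cleanup_reduces_pixel_error_tenfold(self, wt_pair,
                                                         noiseless_scene):
        left, right, _, _ = wt_pair
        speckled_scene = dataclasses.replace(noiseless_scene,
                                             speckle_rate=0.01)
        ref_stack, _, _ = render_stack(left, right, noiseless_scene, seed=11)
        noisy_stack, _, _ = render_stack(left, right, speckled_scene, seed=11)
        cleaned = clean(noisy_stack, ExtractionConfig())
        err_before = np.abs(noisy_stack.pixels - ref_stack.pixels).mean()
        err_after = np.abs(cleaned.pixels - ref_stack.pixels).mean()
        assert err_before > 10 * err_after
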