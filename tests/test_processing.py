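import numpy as np
import pytest

from atpfret.fluorescence import AcquisitionModel, DualChannelTrace, render_image_stack
from atpfret.processing import (compute_ratio, correct_bleach, extract_roi_traces,
                                normalize_trace, process_trace, segment_rois,
                                subtract_background)


def make_trace(cfp, yfp, bg_c=0.0, bg_y=0.0):
    n = len(cfp)
    return DualChannelTrace(time=np.arange(n, dtype=float),
                            cfp=np.asarray(cfp, float),
                            yfp=np.asarray(yfp, float),
                            bg_cfp_est=bg_c, bg_yfp_est=bg_y)


class TestSubtractBackground:
    def test_zero_background_is_identity(self):
        tr = make_trace([100, 100], [50, 50])
        out = subtract_background(tr, 0.0, 0.0)
        assert np.array_equal(out.cfp, tr.cfp)
        assert out.valid.all()

    def test_arithmetic(self):
        out = subtract_background(make_trace([100, 100], [90, 90]), 40.0, 30.0)
        assert np.array_equal(out.cfp, [60, 60])
        assert np.array_equal(out.yfp, [60, 60])

    def test_oversubtraction_flags_invalid_without_raising(self):
        out = subtract_background(make_trace([100, 100], [90, 90]), 150.0, 0.0)
        assert not out.valid.any()

    def test_negative_background_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(make_trace([1], [1]), -5.0, 0.0)

    def test_missing_background_rejected(self):
        tr = make_trace([1], [1])
        tr.bg_cfp_est = None
        with pytest.raises(ValueError, match="background"):
            subtract_background(tr)


class TestComputeRatio:
    def test_requires_background_subtraction_first(self):
        with pytest.raises(ValueError, match="background"):
            compute_ratio(make_trace([1, 2], [1, 2]))

    @pytest.mark.parametrize("cfp,yfp,expected", [
        ([2, 4], [3, 6], [1.5, 1.5]),
        ([5, 5], [5, 5], [1.0, 1.0]),
    ])
    def test_arithmetic(self, cfp, yfp, expected):
        rt = compute_ratio(subtract_background(make_trace(cfp, yfp), 0, 0))
        assert np.allclose(rt.ratio, expected)

    def test_scaling_both_channels_leaves_ratio_unchanged(self):
        a = compute_ratio(subtract_background(make_trace([2, 4], [3, 6]), 0, 0))
        b = compute_ratio(subtract_background(make_trace([6, 12], [9, 18]), 0, 0))
        assert np.allclose(a.ratio, b.ratio)

    def test_invalid_frames_propagate(self):
        tr = subtract_background(make_trace([100, 10, 100], [50, 50, 50]), 20, 0)
        rt = compute_ratio(tr)
        assert rt.valid.tolist() == [True, False, True]
        assert np.isnan(rt.ratio[1])


def ratio_trace(t, r):
    tr = make_trace(np.ones_like(np.asarray(t, float)),
                    np.asarray(r, float))
    tr.time = np.asarray(t, float)
    return compute_ratio(subtract_background(tr, 0, 0))


class TestBleachCorrection:
    def test_flat_trace_unchanged(self):
        t = np.arange(200.0)
        rt = ratio_trace(t, np.full(200, 2.0))
        out, (A, k) = correct_bleach(rt, [(0.0, 199.0)])
        assert k < 1e-6
        assert np.array_equal(out.ratio, rt.ratio)
        assert "bleach_corrected" in out.provenance

    def test_recovers_synthetic_decay(self):
        t = np.arange(600.0)
        rt = ratio_trace(t, 2.0 * np.exp(-0.001 * t))
        out, (A, k) = correct_bleach(rt, [(0.0, 599.0)])
        assert k == pytest.approx(0.001, rel=0.05)
        assert np.allclose(out.ratio, 2.0, rtol=0.01)

    def test_step_amplitude_preserved_with_baseline_windows(self):
        """Bleach fit restricted to the pre-stimulus baseline must not distort
        a later step response."""
        t = np.arange(900.0)
        k = 5e-4
        base = np.where(t < 300, 1.0, 0.6)  # step at t = 300
        rt = ratio_trace(t, base * np.exp(-k * t))
        out, (_, k_hat) = correct_bleach(rt, [(0.0, 299.0)])
        assert k_hat == pytest.approx(k, rel=0.05)
        step = out.ratio[299] - out.ratio[301]
        assert step == pytest.approx(0.4, rel=0.02)

    def test_insufficient_frames_rejected(self):
        rt = ratio_trace(np.arange(20.0), np.ones(20))
        with pytest.raises(ValueError, match="frames"):
            correct_bleach(rt, [(0.0, 5.0)])


class TestNormalize:
    def test_baseline_mean_becomes_one(self):
        rt = ratio_trace(np.arange(10.0), [2, 2, 2, 2, 2, 3, 4, 5, 4, 3])
        out = normalize_trace(rt, (0.0, 4.0))
        assert np.mean(out.ratio[:5]) == pytest.approx(1.0)
        assert out.normalized and out.baseline_mean == pytest.approx(2.0)

    def test_idempotent_on_same_window(self):
        rt = ratio_trace(np.arange(10.0), np.linspace(2, 4, 10))
        once = normalize_trace(rt, (0.0, 4.0))
        twice = normalize_trace(once, (0.0, 4.0))
        assert np.allclose(once.ratio, twice.ratio)

    def test_arithmetic(self):
        rt = ratio_trace(np.arange(4.0), [2.0, 2.0, 2.0, 4.0])
        out = normalize_trace(rt, (0.0, 2.0))
        assert np.allclose(out.ratio, [1, 1, 1, 2])

    def test_small_baseline_rejected(self):
        rt = ratio_trace(np.arange(3.0), [2.0, 2.0, 4.0])
        with pytest.raises(ValueError):
            normalize_trace(rt, (0.0, 1.0))


class TestProcessingOrder:
    def test_full_chain_provenance(self):
        tr = make_trace(100 + np.zeros(20), 150 + np.zeros(20), 10, 10)
        rt = process_trace(tr, (0.0, 10.0), quiescent_windows=[(0.0, 19.0)])
        assert rt.provenance == ("background_subtracted", "ratio",
                                 "bleach_corrected", "normalized")

    def test_bleach_before_ratio_fails(self):
        tr = make_trace([1, 2], [1, 2])
        rt = ratio_trace(np.arange(2.0), [1, 1])
        rt = rt.copy_with(provenance=("background_subtracted",))
        with pytest.raises(ValueError):
            correct_bleach(rt, [(0.0, 1.0)])


@pytest.fixture(scope="module")
def five_cell_stack():
    from atpfret.bioenergetics import ARCHETYPES, simulate_cell
    from atpfret.protocols import make_protocol
    p = make_protocol("glucose_removal", baseline_s=30, removal_s=60)
    sim = simulate_cell(ARCHETYPES["hela_like"], p)
    acq = AcquisitionModel(noise_sd=2.0)
    return render_image_stack([sim] * 5, acq=acq, seed=21)


class TestRois:
    def test_segmentation_recovers_cells(self, five_cell_stack):
        mask = segment_rois(five_cell_stack.frames)
        assert mask.max() == 5
        # each found ROI overlaps exactly one truth cell with IoU >= 0.7
        for lab in range(1, 6):
            found = mask == lab
            best = max(
                ((found & (five_cell_stack.truth_masks == t)).sum()
                 / (found | (five_cell_stack.truth_masks == t)).sum())
                for t in range(1, 6))
            assert best >= 0.7

    def test_segmentation_deterministic(self, five_cell_stack):
        a = segment_rois(five_cell_stack.frames)
        b = segment_rois(five_cell_stack.frames)
        assert np.array_equal(a, b)

    def test_blank_stack_raises(self):
        blank = np.zeros((3, 16, 16, 2))
        with pytest.raises(ValueError, match="foreground"):
            segment_rois(blank)

    def test_roi_mean_equals_bruteforce(self, five_cell_stack):
        mask = five_cell_stack.truth_masks
        traces = extract_roi_traces(five_cell_stack, mask)
        frames = five_cell_stack.frames
        for lab, tr in zip(range(1, 6), traces):
            sel = mask == lab
            # literal per-frame average over mask pixels
            expected = np.array([frames[t][sel][:, 0].mean()
                                 for t in range(frames.shape[0])])
            assert np.allclose(tr.cfp, expected, rtol=0, atol=1e-9)

    def test_uniform_roi_value(self):
        frames = np.zeros((4, 8, 8, 2))
        mask = np.zeros((8, 8), dtype=int)
        mask[2:5, 2:5] = 1
        frames[:, mask == 1, :] = 7.0
        traces = extract_roi_traces(frames, mask, time=np.arange(4.0))
        assert np.allclose(traces[0].cfp, 7.0)
        assert np.allclose(traces[0].yfp, 7.0)

    def test_noiseless_roundtrip_matches_rendered_ratio(self, hela):
        from atpfret.bioenergetics import simulate_cell
        from atpfret.protocols import make_protocol
        p = make_protocol("glucose_removal", baseline_s=30, removal_s=60)
        sim = simulate_cell(hela, p)
        acq = AcquisitionModel(noise_sd=0.0)
        stack = render_image_stack([sim], acq=acq, seed=8)
        tr = extract_roi_traces(stack, stack.truth_masks)[0]
        truth = stack.truth_traces[0]
        got = (tr.cfp - tr.bg_cfp_est, tr.yfp - tr.bg_yfp_est)
        want = (truth.cfp - acq.bg_cfp, truth.yfp - acq.bg_yfp)
        ratio_got = got[1] / got[0]
        ratio_want = want[1] / want[0]
        assert np.allclose(ratio_got, ratio_want, atol=1e-9)

    def test_empty_mask_rejected(self, five_cell_stack):
        with pytest.raises(ValueError, match="no ROI"):
            extract_roi_traces(five_cell_stack,
                               np.zeros_like(five_cell_stack.truth_masks))
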