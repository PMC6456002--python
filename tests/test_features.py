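import numpy as np
import pytest

from atpfret.features import (FeatureConfig, basal_level, depletion_minimum,
                              extract_features, max_change, onset_time,
                              peak_amplitude, peak_width)
from atpfret.processing import RatioTrace


def rt_from(values, t=None, valid=None, normalized=True):
    values = np.asarray(values, float)
    t = np.arange(len(values), dtype=float) if t is None else np.asarray(t, float)
    valid = np.ones(len(values), bool) if valid is None else np.asarray(valid, bool)
    return RatioTrace(time=t, ratio=values, valid=valid,
                      normalized=normalized, provenance=("ratio", "normalized"))


class TestBasalAndMinimum:
    def test_constant_trace(self):
        assert basal_level(rt_from([2.0] * 10), (0, 9)) == 2.0
        assert depletion_minimum(rt_from([2.0] * 10), (0, 9)) == 2.0

    def test_mean_and_min(self):
        rt = rt_from([1.0, 2.0, 3.0])
        assert basal_level(rt, (0, 2)) == pytest.approx(2.0)
        rt2 = rt_from([1.0, 0.6, 0.8])
        assert depletion_minimum(rt2, (0, 2)) == 0.6

    def test_invalid_frames_excluded(self):
        rt = rt_from([1.0, 100.0, 1.0, 1.0], valid=[True, False, True, True])
        assert basal_level(rt, (0, 3)) == pytest.approx(1.0)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            basal_level(rt_from([1.0, 1.0]), (5, 9))


class TestPeakAmplitude:
    def test_monotone_decline_floors_at_zero(self):
        rt = rt_from(np.linspace(1.0, 0.5, 20))
        assert peak_amplitude(rt, (0, 19), basal=1.0) == 0.0

    def test_triangular_bump(self):
        y = np.ones(101)
        y[40:61] = 1.0 + 0.3 * (1 - np.abs(np.arange(-10, 11)) / 10.0)
        rt = rt_from(y)
        assert peak_amplitude(rt, (0, 100), basal=1.0) == pytest.approx(0.3)

    def test_search_stops_at_onset(self):
        # late rebound after the onset of decline must not count as the peak
        y = np.concatenate([np.ones(10), 0.5 * np.ones(10), 2.0 * np.ones(10)])
        rt = rt_from(y)
        assert peak_amplitude(rt, (0, 29), basal=1.0, onset=10.0) == 0.0


class TestOnset:
    def test_flat_trace_has_no_onset(self):
        assert onset_time(rt_from(np.ones(50)), 10.0) is None

    def test_linear_decline_analytic(self):
        """Unit trace until t=100 s, then slope -0.01/s: first frame below
        0.99 at 1-s cadence is t = 101 s."""
        t = np.arange(300.0)
        y = np.where(t <= 100, 1.0, 1.0 - 0.01 * (t - 100))
        y = np.clip(y, 0.0, None)
        assert onset_time(rt_from(y, t), 50.0, noise_sd_est=0.0) == 101.0

    def test_matches_bruteforce_rule(self, rng):
        """Literal re-implementation of the rule agrees on random traces."""
        cfg = FeatureConfig()
        for _ in range(100):
            n = int(rng.integers(20, 60))
            y = 1.0 + rng.normal(0, 0.05, n).cumsum() / 10
            valid = rng.random(n) > 0.1
            t = np.arange(n, dtype=float)
            stim = float(rng.integers(0, n // 2))
            sd = float(rng.uniform(0, 0.05))
            rt = rt_from(y, t, valid)
            got = onset_time(rt, stim, sd, cfg)

            thr = 1.0 - max(3 * sd, 0.01)
            tt = t[(t >= stim) & valid]
            yy = y[(t >= stim) & valid]
            expected = None
            for i in range(len(yy)):
                if len(yy) - i >= 3 and all(v <= thr for v in yy[i:i + 3]):
                    expected = tt[i]
                    break
            assert got == expected


class TestMaxChange:
    def test_simple_drop(self):
        y = np.concatenate([np.ones(10), 0.7 * np.ones(10)])
        rt = rt_from(y)
        assert max_change(rt, (10, 19), (0, 9)) == pytest.approx(-0.3)

    def test_larger_up_excursion_wins_with_sign(self):
        y = np.concatenate([np.ones(10), [1.2], [0.9] * 9])
        rt = rt_from(y)
        assert max_change(rt, (10, 19), (0, 9)) == pytest.approx(+0.2)

    def test_baseline_must_precede_window(self):
        with pytest.raises(ValueError):
            max_change(rt_from(np.ones(20)), (0, 9), (10, 19))

    def test_matches_bruteforce_scan(self, rng):
        for _ in range(100):
            n = int(rng.integers(15, 50))
            y = rng.uniform(0.5, 1.5, n)
            t = np.arange(n, dtype=float)
            rt = rt_from(y, t)
            b_end = int(rng.integers(3, n - 5))
            got = max_change(rt, (b_end + 1, n - 1), (0, b_end))
            base = y[:b_end + 1].mean()
            best = 0.0
            for v in y[b_end + 1:]:
                if abs(v - base) > abs(best):
                    best = v - base
            assert got == pytest.approx(best, abs=1e-12)


class TestPeakWidth:
    def test_symmetric_triangle_fwhm(self):
        """Triangular bump of 100-s base has FWHM 50 s."""
        t = np.arange(301.0)
        y = np.ones(301)
        apex = 150
        ramp = 1 - np.abs(t - apex) / 50.0
        y = np.maximum(y, 1.0 + 0.4 * ramp)
        rt = rt_from(y, t)
        w = peak_width(rt, (0, 300), basal=1.0)
        assert w == pytest.approx(50.0, abs=1.0)

    def test_no_bump_undefined(self):
        assert peak_width(rt_from(np.ones(50)), (0, 49), basal=1.0) is None

    def test_width_fraction_configurable(self):
        t = np.arange(301.0)
        y = 1.0 + 0.4 * np.maximum(1 - np.abs(t - 150) / 50.0, 0.0)
        rt = rt_from(y, t)
        w25 = peak_width(rt, (0, 300), 1.0, FeatureConfig(width_fraction=0.25))
        assert w25 == pytest.approx(75.0, abs=1.0)


@pytest.fixture(scope="module")
def processed(hela, fingerprint_protocol):
    from atpfret.bioenergetics import simulate_cell
    from atpfret.fluorescence import AcquisitionModel, render_trace
    from atpfret.processing import process_trace
    sim = simulate_cell(hela, fingerprint_protocol)
    tr = render_trace(sim, "mito",
                      acq=AcquisitionModel(noise_sd=0.0), seed=0)
    return process_trace(tr, fingerprint_protocol.baseline_window())


class TestExtractFeatures:
    def test_fingerprint_protocol_features(self, processed, fingerprint_protocol):
        f = extract_features(processed, fingerprint_protocol)
        assert f.basal == pytest.approx(1.0, abs=1e-6)
        assert f.delta_glc < -0.3          # deep mitochondrial depletion
        assert f.delta_oligo is not None and f.delta_oligo > 0
        assert abs(f.delta_glc) > abs(f.delta_oligo)
        assert f.peak_amp > 0.05           # transient hexokinase-reversal peak
        assert f.onset_time is not None
        assert f.min_level < 0.6
        assert f.qc_pass

    def test_requires_normalized_trace(self, processed, fingerprint_protocol):
        raw = processed.copy_with(normalized=False)
        with pytest.raises(ValueError, match="normalized"):
            extract_features(raw, fingerprint_protocol)

    def test_qc_fails_with_many_invalid_frames(self, processed,
                                               fingerprint_protocol):
        bad_valid = processed.valid.copy()
        sel = (processed.time >= 400) & (processed.time <= 1800)
        bad_valid[sel] = False
        degraded = processed.copy_with(valid=bad_valid)
        f = extract_features(degraded, fingerprint_protocol)
        assert not f.qc_pass
        assert any("invalid_frames" in fl for fl in f.qc_flags)


def test_features_invariant_to_channel_scaling(hela, removal_protocol):
    """Uniform scaling of both raw channels (zero background) leaves every
    extracted feature unchanged."""
    from atpfret.bioenergetics import simulate_cell
    from atpfret.fluorescence import AcquisitionModel, render_trace
    from atpfret.processing import process_trace
    sim = simulate_cell(hela, removal_protocol)
    acq = AcquisitionModel(noise_sd=0.0, bg_cfp=0.0, bg_yfp=0.0)
    feats = []
    for expr in (1.0, 3.7):
        tr = render_trace(sim, "mito", acq=acq, expression=expr, seed=0)
        rt = process_trace(tr, removal_protocol.baseline_window())
        feats.append(extract_features(rt, removal_protocol))
    a, b = feats
    for attr in ("basal", "peak_amp", "onset_time", "min_level", "delta_glc"):
        va, vb = getattr(a, attr), getattr(b, attr)
        if va is None:
            assert vb is None
        else:
            assert va == pytest.approx(vb, rel=1e-9)
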