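"""Preprocessing stage contracts: scaling, filtering, segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from ecgrobust.errors import DegenerateSignalError, InvalidArgumentError
from ecgrobust.preprocess import (FilterSpec, NormalizationParams,
                                  SegmentationSpec, detect_r_peaks,
                                  detrend_linear, lowpass_butterworth,
                                  normalize_minmax, preprocess_record,
                                  segment_beats)
from ecgrobust.synth import generate_record


class TestNormalizeMinmax:
    def test_endpoints_and_midpoint(self):
        assert np.allclose(normalize_minmax([2.0, 4.0, 6.0]), [0.0, 0.5, 1.0])

    def test_identity_on_unit_range_input(self):
        x = np.array([0.0, 0.3, 0.7, 1.0])
        assert np.allclose(normalize_minmax(x), x)

    def test_affine_relation_and_rank_order(self, rng):
        x = rng.normal(size=100)
        out = normalize_minmax(x)
        expected = (x - x.min()) / (x.max() - x.min())
        assert np.allclose(out, expected, atol=1e-12)
        assert np.array_equal(np.argsort(out), np.argsort(x))

    def test_constant_signal_is_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            normalize_minmax(np.ones(10))

    def test_target_range(self):
        out = normalize_minmax([1.0, 2.0, 5.0], NormalizationParams(a=-1.0, b=3.0))
        assert out.min() == -1.0 and out.max() == 3.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(hnp.arrays(np.float64, st.integers(2, 50),
                      elements=st.floats(-100, 100, allow_nan=False)))
    def test_idempotent_once_scaled(self, x):
        try:
            once = normalize_minmax(x)
        except DegenerateSignalError:
            return
        assert np.allclose(normalize_minmax(once), once, atol=1e-12)


class TestLowpassButterworth:
    def test_constant_signal_unchanged(self):
        x = np.full(2000, 0.7)
        assert np.allclose(lowpass_butterworth(x), x, atol=1e-9)

    def _sine_gain_db(self, f_rel, mode, fs=1000.0, dur=20.0):
        spec = FilterSpec(mode=mode)
        f = f_rel * spec.fc * fs / 2.0
        t = np.arange(int(dur * fs)) / fs
        x = np.sin(2 * np.pi * f * t)
        y = lowpass_butterworth(x, spec)
        # measure amplitude on the middle half (past any transient)
        n = x.size
        sl = slice(n // 4, 3 * n // 4)
        return 20 * np.log10(np.sqrt(np.mean(y[sl] ** 2)) / np.sqrt(np.mean(x[sl] ** 2)))

    def test_causal_minus_3db_at_cutoff(self):
        assert self._sine_gain_db(1.0, "causal") == pytest.approx(-3.0103, abs=0.1)

    def test_zero_phase_minus_6db_at_cutoff(self):
        assert self._sine_gain_db(1.0, "zero_phase") == pytest.approx(-6.0206, abs=0.1)

    def test_attenuation_at_5x_cutoff_matches_analytic(self):
        from scipy.signal import butter, sosfreqz
        spec = FilterSpec()
        measured = self._sine_gain_db(5.0, "causal")
        # exact digital response at 5 fc
        sos = butter(spec.order, spec.fc, btype="lowpass", output="sos")
        _, h = sosfreqz(sos, worN=[np.pi * 5 * spec.fc])
        assert measured == pytest.approx(20 * np.log10(np.abs(h[0])), abs=0.1)
        # analog prototype |H|^2 = 1/(1 + 5^(2N)): ~-112 dB; the bilinear
        # transform's frequency warping adds ~2 dB at this depth
        analog = -10 * np.log10(1 + 5.0 ** 16)
        assert measured == pytest.approx(analog, abs=3.0)

    def test_linearity(self, rng):
        x, y = rng.normal(size=(2, 3000))
        fx = lowpass_butterworth(x)
        fy = lowpass_butterworth(y)
        fxy = lowpass_butterworth(2.0 * x - 0.5 * y)
        assert np.allclose(fxy, 2.0 * fx - 0.5 * fy, atol=1e-9)

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(InvalidArgumentError):
            FilterSpec(fc=1.5)
        with pytest.raises(InvalidArgumentError):
            FilterSpec(fc=0.0)


class TestDetectRPeaks:
    def test_flat_signal_yields_no_peaks(self):
        assert detect_r_peaks(np.zeros(5000), 1000.0).size == 0

    def test_steady_record_peaks_within_10ms(self, steady_patient):
        record, truth = generate_record(steady_patient, n_leads=1, duration_s=10.0)
        found = detect_r_peaks(record.signal[0], 1000.0)
        assert len(found) == len(truth) == 10
        assert np.max(np.abs(found - truth)) <= 10

    def test_jittered_record_perfect_recall_and_precision(self, synthetic_record):
        record, truth = synthetic_record
        found = detect_r_peaks(record.signal[0], record.fs)
        tol = int(0.010 * record.fs)
        matched_truth = sum(np.min(np.abs(found - t)) <= tol for t in truth)
        matched_found = sum(np.min(np.abs(truth - f)) <= tol for f in found)
        assert matched_truth == len(truth)   # recall 1.0
        assert matched_found == len(found)   # precision 1.0

    def test_minimum_separation_respected(self, synthetic_record):
        record, _ = synthetic_record
        found = detect_r_peaks(record.signal[0], record.fs)
        assert np.all(np.diff(found) >= 0.2 * record.fs)


class TestSegmentBeats:
    def test_default_window_is_650_samples(self, rng):
        x = rng.normal(size=5000)
        segs = segment_beats(x, [1000, 2000, 3000])
        assert all(s.samples.size == 650 for s in segs)

    def test_edge_peak_dropped(self, rng):
        x = rng.normal(size=5000)
        segs = segment_beats(x, [100, 2500, 4800])
        assert len(segs) == 1  # first starts at -200, last ends past the record

    def test_segments_are_direct_slices(self, rng):
        x = rng.normal(size=20000)
        peaks = np.arange(1000, 11000, 1000)
        segs = segment_beats(x, peaks)
        assert len(segs) == 10
        for s, p in zip(segs, peaks):
            assert np.array_equal(s.samples, x[p - 300:p + 350])

    def test_conservation_count(self, rng):
        x = rng.normal(size=3000)
        peaks = [100, 900, 1800, 2900]       # first and last cross the edges
        segs = segment_beats(x, peaks)
        assert len(segs) == len(peaks) - 2

    def test_non_integral_window_rejected(self):
        with pytest.raises(InvalidArgumentError):
            SegmentationSpec(t1=0.3001, t2=0.35, fs=999.0)


class TestDetrendLinear:
    @pytest.mark.parametrize("seg", [np.linspace(-2, 5, 101), np.full(64, 3.3)])
    def test_linear_and_constant_go_to_zero(self, seg):
        assert np.allclose(detrend_linear(seg), 0.0, atol=1e-10)

    def test_ramp_plus_sine_equals_detrended_sine(self):
        t = np.linspace(0, 1, 650)
        sine = np.sin(2 * np.pi * 3 * t)
        ramp = 0.8 + 2.5 * t
        assert np.allclose(detrend_linear(sine + ramp), detrend_linear(sine), atol=1e-10)

    def test_residual_fit_is_zero(self, rng):
        out = detrend_linear(rng.normal(size=300))
        t = np.arange(out.size)
        slope, intercept = np.polyfit(t, out, 1)
        assert abs(slope) < 1e-12 and abs(intercept) < 1e-10


class TestPreprocessRecord:
    def test_pipeline_emits_650_sample_detrended_rows(self, synthetic_record):
        record, peaks = synthetic_record
        table = preprocess_record(record, use_ground_truth_peaks=True)
        assert table.X.shape[1] == 650
        # one row per (lead, interior peak)
        interior = sum(1 for p in peaks if p - 300 >= 0 and p + 350 <= record.n_samples)
        assert len(table) == record.n_leads * interior
        t = np.arange(650)
        slopes = np.polyfit(t, table.X.T, 1)[0]
        assert np.max(np.abs(slopes)) < 1e-12
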