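"""Trace-level operations: filtering, rms, epoch windows, PPA detection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tmsemg.signal import (EmgTrace, TraceError, bandpass_filter, butter_gain,
                           detect_paired_ppas, detect_ppa, ensemble_average,
                           prestimulus_rms, rms)
from tmsemg.synthetic import mep_template

from conftest import sinusoid_trace

FS = 1000.0


class TestBandpassFilter:
    @pytest.mark.parametrize("freq", [5.0, 100.0, 40.0])
    def test_gain_matches_analytic_squared_butterworth(self, freq):
        """Mid-trace amplitude of a filtered sinusoid equals |H(f)|^2."""
        trace = sinusoid_trace(freq, n=8000)
        out = bandpass_filter(trace).samples
        mid = out[2000:6000]  # integer periods at all tested frequencies
        measured = rms(mid) * np.sqrt(2.0)
        expected = butter_gain(freq, 13.0, 500.0, 4, FS)
        assert measured == pytest.approx(expected, rel=0.01)

    def test_dc_rejected(self):
        trace = EmgTrace(np.ones(4000), FS)
        out = bandpass_filter(trace).samples
        assert np.max(np.abs(out[1000:3000])) < 1e-3

    def test_zero_lag_for_inband_sinusoid(self):
        trace = sinusoid_trace(80.0, n=4000)
        out = bandpass_filter(trace).samples
        lags = range(-5, 6)
        xc = [np.dot(trace.samples[1000:3000], out[1000 + k:3000 + k]) for k in lags]
        assert list(lags)[int(np.argmax(xc))] == 0

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        y = rng.standard_normal(2000)
        fx = bandpass_filter(EmgTrace(x, FS)).samples
        fy = bandpass_filter(EmgTrace(y, FS)).samples
        fxy = bandpass_filter(EmgTrace(2.0 * x - 3.0 * y, FS)).samples
        np.testing.assert_allclose(fxy, 2.0 * fx - 3.0 * fy, atol=1e-10)

    def test_nyquist_cutoff_clamped_with_warning(self, caplog):
        from tmsemg.signal import _design_sos
        _design_sos.cache_clear()
        with caplog.at_level("WARNING"):
            bandpass_filter(sinusoid_trace(50.0), high=500.0)
        assert any("clamping" in r.message for r in caplog.records)

    def test_too_short_trace_rejected(self):
        with pytest.raises(TraceError, match="too short"):
            bandpass_filter(EmgTrace(np.zeros(10), FS))


class TestRms:
    @pytest.mark.parametrize("segment, expected", [
        (np.full(100, 2.0), 2.0),
        ([3.0, 4.0], np.sqrt(12.5)),
    ])
    def test_known_values(self, segment, expected):
        assert rms(segment) == pytest.approx(expected, rel=1e-12)

    def test_unit_sinusoid_integer_periods(self):
        t = np.arange(1000) / FS
        assert rms(np.sin(2 * np.pi * 50 * t)) == pytest.approx(1 / np.sqrt(2), rel=1e-9)

    def test_empty_segment_rejected(self):
        with pytest.raises(TraceError):
            rms([])


class TestPrestimulusRms:
    def test_constant_prestim_window(self):
        x = np.zeros(400)
        x[:150] = 0.5
        trace = EmgTrace(x, FS, (150,))
        assert prestimulus_rms(trace) == pytest.approx(0.5)

    def test_window_convention_covers_samples_0_to_99(self):
        """stim at 100 with 1 kHz sampling: window is samples [0, 100)."""
        x = np.zeros(300)
        x[:100] = 1.0          # window content
        x[100] = 100.0         # stimulus sample itself must be excluded
        trace = EmgTrace(x, FS, (100,))
        assert prestimulus_rms(trace) == pytest.approx(1.0)

    def test_insufficient_samples_rejected(self):
        trace = EmgTrace(np.zeros(300), FS, (50,))
        with pytest.raises(TraceError):
            prestimulus_rms(trace)


class TestDetectPpa:
    def test_max_minus_min(self):
        x = np.zeros(400)
        x[200], x[230] = 1.2, -0.8
        assert detect_ppa(EmgTrace(x, FS, (150,))).ppa == pytest.approx(2.0)

    def test_all_zero_window(self):
        assert detect_ppa(EmgTrace(np.zeros(400), FS, (150,))).ppa == 0.0

    def test_injected_template_recovered(self):
        x = np.zeros(400)
        x[151:251] = mep_template(1.7, 25.0, 18.0, FS)
        assert detect_ppa(EmgTrace(x, FS, (150,))).ppa == pytest.approx(1.7, abs=1e-9)

    def test_stimulus_sample_excluded(self):
        x = np.zeros(400)
        x[150] = 50.0  # artifact at the stimulus sample
        assert detect_ppa(EmgTrace(x, FS, (150,))).ppa == 0.0

    def test_window_beyond_trace_rejected(self):
        with pytest.raises(TraceError):
            detect_ppa(EmgTrace(np.zeros(200), FS, (150,)))

    @given(offset=st.floats(-5, 5, allow_nan=False))
    def test_offset_invariance(self, offset):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(400)
        base = detect_ppa(EmgTrace(x, FS, (150,))).ppa
        shifted = detect_ppa(EmgTrace(x + offset, FS, (150,))).ppa
        assert shifted == pytest.approx(base, abs=1e-9)


class TestDetectPairedPpas:
    def _lici_trace(self, amp1, amp2, n=500, stim1=150, stim2=250):
        x = np.zeros(n)
        if amp1 > 0:
            x[stim1 + 1:stim1 + 101] += mep_template(amp1, 25.0, 18.0, FS)
        if amp2 > 0:
            x[stim2 + 1:stim2 + 101] += mep_template(amp2, 25.0, 18.0, FS)
        return EmgTrace(x, FS, (stim1, stim2))

    def test_both_templates_measured(self):
        cond, test = detect_paired_ppas(self._lici_trace(1.0, 0.5))
        assert cond.ppa == pytest.approx(1.0, abs=1e-9)
        assert test.ppa == pytest.approx(0.5, abs=1e-9)
        assert cond.detectable and test.detectable

    def test_absent_test_mep_not_detectable(self):
        rng = np.random.default_rng(2)
        trace = self._lici_trace(1.0, 0.0)
        trace.samples += 0.01 * rng.standard_normal(trace.samples.size)
        _, test = detect_paired_ppas(trace)
        assert not test.detectable

    def test_identical_templates_give_equal_ppas(self):
        cond, test = detect_paired_ppas(self._lici_trace(0.8, 0.8))
        assert cond.ppa == pytest.approx(test.ppa, abs=1e-9)

    def test_windows_disjoint(self):
        cond, test = detect_paired_ppas(self._lici_trace(1.0, 1.0))
        assert cond.window_end <= test.window_start
        assert cond.window_start > 150 and test.window_start > 250

    def test_conditioning_window_truncated_at_second_stimulus(self):
        # ISI shorter than the detection epoch: window must stop at stim2
        x = np.zeros(400)
        trace = EmgTrace(x, FS, (150, 200))
        cond, _ = detect_paired_ppas(trace)
        assert cond.window_end == 200

    def test_out_of_order_stimuli_rejected(self):
        trace = self._lici_trace(1.0, 1.0)
        with pytest.raises(TraceError):
            detect_paired_ppas(trace, stim1=250, stim2=150)


class TestEnsembleAverage:
    def test_idempotent_on_identical_traces(self):
        rng = np.random.default_rng(3)
        t = EmgTrace(rng.standard_normal(400), FS, (150,))
        avg = ensemble_average([t] * 10)
        np.testing.assert_allclose(avg.samples, t.samples)
        assert avg.stim_indices == t.stim_indices

    def test_opposite_traces_cancel(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(400)
        avg = ensemble_average([EmgTrace(x, FS, (150,)), EmgTrace(-x, FS, (150,))])
        np.testing.assert_allclose(avg.samples, 0.0, atol=1e-15)

    def test_noise_suppression_recovers_template_amplitude(self):
        """PPA of the 10-trace average is within the noise-predicted band."""
        rng = np.random.default_rng(5)
        sigma = 0.05
        template = mep_template(1.0, 25.0, 18.0, FS)
        traces = []
        for _ in range(10):
            x = sigma * rng.standard_normal(400)
            x[151:251] += template
            traces.append(EmgTrace(x, FS, (150,)))
        ppa = detect_ppa(ensemble_average(traces)).ppa
        # averaged noise sd sigma/sqrt(10); PPA perturbed by ~2 extreme draws
        assert ppa == pytest.approx(1.0, abs=6 * sigma / np.sqrt(10))

    def test_mixed_sampling_rates_rejected(self):
        a = EmgTrace(np.zeros(400), 1000.0, (150,))
        b = EmgTrace(np.zeros(400), 2000.0, (150,))
        with pytest.raises(TraceError):
            ensemble_average([a, b])

    def test_empty_list_rejected(self):
        with pytest.raises(TraceError):
            ensemble_average([])
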