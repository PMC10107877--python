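"""Low-level sEMG trace processing.

Filtering, rms, stimulus-locked epoch extraction and MEP peak-to-peak
amplitude (PPA) detection. Window conventions: the pre-stimulus epoch is
``[stim - epoch, stim)`` and the post-stimulus epoch is
``(stim, stim + epoch]`` -- the stimulus-artifact sample itself belongs to
neither window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)


class TraceError(ValueError):
    """Raised for malformed traces or epoch requests that do not fit them."""


@dataclass
class EmgTrace:
    """One trial's sampled surface EMG (mV) with stimulus markers.

    ``stim_indices`` holds the sample indices of the stimulus artifacts:
    one for single-pulse trials, two (conditioning then test) for
    paired-pulse trials.
    """

    samples: np.ndarray
    sampling_rate: float
    stim_indices: tuple[int, ...] = ()
    meta: Mapping | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise TraceError("samples must be one-dimensional")
        if self.sampling_rate <= 0:
            raise TraceError("sampling_rate must be positive")
        self.stim_indices = tuple(int(i) for i in self.stim_indices)
        if any(b <= a for a, b in zip(self.stim_indices, self.stim_indices[1:])):
            raise TraceError("stim_indices must be strictly increasing")
        if any(i < 0 or i >= self.samples.size for i in self.stim_indices):
            raise TraceError("stim indices outside trace")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class PpaMeasurement:
    """A peak-to-peak amplitude over one post-stimulus window.

    ``detectable`` records whether the deflection exceeded the trial's own
    noise floor (used for the LICI second-MEP rule); single-pulse
    measurements are detectable by definition.
    """

    ppa: float
    window_start: int
    window_end: int  # exclusive
    detectable: bool = True


def ms_to_samples(ms: float, sampling_rate: float) -> int:
    return int(round(ms * sampling_rate / 1000.0))


@lru_cache(maxsize=32)
def _design_sos(low: float, high: float, order: int, fs: float):
    nyq = fs / 2.0
    if high >= nyq:
        clamped = 0.99 * nyq
        logger.warning(
            "low-pass cutoff %.1f Hz is at/above Nyquist (%.1f Hz); clamping to %.1f Hz",
            high, nyq, clamped,
        )
        high = clamped
    if low >= high:
        raise TraceError("high-pass cutoff must be below the (clamped) low-pass cutoff")
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(trace: EmgTrace, low: float = 13.0, high: float = 500.0,
                    order: int = 4) -> EmgTrace:
    """Zero-lag Butterworth band-pass.

    The filter is applied forward and backward (``sosfiltfilt``), giving zero
    net phase shift and a magnitude response equal to the squared single-pass
    Butterworth magnitude. A low-pass cutoff at or above Nyquist (500 Hz at
    1 kHz sampling) is clamped to 0.99x Nyquist with a logged warning.
    """
    sos = _design_sos(float(low), float(high), int(order), float(trace.sampling_rate))
    padlen = 3 * (2 * sos.shape[0] + 1)
    if trace.samples.size <= padlen:
        raise TraceError(
            f"trace too short for stable zero-lag filtering "
            f"({trace.samples.size} samples <= padlen {padlen})"
        )
    filtered = sps.sosfiltfilt(sos, trace.samples)
    return EmgTrace(filtered, trace.sampling_rate, trace.stim_indices, trace.meta)


def butter_gain(freq_hz: float, low: float, high: float, order: int,
                sampling_rate: float) -> float:
    """Analytic zero-lag gain at one frequency: |H(f)|^2 of the single pass.

    Used as the oracle against which the digital implementation is tested;
    computed from the actual designed filter (bilinear-transform response),
    including any Nyquist clamping.
    """
    sos = _design_sos(float(low), float(high), int(order), float(sampling_rate))
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=sampling_rate)
    return float(np.abs(h[0]) ** 2)


def rms(segment: Sequence[float] | np.ndarray) -> float:
    """Root mean square of a sample window."""
    x = np.asarray(segment, dtype=float)
    if x.size == 0:
        raise TraceError("rms of an empty segment is undefined")
    return float(np.sqrt(np.mean(np.square(x))))


def _prestim_slice(trace: EmgTrace, stim_index: int, epoch_ms: float) -> np.ndarray:
    n = ms_to_samples(epoch_ms, trace.sampling_rate)
    if stim_index - n < 0:
        raise TraceError(
            f"need {n} samples before stimulus at {stim_index}, trace has {stim_index}"
        )
    return trace.samples[stim_index - n:stim_index]


def prestimulus_rms(trace: EmgTrace, stim_index: int | None = None,
                    epoch_ms: float = 100.0) -> float:
    """rms over the epoch immediately preceding the (first) stimulus.

    Window is ``[stim - epoch, stim)``; for paired-pulse trials the epoch
    precedes the first (conditioning) stimulus.
    """
    if stim_index is None:
        if not trace.stim_indices:
            raise TraceError("trace has no stimulus markers")
        stim_index = trace.stim_indices[0]
    return rms(_prestim_slice(trace, stim_index, epoch_ms))


def prestimulus_peak_to_peak(trace: EmgTrace, stim_index: int | None = None,
                             epoch_ms: float = 100.0) -> float:
    """max - min over the pre-stimulus epoch; the trial's noise-floor yardstick."""
    if stim_index is None:
        if not trace.stim_indices:
            raise TraceError("trace has no stimulus markers")
        stim_index = trace.stim_indices[0]
    seg = _prestim_slice(trace, stim_index, epoch_ms)
    return float(np.max(seg) - np.min(seg))


def detect_ppa(trace: EmgTrace, stim_index: int | None = None,
               window_ms: float = 100.0) -> PpaMeasurement:
    """MEP peak-to-peak amplitude: max - min over ``(stim, stim + window]``."""
    if stim_index is None:
        if not trace.stim_indices:
            raise TraceError("trace has no stimulus markers")
        stim_index = trace.stim_indices[-1]
    n = ms_to_samples(window_ms, trace.sampling_rate)
    start, end = stim_index + 1, stim_index + 1 + n
    if end > trace.samples.size:
        raise TraceError(
            f"post-stimulus window [{start}, {end}) exceeds trace length "
            f"{trace.samples.size}"
        )
    seg = trace.samples[start:end]
    if seg.size == 0:
        raise TraceError("empty post-stimulus window")
    return PpaMeasurement(float(np.max(seg) - np.min(seg)), start, end)


def detect_paired_ppas(trace: EmgTrace, stim1: int | None = None,
                       stim2: int | None = None, window_ms: float = 100.0,
                       detect_multiplier: float = 3.0
                       ) -> tuple[PpaMeasurement, PpaMeasurement]:
    """Conditioning and test PPAs for a long-ISI paired-pulse trial.

    The conditioning window ``(stim1, stim2)`` is truncated at the second
    stimulus so the two windows never overlap; the test window is
    ``(stim2, stim2 + window]``. Each measurement's ``detectable`` flag is
    true when its PPA exceeds ``detect_multiplier`` times the pre-stimulus
    peak-to-peak amplitude of the same trace -- the operational meaning of a
    "distinct" MEP.
    """
    if stim1 is None or stim2 is None:
        if len(trace.stim_indices) != 2:
            raise TraceError("paired-pulse trace must carry exactly two stimulus markers")
        stim1, stim2 = trace.stim_indices
    if stim2 <= stim1:
        raise TraceError("stimuli out of order")
    n = ms_to_samples(window_ms, trace.sampling_rate)
    cond_start, cond_end = stim1 + 1, min(stim1 + 1 + n, stim2)
    if cond_end <= cond_start:
        raise TraceError("stimuli too close: empty conditioning window")
    test_start, test_end = stim2 + 1, stim2 + 1 + n
    if test_end > trace.samples.size:
        raise TraceError("test window exceeds trace end")
    floor = detect_multiplier * prestimulus_peak_to_peak(trace, stim1, window_ms)
    cond_seg = trace.samples[cond_start:cond_end]
    test_seg = trace.samples[test_start:test_end]
    cond = PpaMeasurement(float(np.max(cond_seg) - np.min(cond_seg)),
                          cond_start, cond_end)
    test = PpaMeasurement(float(np.max(test_seg) - np.min(test_seg)),
                          test_start, test_end)
    cond.detectable = cond.ppa > floor
    test.detectable = test.ppa > floor
    return cond, test


def ensemble_average(traces: Sequence[EmgTrace]) -> EmgTrace:
    """Pointwise mean of stimulus-aligned repetitions.

    All traces must share sampling rate, length and stimulus-marker layout;
    the markers are preserved on the averaged trace.
    """
    if not traces:
        raise TraceError("cannot average an empty list of traces")
    first = traces[0]
    for t in traces[1:]:
        if t.sampling_rate != first.sampling_rate:
            raise TraceError("mixed sampling rates in ensemble")
        if t.samples.size != first.samples.size:
            raise TraceError("mixed trace lengths in ensemble")
        if t.stim_indices != first.stim_indices:
            raise TraceError("traces are not stimulus-aligned")
    mean = np.mean(np.stack([t.samples for t in traces]), axis=0)
    return EmgTrace(mean, first.sampling_rate, first.stim_indices, first.meta)
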