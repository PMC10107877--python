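"""Synthetic multi-session TMS-EMG study generator.

Emulates the measurement protocol end to end so every downstream stage can
be tested against known ground truth: 1 kHz sEMG with background activity
held near 5% of maximal isometric rmsEMG, biphasic MEPs whose log-amplitude
carries subject-, session- and trial-level variance components, a logistic
stimulus-response gain over %AMT anchored at 120 %AMT, multiplicative
paired-pulse conditioning effects (SICI/ICF at 3/12 ms ISI, LICI with a
second delayed MEP at 100 ms ISI), occasional sessions whose LICI second MEP
is absent, and optional non-responder subjects with no elicitable MEP.

Reproducibility: one global seed expands into independent per-subject,
per-session and per-trial substreams by hashing the (seed, subject, session,
mode, test-type, trial) coordinates through ``numpy.random.SeedSequence``,
so any trial can be regenerated in isolation and generation order is
irrelevant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (ISI_MS, PAIRED_PULSE_TYPES, SINGLE_PULSE_TYPES, ConfigError,
                     SimConfig, intensity_pct_amt)
from .signal import (EmgTrace, bandpass_filter, ms_to_samples, prestimulus_rms,
                     rms)

# substream tags (arbitrary distinct constants mixed into SeedSequence entropy)
_SUBJECT_TAG = 101
_SESSION_TAG = 202
_TRIAL_TAG = 303
_AMT_TAG = 404

_MODE_CODE = {"isometric": 1, "concentric": 2, "eccentric": 3}
_TT_CODE = {tt: i + 1 for i, tt in enumerate(SINGLE_PULSE_TYPES + PAIRED_PULSE_TYPES + ("MVC",))}

#: amplitude scale applied to every MEP of a non-responder subject; keeps all
#: PPAs far below the 0.5 mV threshold criterion at every intensity
NONRESPONDER_SCALE = 0.05


class SimulationError(ValueError):
    pass


def subject_label(subject: int) -> str:
    return f"S{subject:02d}"


def sr_gain(pct_amt: float, midpoint: float = 130.0, slope: float = 40.0) -> float:
    """Logistic stimulus-response gain over %AMT, fixed to 1 at 120 %AMT.

    ``g(x) = L(x) / L(120)`` with ``L(x) = 1 / (1 + exp(-(x - midpoint)/slope))``,
    so the 120 %AMT reference block used by the SICI/ICF ratios has unit gain.
    """
    def logistic(x: float) -> float:
        return 1.0 / (1.0 + math.exp(-(x - midpoint) / slope))

    return logistic(pct_amt) / logistic(120.0)


def mep_template(amplitude: float, latency_ms: float, duration_ms: float,
                 sampling_rate: float, epoch_ms: float = 100.0) -> np.ndarray:
    """Biphasic MEP stand-in: one sine cycle with exact peak-to-peak amplitude.

    Returns the post-stimulus detection epoch (``epoch_ms`` of samples, sample
    0 being the first sample after the stimulus). The waveform is zero outside
    ``[latency, latency + duration)`` and its max - min equals ``amplitude``
    exactly (the sampled cycle is renormalized).
    """
    if amplitude < 0:
        raise SimulationError("amplitude must be non-negative")
    if duration_ms <= 0:
        raise SimulationError("duration must be positive")
    if latency_ms + duration_ms >= epoch_ms:
        raise SimulationError(
            f"MEP (latency {latency_ms} + duration {duration_ms} ms) overflows "
            f"the {epoch_ms} ms detection epoch"
        )
    n_epoch = ms_to_samples(epoch_ms, sampling_rate)
    wave = np.zeros(n_epoch)
    if amplitude == 0:
        return wave
    n_lat = ms_to_samples(latency_ms, sampling_rate)
    n_dur = max(ms_to_samples(duration_ms, sampling_rate), 2)
    k = np.arange(n_dur)
    # half-sample offset keeps the endpoint samples nonzero; the Hann taper
    # suppresses spectral sidelobes below the analysis band so the zero-lag
    # filter spreads negligible MEP energy into the pre-stimulus epoch
    cycle = np.sin(2.0 * np.pi * (k + 0.5) / n_dur)
    cycle *= np.hanning(n_dur + 2)[1:-1]
    cycle *= amplitude / (cycle.max() - cycle.min())
    wave[n_lat:n_lat + n_dur] = cycle
    return wave


def _rng(config: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), *key]))


@dataclass
class _SubjectParams:
    b_subject: float
    amt_true: float
    factor_offsets: dict  # paradigm -> log-scale subject offset


@dataclass
class _SessionParams:
    s_session: float
    factor_offsets: dict
    lici_missing: dict  # mode -> bool


def _subject_params(config: SimConfig, subject: int) -> _SubjectParams:
    rng = _rng(config, _SUBJECT_TAG, subject)
    b = rng.normal(0.0, config.sigma_subject)
    amt = float(np.clip(rng.normal(config.amt_mean, config.amt_sd), 25.0, 85.0))
    offs = {p: rng.normal(0.0, config.factor_sigma_subject)
            for p in PAIRED_PULSE_TYPES}
    return _SubjectParams(b, amt, offs)


def _session_params(config: SimConfig, subject: int, session: int) -> _SessionParams:
    rng = _rng(config, _SESSION_TAG, subject, session)
    s = rng.normal(0.0, config.sigma_session)
    offs = {p: rng.normal(0.0, config.factor_sigma_session)
            for p in PAIRED_PULSE_TYPES}
    missing = {mode: bool(rng.random() < config.p_lici_missing)
               for mode in ("isometric", "concentric", "eccentric")}
    return _SessionParams(s, offs, missing)


def _band_noise(rng: np.random.Generator, n: int, sampling_rate: float,
                band: tuple[float, float]) -> np.ndarray:
    """Gaussian noise with a flat spectrum confined to ``band``.

    Synthesized in the frequency domain so its support sits inside the flat
    region of the analysis passband: the pipeline's own band-pass leaves it
    (and therefore the calibrated pre-stimulus rms) essentially unchanged.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.zeros(freqs.size, dtype=complex)
    m = int(mask.sum())
    spec[mask] = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    return np.fft.irfft(spec, n)


def _trace_layout(config: SimConfig, test_type: str) -> tuple[tuple[int, ...], int]:
    """Stimulus marker indices and total length for one trial trace."""
    fs = config.sampling_rate
    pre = ms_to_samples(150.0, fs)
    if test_type == "MVC":
        return (), ms_to_samples(1000.0, fs)
    if test_type in PAIRED_PULSE_TYPES:
        stims = (pre, pre + ms_to_samples(ISI_MS[test_type], fs))
    else:
        stims = (pre,)
    return stims, stims[-1] + ms_to_samples(250.0, fs)


def _log_amp_components(config: SimConfig, sp: _SubjectParams, ss: _SessionParams,
                        eps: float, pct_amt: float) -> float:
    return (config.mu_log_amp + sp.b_subject + ss.s_session + eps
            + math.log(sr_gain(pct_amt, config.sr_midpoint, config.sr_slope)))


def _conditioning_factor(config: SimConfig, sp: _SubjectParams,
                         ss: _SessionParams, paradigm: str) -> float:
    base = {"SICI": config.sici_factor, "ICF": config.icf_factor,
            "LICI": config.lici_factor}[paradigm]
    return base * math.exp(sp.factor_offsets[paradigm] + ss.factor_offsets[paradigm])


def simulate_trial(config: SimConfig, subject: int, session: int, mode: str,
                   test_type: str, trial: int,
                   forced_reject: bool = False) -> tuple[EmgTrace, dict]:
    """Generate one trial trace plus its ground-truth record.

    ``trial`` is the 1-based delivery index within the block. The record
    carries the drawn background fraction, range-of-motion flag, acceptance
    status under the delivery gating rule, and the injected MEP amplitude(s).
    """
    if mode not in _MODE_CODE:
        raise SimulationError(f"unknown mode {mode!r}")
    if test_type not in _TT_CODE:
        raise SimulationError(f"unknown test type {test_type!r}")
    sp = _subject_params(config, subject)
    ss = _session_params(config, subject, session)
    rng = _rng(config, _TRIAL_TAG, subject, session,
               _MODE_CODE[mode], _TT_CODE[test_type], trial)

    fs = config.sampling_rate
    stims, n_samples = _trace_layout(config, test_type)
    epoch_samples = ms_to_samples(100.0, fs)

    # background contraction level and range-of-motion validity
    fraction = max(float(rng.normal(config.background_target, config.background_sd)), 0.0)
    in_rom = True
    if mode != "isometric" and config.p_out_of_rom > 0:
        in_rom = bool(rng.random() >= config.p_out_of_rom)
    if forced_reject:
        if trial % 2 == 0 and mode != "isometric":
            in_rom = False
        else:
            fraction = float(config.background_target + config.gate_tol
                             + 0.01 + 0.04 * rng.random())

    amp = math.nan
    amp_cond = math.nan
    lici_missing = False
    scale = NONRESPONDER_SCALE if subject in config.nonresponder_subjects else 1.0

    samples = np.zeros(n_samples)
    if test_type == "MVC":
        noise = _band_noise(rng, n_samples, fs, config.noise_band)
        # calibrate on the steady-state interior window (50 ms edges excluded),
        # matching the window over which the normalizer rms is measured
        edge = ms_to_samples(50.0, fs)
        samples = noise * (config.mvc_rms / rms(noise[edge:n_samples - edge]))
        fraction = 1.0
        accepted = True
    else:
        pct = intensity_pct_amt(test_type)
        if test_type in ("SICI", "ICF"):
            # conditioning pulse at 80 %AMT is subthreshold: test MEP only
            eps = rng.normal(0.0, config.sigma_trial)
            amp = scale * math.exp(_log_amp_components(config, sp, ss, eps, pct)
                                   + math.log(_conditioning_factor(config, sp, ss, test_type)))
            samples[stims[1] + 1:stims[1] + 1 + epoch_samples] += mep_template(
                amp, config.mep_latency_ms, config.mep_duration_ms, fs)
        elif test_type == "LICI":
            eps_c = rng.normal(0.0, config.sigma_trial)
            eps_t = rng.normal(0.0, config.sigma_trial)
            amp_cond = scale * math.exp(_log_amp_components(config, sp, ss, eps_c, pct))
            samples[stims[0] + 1:stims[0] + 1 + epoch_samples] += mep_template(
                amp_cond, config.mep_latency_ms, config.mep_duration_ms, fs)
            lici_missing = ss.lici_missing[mode]
            amp = scale * math.exp(_log_amp_components(config, sp, ss, eps_t, pct)
                                   + math.log(_conditioning_factor(config, sp, ss, "LICI")))
            if lici_missing:
                amp = math.nan  # second MEP not elicited this session
            else:
                samples[stims[1] + 1:stims[1] + 1 + epoch_samples] += mep_template(
                    amp, config.mep_latency_ms, config.mep_duration_ms, fs)
        else:  # single pulse
            eps = rng.normal(0.0, config.sigma_trial)
            amp = scale * math.exp(_log_amp_components(config, sp, ss, eps, pct))
            samples[stims[0] + 1:stims[0] + 1 + epoch_samples] += mep_template(
                amp, config.mep_latency_ms, config.mep_duration_ms, fs)

        target_rms = fraction * config.mvc_rms
        if target_rms > 0:
            noise = _band_noise(rng, n_samples, fs, config.noise_band)
            window = noise[stims[0] - epoch_samples:stims[0]]
            samples += noise * (target_rms / rms(window))

    trace = EmgTrace(samples, fs, stims,
                     meta={"subject": subject_label(subject), "session": session,
                           "mode": mode, "test_type": test_type, "trial": trial})
    # the delivery gate acts on what the rmsEMG feedback display (and the
    # offline analysis) shows: the filtered trace's pre-stimulus epoch
    if test_type == "MVC":
        realized = 1.0
        accepted = True
    else:
        realized = prestimulus_rms(bandpass_filter(trace),
                                   stims[0]) / config.mvc_rms
        accepted = in_rom and (config.background_target - config.gate_tol
                               <= realized <= config.background_target + config.gate_tol)
    record = {
        "subject_id": subject_label(subject), "session": session, "mode": mode,
        "test_type": test_type, "trial_index": trial, "in_rom": in_rom,
        "background_fraction": fraction, "realized_fraction": realized,
        "accepted": accepted,
        "amplitude_mv": amp, "conditioning_amplitude_mv": amp_cond,
        "lici_missing": lici_missing,
    }
    return trace, record


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery testing.

    ``trials`` has one row per delivered trial (amplitudes, background
    fraction, acceptance); ``expected_outcomes`` the natural-scale outcome
    value each subject-session-mode block should yield under noise-free
    measurement; ``expected_icc`` the closed-form session-level ICC per
    outcome family; ``lici_missing`` / ``rejected_trials`` the deliberately
    degraded parts of the study.
    """

    trials: pd.DataFrame
    expected_outcomes: pd.DataFrame
    expected_icc: dict
    lici_missing: list
    config: SimConfig

    @property
    def rejected_trials(self) -> pd.DataFrame:
        return self.trials[~self.trials["accepted"]]


@dataclass
class Study:
    """An in-memory simulated study: manifest + traces + ground truth."""

    manifest: pd.DataFrame
    traces: dict
    ground_truth: GroundTruth


def expected_icc(config: SimConfig, outcome: str = "single_pulse") -> float:
    """Closed-form session-level ICC implied by the variance components.

    For single-pulse outcomes (log scale, session mean of n trials):
    ``sigma_b^2 / (sigma_b^2 + sigma_s^2 + sigma_e^2 / n)``. Ratio outcomes
    (SICI/ICF/LICI) cancel the shared subject/session amplitude components,
    leaving the conditioning-factor heterogeneity over twice the trial noise.
    """
    n = config.n_trials_per_outcome
    if outcome == "single_pulse":
        vb = config.sigma_subject ** 2
        vw = config.sigma_session ** 2 + config.sigma_trial ** 2 / n
    elif outcome == "ratio":
        vb = config.factor_sigma_subject ** 2
        vw = config.factor_sigma_session ** 2 + 2.0 * config.sigma_trial ** 2 / n
    else:
        raise ConfigError(f"unknown outcome family {outcome!r}")
    if vb + vw == 0:
        raise SimulationError("all variance components are zero: ICC undefined")
    return vb / (vb + vw)


def simulate_study(config: SimConfig) -> Study:
    """Generate the full study: manifest rows, traces and ground truth.

    For each outcome block, trials are delivered until
    ``n_trials_per_outcome`` are accepted by the delivery gating rule or
    ``max_stimulations`` have been delivered; rejected deliveries remain in
    the manifest so downstream gating is exercised. MVC normalization trials
    (isometric) are emitted for every session.
    """
    manifest_rows: list[dict] = []
    truth_rows: list[dict] = []
    traces: dict = {}
    lici_missing_sessions: list[tuple] = []

    for subject in range(1, config.n_subjects + 1):
        for session in range(1, config.n_sessions + 1):
            if (subject, session) in config.missing_sessions:
                continue
            ss = _session_params(config, subject, session)
            for mode in config.modes:
                if "LICI" in config.test_types and ss.lici_missing[mode]:
                    lici_missing_sessions.append((subject_label(subject), session, mode))
            # MVC normalization block: isometric, once per session, always
            # present regardless of which contraction modes are under study
            blocks = [("isometric", "MVC", config.n_mvc_trials,
                       config.n_mvc_trials)]
            for mode in config.modes:
                for test_type in config.test_types:
                    blocks.append((mode, test_type, config.n_trials_per_outcome,
                                   config.max_stimulations))
            for mode, test_type, n_target, n_max in blocks:
                accepted_count = 0
                trial = 0
                while accepted_count < n_target and trial < n_max:
                    trial += 1
                    forced = (test_type != "MVC"
                              and trial <= config.n_forced_rejects)
                    trace, record = simulate_trial(
                        config, subject, session, mode, test_type, trial,
                        forced_reject=forced)
                    key = (record["subject_id"], session, mode, test_type, trial)
                    traces[key] = trace
                    manifest_rows.append({
                        "subject_id": record["subject_id"], "session": session,
                        "mode": mode, "test_type": test_type,
                        "trial_index": trial, "in_rom": record["in_rom"],
                        "trace_path": "",
                    })
                    truth_rows.append(record)
                    if record["accepted"]:
                        accepted_count += 1

    trials = pd.DataFrame(truth_rows)
    manifest = pd.DataFrame(manifest_rows)
    expected = _expected_outcomes(config, trials)
    icc = {}
    for family in ("single_pulse", "ratio"):
        try:
            icc[family] = expected_icc(config, family)
        except SimulationError:
            icc[family] = math.nan  # degenerate: no variance at all
    gt = GroundTruth(trials, expected, icc, lici_missing_sessions, config)
    return Study(manifest, traces, gt)


def _expected_outcomes(config: SimConfig, trials: pd.DataFrame) -> pd.DataFrame:
    """Noise-free outcome values implied by the injected amplitudes.

    Uses the first ``n_trials_per_outcome`` accepted trials of each block --
    the same selection rule the pipeline applies -- and the constant MVC
    normalizer. Ensemble averaging of identically shaped templates makes the
    averaged-trace PPA equal the mean injected amplitude, so these values are
    exact apart from background-noise contamination of the measurement.
    """
    rows = []
    n = config.n_trials_per_outcome
    grouped = trials[trials["test_type"] != "MVC"].groupby(
        ["subject_id", "session", "mode", "test_type"], sort=False)
    block_means: dict = {}
    block_cond_means: dict = {}
    for (sid, sess, mode, tt), block in grouped:
        sel = block[block["accepted"]].head(n)
        if len(sel) < n:
            continue
        block_means[(sid, sess, mode, tt)] = float(sel["amplitude_mv"].mean())
        if tt == "LICI":
            block_cond_means[(sid, sess, mode, tt)] = float(
                sel["conditioning_amplitude_mv"].mean())

    keys = sorted({(sid, sess, mode) for (sid, sess, mode, _) in block_means})
    for sid, sess, mode in keys:
        def mean_of(tt):
            return block_means.get((sid, sess, mode, tt))

        for tt in SINGLE_PULSE_TYPES:
            if mean_of(tt) is not None:
                rows.append({"subject_id": sid, "session": sess, "mode": mode,
                             "outcome": tt, "value": mean_of(tt) / config.mvc_rms})
        sr = [mean_of(f"AMT{i}") for i in (110, 130, 150, 170)]
        if all(v is not None for v in sr):
            amps = [v / config.mvc_rms for v in sr]
            aurc = float(np.trapezoid(amps, [110.0, 130.0, 150.0, 170.0]))
            rows.append({"subject_id": sid, "session": sess, "mode": mode,
                         "outcome": "AURC", "value": aurc})
        ref = mean_of("AMT120")
        for tt in ("SICI", "ICF"):
            if mean_of(tt) is not None and ref:
                rows.append({"subject_id": sid, "session": sess, "mode": mode,
                             "outcome": tt, "value": mean_of(tt) / ref})
        lici = block_means.get((sid, sess, mode, "LICI"))
        cond = block_cond_means.get((sid, sess, mode, "LICI"))
        if cond and lici is not None and not math.isnan(lici):
            rows.append({"subject_id": sid, "session": sess, "mode": mode,
                         "outcome": "LICI", "value": lici / cond})
    return pd.DataFrame(rows, columns=["subject_id", "session", "mode",
                                       "outcome", "value"])


def simulate_amt_blocks(config: SimConfig, subject: int, session: int,
                        start_pct_mso: float = 60.0, step_pct: float = 2.0,
                        floor_pct_mso: float = 30.0) -> list[tuple[float, list[float]]]:
    """Stepwise-decrement threshold-hunt blocks for one subject-session.

    Starting at 60% of maximal stimulator output and descending in 2% steps,
    draws 10 MEP PPAs per intensity from the subject's amplitude model (the
    intensity is converted to %AMT via the subject's true threshold). Feed the
    result to :func:`tmsemg.outcomes.determine_amt`.
    """
    sp = _subject_params(config, subject)
    ss = _session_params(config, subject, session)
    rng = _rng(config, _AMT_TAG, subject, session)
    scale = NONRESPONDER_SCALE if subject in config.nonresponder_subjects else 1.0
    blocks = []
    intensity = start_pct_mso
    while intensity >= floor_pct_mso:
        pct_amt = 100.0 * intensity / sp.amt_true
        ppas = [scale * math.exp(_log_amp_components(
                    config, sp, ss, rng.normal(0.0, config.sigma_trial), pct_amt))
                for _ in range(10)]
        blocks.append((intensity, ppas))
        intensity -= step_pct
    return blocks
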