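"""Configuration objects for the simulator and the processing pipeline.

Both configs are plain dataclasses that round-trip losslessly through YAML.
Defaults encode the study protocol constants: 1 kHz sampling, 13-500 Hz
zero-lag 4th-order Butterworth band, 100 ms pre/post-stimulus epochs,
contraction gating at 5% +/- 2% of maximal isometric rmsEMG, a 0.5 mV
motor-threshold criterion, 10 accepted trials per outcome, and stimulus
intensities of 110/130/150/170 %AMT for the recruitment curve with 120 %AMT
as the single-pulse / paired-pulse reference.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

SINGLE_PULSE_TYPES = ("AMT110", "AMT120", "AMT130", "AMT150", "AMT170")
PAIRED_PULSE_TYPES = ("SICI", "LICI", "ICF")
ALL_TEST_TYPES = SINGLE_PULSE_TYPES + PAIRED_PULSE_TYPES + ("MVC",)
MODES = ("isometric", "concentric", "eccentric")

#: interstimulus interval in ms for each paired-pulse paradigm
ISI_MS = {"SICI": 3.0, "ICF": 12.0, "LICI": 100.0}


class ConfigError(ValueError):
    """Raised when a configuration violates its documented constraints."""


def intensity_pct_amt(test_type: str) -> float:
    """Stimulus intensity in %AMT implied by a test type label.

    ``AMTxxx`` encodes its own intensity; all paired-pulse test stimuli are
    delivered at 120 %AMT.
    """
    if test_type.startswith("AMT"):
        return float(test_type[3:])
    if test_type in PAIRED_PULSE_TYPES:
        return 120.0
    raise ConfigError(f"no stimulus intensity defined for test type {test_type!r}")


@dataclass
class SimConfig:
    """Generative parameters for a synthetic multi-session TMS-EMG study.

    MEP log-amplitude decomposes into subject, session and trial components
    (``mu_log_amp`` + N(0, sigma_subject) + N(0, sigma_session) +
    N(0, sigma_trial)), multiplied on the natural scale by a logistic
    stimulus-response gain anchored to 1 at 120 %AMT and, for paired-pulse
    trials, by a conditioning factor (SICI < 1, ICF > 1, LICI < 1).
    Conditioning factors carry their own subject/session log-scale
    heterogeneity so ratio outcomes have non-trivial between-subject variance.
    """

    n_subjects: int = 10
    n_sessions: int = 3
    n_trials_per_outcome: int = 10
    max_stimulations: int = 20
    sampling_rate: float = 1000.0
    modes: tuple[str, ...] = MODES
    test_types: tuple[str, ...] = SINGLE_PULSE_TYPES + PAIRED_PULSE_TYPES

    # log-amplitude model (log-mV)
    mu_log_amp: float = math.log(0.6)
    sigma_subject: float = 0.45
    sigma_session: float = 0.18
    sigma_trial: float = 0.42

    # background contraction
    mvc_rms: float = 0.5  # mV; session-constant maximal isometric rmsEMG
    background_target: float = 0.05  # fraction of mvc_rms
    background_sd: float = 0.009  # fraction; most trials fall in [0.03, 0.07]
    gate_tol: float = 0.02  # delivery repeats trials outside target +/- tol

    # MEP template
    mep_latency_ms: float = 25.0
    mep_duration_ms: float = 18.0

    # stimulus-response sigmoid over %AMT, gain == 1 at 120 %AMT
    sr_slope: float = 40.0
    sr_midpoint: float = 130.0

    # conditioning effects (multiplicative on the natural scale)
    sici_factor: float = 0.7
    icf_factor: float = 1.2
    lici_factor: float = 0.6
    factor_sigma_subject: float = 0.25
    factor_sigma_session: float = 0.10

    p_lici_missing: float = 0.1  # per subject-session-mode

    # active motor threshold model (% of maximal stimulator output)
    amt_mean: float = 48.0
    amt_sd: float = 8.0

    n_mvc_trials: int = 3
    n_forced_rejects: int = 0
    p_out_of_rom: float = 0.0  # dynamic modes only

    nonresponder_subjects: tuple[int, ...] = ()
    missing_sessions: tuple[tuple[int, int], ...] = ()  # (subject, session)

    noise_band: tuple[float, float] = (35.0, 250.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.modes = tuple(self.modes)
        self.test_types = tuple(self.test_types)
        self.nonresponder_subjects = tuple(self.nonresponder_subjects)
        self.missing_sessions = tuple(tuple(ms) for ms in self.missing_sessions)
        self.noise_band = tuple(self.noise_band)
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_sessions < 1:
            raise ConfigError("n_subjects and n_sessions must be positive")
        if self.n_trials_per_outcome < 1:
            raise ConfigError("n_trials_per_outcome must be positive")
        if self.max_stimulations < self.n_trials_per_outcome:
            raise ConfigError("max_stimulations must be >= n_trials_per_outcome")
        for s in (self.sigma_subject, self.sigma_session, self.sigma_trial,
                  self.factor_sigma_subject, self.factor_sigma_session):
            if s < 0:
                raise ConfigError("variance components must be non-negative")
        if not 0 <= self.background_target < 1:
            raise ConfigError("background_target must lie in [0, 1)")
        if self.background_sd < 0:
            raise ConfigError("background_sd must be non-negative")
        if self.sampling_rate <= 2 * self.noise_band[1]:
            raise ConfigError("sampling_rate must exceed twice the noise band top")
        for f in (self.sici_factor, self.icf_factor, self.lici_factor):
            if f <= 0:
                raise ConfigError("conditioning factors must be positive")
        if not 0 <= self.p_lici_missing <= 1:
            raise ConfigError("p_lici_missing must be a probability")
        if self.mvc_rms <= 0:
            raise ConfigError("mvc_rms must be positive")
        unknown = set(self.modes) - set(MODES)
        if unknown:
            raise ConfigError(f"unknown contraction modes: {sorted(unknown)}")
        unknown = set(self.test_types) - set(SINGLE_PULSE_TYPES + PAIRED_PULSE_TYPES)
        if unknown:
            raise ConfigError(f"unknown test types: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Processing-pipeline settings (filtering, gating, epochs, analysis order)."""

    filter_low_hz: float = 13.0
    filter_high_hz: float = 500.0
    filter_order: int = 4
    epoch_ms: float = 100.0
    gate_target: float = 0.05
    gate_tol: float = 0.02
    n_trials: int = 10
    amt_threshold_mv: float = 0.5
    lici_detect_multiplier: float = 3.0
    #: 'average_then_measure' averages the 10 aligned traces and measures one
    #: PPA; 'measure_then_average' takes the mean of 10 per-trial PPAs.
    averaging: str = "average_then_measure"
    sr_intensities: tuple[int, ...] = (110, 130, 150, 170)
    reference_test: str = "AMT120"
    #: a session's LICI outcome is dropped when more than this fraction of its
    #: trials lack a detectable test MEP (measure-then-average mode)
    lici_missing_max_fraction: float = 0.5

    def __post_init__(self) -> None:
        self.sr_intensities = tuple(self.sr_intensities)
        if not 0 < self.filter_low_hz < self.filter_high_hz:
            raise ConfigError("require 0 < filter_low_hz < filter_high_hz")
        if self.filter_order < 1:
            raise ConfigError("filter_order must be >= 1")
        if self.epoch_ms <= 0:
            raise ConfigError("epoch_ms must be positive")
        if self.gate_tol < 0 or self.gate_target < 0:
            raise ConfigError("gating target/tolerance must be non-negative")
        if self.averaging not in ("average_then_measure", "measure_then_average"):
            raise ConfigError(f"unknown averaging mode {self.averaging!r}")
        if self.lici_detect_multiplier <= 0:
            raise ConfigError("lici_detect_multiplier must be positive")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, list):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(config: SimConfig | RunConfig, path: str | Path) -> None:
    """Serialize a config to YAML; ``load_*_config`` restores it losslessly."""
    payload = {"kind": type(config).__name__, **_to_plain(config)}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def _load(path: str | Path, cls, kind: str):
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping")
    raw.pop("kind", None)
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - valid
    if unknown:
        raise ConfigError(f"{path}: unknown {kind} fields: {sorted(unknown)}")
    try:
        return cls(**raw)
    except TypeError as exc:  # missing required field etc.
        raise ConfigError(f"{path}: {exc}") from exc


def load_sim_config(path: str | Path) -> SimConfig:
    return _load(path, SimConfig, "SimConfig")


def load_run_config(path: str | Path) -> RunConfig:
    return _load(path, RunConfig, "RunConfig")
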