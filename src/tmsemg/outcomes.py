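"""Trial gating, session normalization and per-session TMS outcome derivation.

Covers the measurement rules of the protocol: trials are accepted when
delivered within the valid range of motion and with pre-stimulus rmsEMG at
5% +/- 2% of the session's maximal isometric rmsEMG; the first 10 accepted
trials of each block enter analysis; MEP peak-to-peak amplitudes are
normalized to the session's maximal isometric rmsEMG; the recruitment curve
spans 110-170 %AMT with its area taken by trapezoidal integration; SICI/ICF
are ratios of the paired-pulse test MEP to the 120 %AMT single-pulse MEP and
LICI the ratio of its test MEP to its own conditioning MEP; the active motor
threshold is the lowest stimulator intensity at which at least five of ten
stimuli evoke MEPs of at least 0.5 mV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .signal import EmgTrace, bandpass_filter, rms

logger = logging.getLogger(__name__)


class GatingError(ValueError):
    pass


class IncompleteOutcomeError(ValueError):
    """Fewer accepted trials than the analysis requires."""


@dataclass
class TrialRecord:
    """Delivery metadata plus acceptance status for one stimulation."""

    subject_id: str
    session: int
    mode: str
    test_type: str
    trial_index: int
    in_rom: bool
    prestim_fraction: float
    accepted: bool


@dataclass
class SessionNormalization:
    """Largest rmsEMG across a session's isometric MVC trials (mV)."""

    subject_id: str
    session: int
    max_rms: float

    def __post_init__(self) -> None:
        if self.max_rms <= 0:
            raise GatingError("max_rms must be positive")


@dataclass
class SRCurve:
    """Stimulus-response (recruitment) curve over %AMT with its area."""

    intensities: tuple[float, ...]
    amplitudes: tuple[float, ...]
    aurc: float = field(init=False)

    def __post_init__(self) -> None:
        order = np.argsort(self.intensities)
        self.intensities = tuple(float(self.intensities[i]) for i in order)
        self.amplitudes = tuple(float(self.amplitudes[i]) for i in order)
        if any(b <= a for a, b in zip(self.intensities, self.intensities[1:])):
            raise GatingError("intensities must be strictly increasing")
        if any(a < 0 for a in self.amplitudes):
            raise GatingError("amplitudes must be non-negative")
        self.aurc = aurc(self.intensities, self.amplitudes)


@dataclass
class AmtResult:
    """Active motor threshold in % of maximal stimulator output."""

    subject_id: str
    amt: float | None
    responder: bool


def gate_trial(prestim_fraction: float, in_rom: bool, target: float = 0.05,
               tol: float = 0.02) -> bool:
    """Trial acceptance: in range of motion and background within target +/- tol.

    Bounds are inclusive: a pre-stimulus fraction of exactly 3% or 7% (at the
    default 5% +/- 2% window) is accepted.
    """
    if prestim_fraction < 0:
        raise GatingError("prestim_fraction must be non-negative")
    eps = 1e-12  # keep the stated bounds inclusive despite binary rounding
    return bool(in_rom) and (target - tol - eps <= prestim_fraction
                             <= target + tol + eps)


def select_first_n_accepted(trials: Sequence[TrialRecord], n: int = 10
                            ) -> list[TrialRecord]:
    """The first ``n`` accepted trials in delivery order."""
    out = [t for t in trials if t.accepted][:n]
    if len(out) < n:
        raise IncompleteOutcomeError(
            f"only {len(out)} accepted trials of {n} required")
    return out


def session_max_rms(subject_id: str, session: int,
                    mvc_traces: Sequence[EmgTrace],
                    filter_low: float = 13.0, filter_high: float = 500.0,
                    filter_order: int = 4, edge_ms: float = 50.0
                    ) -> SessionNormalization:
    """Largest rmsEMG over the session's filtered isometric MVC trials.

    The first and last ``edge_ms`` of each filtered trace are excluded so the
    zero-lag filter's edge transients do not leak into the steady-state
    contraction window that defines the normalizer.
    """
    if not mvc_traces:
        raise GatingError(f"no MVC trials for {subject_id} session {session}")
    values = []
    for t in mvc_traces:
        filtered = bandpass_filter(t, filter_low, filter_high, filter_order)
        edge = int(round(edge_ms * t.sampling_rate / 1000.0))
        interior = filtered.samples[edge:filtered.samples.size - edge]
        values.append(rms(interior if interior.size else filtered.samples))
    return SessionNormalization(subject_id, session, max(values))


def normalize_ppa(ppa: float, norm: SessionNormalization) -> float:
    """Dimensionless MEP size: PPA (mV) / maximal isometric rmsEMG (mV)."""
    if norm.max_rms <= 0:
        raise GatingError("normalizer must be positive")
    return ppa / norm.max_rms


def aurc(intensities: Sequence[float], amplitudes: Sequence[float]) -> float:
    """Area under the recruitment curve by trapezoidal integration."""
    x = np.asarray(intensities, dtype=float)
    y = np.asarray(amplitudes, dtype=float)
    if x.size != y.size or x.size < 2:
        raise GatingError("need >= 2 matching intensity/amplitude points")
    return float(np.trapezoid(y, x))


def build_sr_curve(amplitudes_by_intensity: Mapping[float, float],
                   required: Sequence[float] = (110, 130, 150, 170)) -> SRCurve:
    """Assemble the recruitment curve; all required intensities must be present."""
    missing = [i for i in required if i not in amplitudes_by_intensity]
    if missing:
        raise GatingError(f"missing stimulus intensities: {missing}")
    intensities = tuple(sorted(float(i) for i in required))
    amps = tuple(float(amplitudes_by_intensity[i]) for i in sorted(required))
    return SRCurve(intensities, amps)


def _ratio(test_mep: float, reference_mep: float, name: str) -> float:
    if reference_mep <= 0:
        raise GatingError(f"{name}: reference MEP must be positive")
    return test_mep / reference_mep


def sici_ratio(test_mep: float, amt120_mep: float) -> float:
    """Short-interval intracortical inhibition: test MEP / 120 %AMT MEP (<1 inhibits)."""
    return _ratio(test_mep, amt120_mep, "SICI")


def icf_ratio(test_mep: float, amt120_mep: float) -> float:
    """Intracortical facilitation: test MEP / 120 %AMT MEP (>1 facilitates)."""
    return _ratio(test_mep, amt120_mep, "ICF")


def lici_ratio(test_mep: float, conditioning_mep: float,
               test_detectable: bool = True,
               conditioning_detectable: bool = True) -> tuple[float | None, bool]:
    """Long-interval intracortical inhibition: test MEP / conditioning MEP.

    When the second (test) MEP is not distinct from the noise floor the
    session's LICI outcome is invalid: returns ``(None, False)``.
    """
    if not conditioning_detectable or conditioning_mep <= 0:
        raise GatingError("LICI: conditioning MEP undetectable")
    if not test_detectable:
        return None, False
    return test_mep / conditioning_mep, True


def determine_amt(blocks: Sequence[tuple[float, Sequence[float]]],
                  subject_id: str = "", threshold_mv: float = 0.5,
                  min_count: int = 5) -> AmtResult:
    """Active motor threshold from descending-intensity stimulus blocks.

    Each block is ``(intensity %MSO, 10 PPAs in mV)``; the threshold is the
    lowest tested intensity whose block has at least ``min_count`` PPAs at or
    above ``threshold_mv``. With no qualifying block the subject is a
    non-responder.
    """
    if not blocks:
        raise GatingError("no intensity blocks provided")
    intensities = [float(i) for i, _ in blocks]
    if any(b >= a for a, b in zip(intensities, intensities[1:])):
        raise GatingError("intensities must be strictly decreasing")
    if intensities[0] > 100:
        raise GatingError("intensities are % of maximal stimulator output (<= 100)")
    qualifying = []
    for intensity, ppas in blocks:
        ppas = list(ppas)
        if len(ppas) != 10:
            raise GatingError(f"block at {intensity}% must contain 10 PPAs, "
                              f"got {len(ppas)}")
        if sum(p >= threshold_mv for p in ppas) >= min_count:
            qualifying.append(intensity)
    if not qualifying:
        return AmtResult(subject_id, None, False)
    return AmtResult(subject_id, min(qualifying), True)


def find_hotspot(site_ppas: Sequence[tuple[str, Sequence[float]]] | Mapping[str, Sequence[float]]
                 ) -> str:
    """Optimal stimulation site: largest mean PPA of three stimulations.

    Ties break toward the first-visited site (and are logged). Site order is
    the iteration order of the input.
    """
    items = list(site_ppas.items()) if isinstance(site_ppas, Mapping) else list(site_ppas)
    if not items:
        raise GatingError("no candidate sites")
    best_site, best_mean = None, -math.inf
    for site, ppas in items:
        ppas = list(ppas)
        if len(ppas) != 3:
            raise GatingError(f"site {site!r} needs exactly 3 stimulations, "
                              f"got {len(ppas)}")
        m = float(np.mean(ppas))
        if m == best_mean:
            logger.info("hotspot tie between %r and %r; keeping first-visited %r",
                        best_site, site, best_site)
        if m > best_mean:
            best_site, best_mean = site, m
    return best_site
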