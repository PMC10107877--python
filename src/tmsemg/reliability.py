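"""Test-retest reliability battery over the tidy per-session outcome table.

For each outcome x contraction mode, reliability is assessed over the two
consecutive session pairs (1 -> 2 and 2 -> 3) with pairwise complete cases:

* ICC(3,1): two-way mixed, single-measure, consistency intraclass
  correlation, ``(MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error)``
  from the subjects x sessions ANOVA with k = 2.
* Typical error (TE): SD of the pairwise difference scores divided by
  sqrt(2) -- the within-subject SD of a single measurement.
* CV%: TE of the natural-log-transformed scores, back-transformed to a
  percentage, ``100 (exp(te_ln) - 1)``; scale-invariant.
* MDC95 = TE x 1.96 x sqrt(2), the change needed to exceed measurement noise
  with 95% confidence.
* SWC = 0.2 x between-subject SD (of subject means across available
  sessions), also expressed as a percentage of the grand mean (%SWC).

The point estimates reported per outcome are the arithmetic means of the two
session pairs. A measure is flagged ``sensitive`` when its CV% is below its
%SWC, i.e. when measurement noise is smaller than the smallest change worth
detecting. ICC point estimates are banded as poor (< .40), fair (.40-.59),
good (.60-.74) or excellent (>= .75).

Confidence intervals (reported, never used for banding): TE via chi-square
limits on the difference-score SD, ICC via the exact F method for the
consistency ICC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

SESSION_PAIRS = ((1, 2), (2, 3))


class ReliabilityError(ValueError):
    pass


class DegenerateVarianceError(ReliabilityError):
    """Total variance is zero: the ICC is undefined."""


@dataclass
class PairStats:
    """Reliability statistics for one consecutive session pair."""

    session_pair: tuple[int, int]
    n_subjects_used: int
    icc: float
    icc_ci: tuple[float, float]
    te: float
    te_ci: tuple[float, float]
    cv_pct: float
    cv_pct_ci: tuple[float, float]


@dataclass
class ReliabilityResult:
    """Aggregated reliability for one outcome in one contraction mode."""

    outcome: str
    mode: str
    pairs: list[PairStats]
    icc_mean: float
    te_mean: float
    cv_pct_mean: float
    mdc95: float
    swc: float
    pct_swc: float
    band: str
    sensitive: bool
    session_means: dict  # session -> (mean, sd, n)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Display rounding matching conventional table formatting (half away from zero)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def icc_3_1(scores: np.ndarray | Sequence[Sequence[float]]) -> float:
    """ICC(3,1): two-way mixed, single measures, consistency.

    ``scores`` is an n-subjects x k-sessions matrix of complete cases.
    """
    icc, _ = _icc_3_1_with_ci(scores)
    return icc


def _anova_mean_squares(m: np.ndarray) -> tuple[float, float, int, int]:
    n, k = m.shape
    grand = m.mean()
    ss_rows = k * np.sum((m.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((m.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    return ms_rows, ms_err, n, k


def _icc_3_1_with_ci(scores, conf: float = 0.95) -> tuple[float, tuple[float, float]]:
    m = np.asarray(scores, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ReliabilityError("scores must be an n x k matrix with k >= 2")
    if np.isnan(m).any():
        raise ReliabilityError("scores must be complete cases (no NaN)")
    if m.shape[0] < 3:
        raise ReliabilityError("need at least 3 subjects")
    ms_rows, ms_err, n, k = _anova_mean_squares(m)
    denom = ms_rows + (k - 1) * ms_err
    if denom == 0:
        raise DegenerateVarianceError("zero total variance: ICC undefined")
    icc = (ms_rows - ms_err) / denom
    if ms_err == 0:
        return icc, (icc, icc)
    alpha = 1 - conf
    f_obs = ms_rows / ms_err
    df1, df2 = n - 1, (n - 1) * (k - 1)
    fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    lo = (fl - 1) / (fl + k - 1)
    hi = (fu - 1) / (fu + k - 1)
    return icc, (lo, hi)


def typical_error(scores_a: Sequence[float], scores_b: Sequence[float]) -> float:
    """Within-subject SD of one measurement: SD(differences) / sqrt(2)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size != b.size:
        raise ReliabilityError("sessions must have matching subjects")
    if a.size < 2:
        raise ReliabilityError("need at least 2 complete pairs")
    return float(np.std(b - a, ddof=1) / math.sqrt(2.0))


def _te_ci(scores_a, scores_b, conf: float = 0.95) -> tuple[float, float]:
    diffs = np.asarray(scores_b, dtype=float) - np.asarray(scores_a, dtype=float)
    n = diffs.size
    sd = float(np.std(diffs, ddof=1))
    alpha = 1 - conf
    lo = sd * math.sqrt((n - 1) / stats.chi2.ppf(1 - alpha / 2, n - 1))
    hi = sd * math.sqrt((n - 1) / stats.chi2.ppf(alpha / 2, n - 1))
    return lo / math.sqrt(2.0), hi / math.sqrt(2.0)


def cv_percent(scores_a: Sequence[float], scores_b: Sequence[float]) -> float:
    """Typical error as a coefficient of variation, via log-transform.

    ``100 (exp(te_ln) - 1)`` where ``te_ln`` is the typical error of the
    natural-log scores. Subjects with non-positive values in either session
    cannot be log-transformed and are dropped with a warning.
    """
    a, b = _positive_pairs(scores_a, scores_b)
    return 100.0 * (math.exp(typical_error(np.log(a), np.log(b))) - 1.0)


def _positive_pairs(scores_a, scores_b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    ok = (a > 0) & (b > 0)
    if not ok.all():
        warnings.warn(
            f"dropping {int((~ok).sum())} subject(s) with non-positive values "
            "from CV% (log-transform undefined)", stacklevel=2)
    if ok.sum() < 2:
        raise ReliabilityError("fewer than 2 positive pairs for CV%")
    return a[ok], b[ok]


def _cv_ci(scores_a, scores_b, conf: float = 0.95) -> tuple[float, float]:
    a, b = _positive_pairs(scores_a, scores_b)
    lo, hi = _te_ci(np.log(a), np.log(b), conf)
    return 100.0 * (math.exp(lo) - 1.0), 100.0 * (math.exp(hi) - 1.0)


def mdc95(te: float) -> float:
    """Minimal detectable change at 95% confidence: TE x 1.96 x sqrt(2)."""
    if te < 0:
        raise ReliabilityError("typical error must be non-negative")
    return te * 1.96 * math.sqrt(2.0)


def swc(session_values: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """Smallest worthwhile change: 0.2 x between-subject SD.

    ``session_values`` is either a tidy frame with ``subject_id`` and
    ``value`` columns or an n x k matrix (NaN allowed for missing sessions);
    subject means are taken across available sessions. Also returns the SWC
    as a percentage of the grand mean of all available values.
    """
    if isinstance(session_values, pd.DataFrame):
        means = session_values.groupby("subject_id")["value"].mean().to_numpy()
        grand = float(session_values["value"].mean())
    else:
        m = np.asarray(session_values, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(m, axis=1)
        means = means[~np.isnan(means)]
        grand = float(np.nanmean(m))
    if means.size < 3:
        raise ReliabilityError("need at least 3 subjects for SWC")
    sd = float(np.std(means, ddof=1))
    if sd == 0:
        return 0.0, 0.0
    value = 0.2 * sd
    return value, 100.0 * value / grand


def classify_icc(icc: float) -> str:
    """Qualitative ICC band: poor < .40 <= fair <= .59 < good <= .74 < excellent."""
    if not math.isfinite(icc):
        raise ReliabilityError("ICC must be finite")
    if icc < 0.40:
        return "poor"
    if icc < 0.60:
        return "fair"
    if icc < 0.75:
        return "good"
    return "excellent"


def pair_stats(scores_a: Sequence[float], scores_b: Sequence[float],
               session_pair: tuple[int, int]) -> PairStats:
    """All pairwise statistics for one session pair of complete cases."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 3:
        raise ReliabilityError(
            f"session pair {session_pair}: need >= 3 complete cases, got {a.size}")
    icc, icc_ci = _icc_3_1_with_ci(np.column_stack([a, b]))
    te = typical_error(a, b)
    return PairStats(session_pair, int(a.size), icc, icc_ci, te,
                     _te_ci(a, b), cv_percent(a, b), _cv_ci(a, b))


def summarize(outcome_table: pd.DataFrame, outcome: str, mode: str,
              session_pairs: Sequence[tuple[int, int]] = SESSION_PAIRS
              ) -> ReliabilityResult:
    """Full reliability battery for one outcome in one contraction mode.

    ``outcome_table`` is tidy: subject_id, session, mode, outcome, value.
    Each session pair uses its own complete cases (a subject missing one
    session drops out of that pair only); SWC uses all available values.
    """
    sub = outcome_table[(outcome_table["outcome"] == outcome)
                        & (outcome_table["mode"] == mode)]
    if sub.empty:
        raise ReliabilityError(f"no rows for outcome {outcome!r}, mode {mode!r}")
    wide = sub.pivot_table(index="subject_id", columns="session", values="value",
                           aggfunc="first")
    pairs = []
    for s1, s2 in session_pairs:
        if s1 not in wide.columns or s2 not in wide.columns:
            raise ReliabilityError(f"sessions {s1}/{s2} absent for {outcome} ({mode})")
        complete = wide[[s1, s2]].dropna()
        pairs.append(pair_stats(complete[s1].to_numpy(),
                                complete[s2].to_numpy(), (s1, s2)))
    icc_mean = float(np.mean([p.icc for p in pairs]))
    te_mean = float(np.mean([p.te for p in pairs]))
    cv_mean = float(np.mean([p.cv_pct for p in pairs]))
    swc_value, pct = swc(sub)
    session_means = {
        int(s): (float(wide[s].mean()), float(wide[s].std(ddof=1)),
                 int(wide[s].count()))
        for s in wide.columns
    }
    return ReliabilityResult(
        outcome=outcome, mode=mode, pairs=pairs, icc_mean=icc_mean,
        te_mean=te_mean, cv_pct_mean=cv_mean, mdc95=mdc95(te_mean),
        swc=swc_value, pct_swc=pct, band=classify_icc(icc_mean),
        sensitive=cv_mean < pct,
        session_means=session_means,
    )


def reliability_table(outcome_table: pd.DataFrame,
                      session_pairs: Sequence[tuple[int, int]] = SESSION_PAIRS
                      ) -> pd.DataFrame:
    """Run :func:`summarize` for every outcome x mode present; tidy report.

    Outcomes that cannot be summarized (too few complete cases, e.g. heavily
    excluded LICI) are skipped with a warning rather than failing the run.
    """
    rows = []
    for (mode, outcome), _ in outcome_table.groupby(["mode", "outcome"], sort=False):
        try:
            r = summarize(outcome_table, outcome, mode, session_pairs)
        except ReliabilityError as exc:
            warnings.warn(f"{outcome} ({mode}): {exc}", stacklevel=2)
            continue
        row = {"outcome": outcome, "mode": mode,
               "icc_mean": r.icc_mean, "te_mean": r.te_mean,
               "cv_pct_mean": r.cv_pct_mean, "mdc95": r.mdc95,
               "swc": r.swc, "pct_swc": r.pct_swc, "band": r.band,
               "sensitive": r.sensitive}
        for p in r.pairs:
            tag = f"s{p.session_pair[0]}{p.session_pair[1]}"
            row[f"n_{tag}"] = p.n_subjects_used
            row[f"icc_{tag}"] = p.icc
            row[f"icc_{tag}_lo"], row[f"icc_{tag}_hi"] = p.icc_ci
            row[f"te_{tag}"] = p.te
            row[f"cv_{tag}"] = p.cv_pct
        for s, (mean, sd, n) in sorted(r.session_means.items()):
            row[f"mean_s{s}"], row[f"sd_s{s}"], row[f"n_s{s}"] = mean, sd, n
        rows.append(row)
    return pd.DataFrame(rows)
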