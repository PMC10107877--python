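"""File dialects for the pipeline.

All artifacts are plain UTF-8 comma-separated text with a header row and
"." decimal separator:

* trace files -- three columns ``time_s, emg_mV, stim`` where ``stim`` is 0
  off-stimulus and 1/2 at the first/second stimulus-artifact sample;
* the study manifest -- one row per delivered trial with a resolvable
  ``trace_path`` relative to the manifest's directory;
* the tidy outcome table and the reliability report.

Ground truth is written as a YAML summary plus two CSV tables.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .reliability import round_half_up
from .signal import EmgTrace
from .synthetic import GroundTruth, Study

MANIFEST_COLUMNS = ["subject_id", "session", "mode", "test_type",
                    "trial_index", "in_rom", "trace_path"]


class IOError_(ValueError):
    pass


def write_trace(trace: EmgTrace, path: str | Path) -> None:
    n = trace.samples.size
    stim = np.zeros(n, dtype=int)
    for order, idx in enumerate(trace.stim_indices, start=1):
        stim[idx] = order
    t = np.arange(n) / trace.sampling_rate
    df = pd.DataFrame({"time_s": t, "emg_mV": trace.samples, "stim": stim})
    df.to_csv(path, index=False, float_format="%.9g")


def read_trace(path: str | Path) -> EmgTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "emg_mV", "stim"):
        if col not in df.columns:
            raise IOError_(f"{path}: trace file missing column {col!r}")
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise IOError_(f"{path}: trace too short")
    fs = 1.0 / float(np.median(np.diff(t)))
    stim_col = df["stim"].to_numpy()
    order = np.argsort(stim_col[stim_col > 0])
    stim_indices = tuple(int(i) for i in np.flatnonzero(stim_col > 0)[order])
    return EmgTrace(df["emg_mV"].to_numpy(), round(fs, 6), stim_indices)


def _trace_filename(sid: str, session: int, mode: str, test_type: str,
                    trial: int) -> str:
    return f"{sid}_s{session}_{mode}_{test_type}_t{trial:02d}.csv"


def write_study(study: Study, outdir: str | Path) -> Path:
    """Write manifest, per-trial trace files and ground truth; returns outdir."""
    outdir = Path(outdir)
    trace_dir = outdir / "traces"
    trace_dir.mkdir(parents=True, exist_ok=True)
    manifest = study.manifest.copy()
    paths = []
    for row in manifest.itertuples():
        fname = _trace_filename(row.subject_id, row.session, row.mode,
                                row.test_type, row.trial_index)
        key = (row.subject_id, row.session, row.mode, row.test_type,
               row.trial_index)
        write_trace(study.traces[key], trace_dir / fname)
        paths.append(f"traces/{fname}")
    manifest["trace_path"] = paths
    manifest[MANIFEST_COLUMNS].to_csv(outdir / "manifest.csv", index=False)
    write_ground_truth(study.ground_truth, outdir)
    return outdir


def write_ground_truth(gt: GroundTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    gt.trials.to_csv(outdir / "ground_truth_trials.csv", index=False,
                     float_format="%.9g")
    gt.expected_outcomes.to_csv(outdir / "ground_truth_outcomes.csv",
                                index=False, float_format="%.9g")
    summary = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(gt.config).items()},
        "expected_icc": {k: float(v) for k, v in gt.expected_icc.items()},
        "lici_missing_sessions": [list(x) for x in gt.lici_missing],
        "n_rejected_trials": int((~gt.trials["accepted"]).sum()),
        "tables": ["ground_truth_trials.csv", "ground_truth_outcomes.csv"],
    }
    (outdir / "ground_truth.yaml").write_text(
        yaml.safe_dump(summary, sort_keys=False))


def load_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise IOError_(f"{path}: manifest missing columns {sorted(missing)}")
    df["in_rom"] = df["in_rom"].astype(bool)
    return df


def load_traces(manifest: pd.DataFrame, base_dir: str | Path) -> dict:
    """Load every trace referenced by the manifest, keyed like the pipeline."""
    base = Path(base_dir)
    traces = {}
    for row in manifest.itertuples():
        p = base / row.trace_path
        if not p.exists():
            raise IOError_(f"unresolvable trace path: {p}")
        traces[(row.subject_id, row.session, row.mode, row.test_type,
                row.trial_index)] = read_trace(p)
    return traces


def write_outcomes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.9g")


def read_outcomes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def render_report(report: pd.DataFrame, mode: str | None = None) -> str:
    """Human-readable reliability table, two decimals, half-up rounding.

    Mirrors the standard layout: per-session mean +/- SD, mean ICC with the
    two pairwise 95% CIs, TE, CV%, MDC95 and %SWC per outcome row.
    """
    sub = report if mode is None else report[report["mode"] == mode]
    lines = []
    for m, block in sub.groupby("mode", sort=False):
        lines.append(f"== {m} ==")
        header = (f"{'Variable':<8} {'Session 1':>14} {'Session 2':>14} "
                  f"{'Session 3':>14} {'ICC':>6} {'band':>10} {'TE':>7} "
                  f"{'CV%':>7} {'MDC95':>7} {'%SWC':>7} {'sens':>5}")
        lines.append(header)
        for r in block.itertuples():
            def ms(s):
                mean = getattr(r, f"mean_s{s}", float("nan"))
                sd = getattr(r, f"sd_s{s}", float("nan"))
                n = getattr(r, f"n_s{s}", "")
                if pd.isna(mean):
                    return "-"
                return f"{round_half_up(mean):.2f}±{round_half_up(sd):.2f} (n={n})"

            lines.append(
                f"{r.outcome:<8} {ms(1):>14} {ms(2):>14} {ms(3):>14} "
                f"{round_half_up(r.icc_mean):>6.2f} {r.band:>10} "
                f"{round_half_up(r.te_mean):>7.2f} "
                f"{round_half_up(r.cv_pct_mean):>7.2f} "
                f"{round_half_up(r.mdc95):>7.2f} "
                f"{round_half_up(r.pct_swc):>7.2f} "
                f"{'yes' if r.sensitive else 'no':>5}")
        lines.append("")
    return "\n".join(lines)
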