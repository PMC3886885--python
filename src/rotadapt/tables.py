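"""Long-format result tables and their on-disk CSV schema.

Two tables are produced per simulation command: a trial-level table (one row
per realization x trial) and a summary table (one row per realization x
target). Each CSV gets a sidecar ``.schema.json`` describing columns and the
schema version, and a run ``manifest.json`` ties outputs to the exact
configuration and seeds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .experiments import RunResult
from .stats import performance_metrics, summarize_curve

__all__ = ["trials_table", "summary_table", "write_table", "read_table", "write_manifest"]

TABLE_SCHEMA_VERSION = 1

TRIAL_COLUMNS = ["realization", "t", "target_index", "E", "E_noiseless", "R", "n0_t", "gamma_t"]
SUMMARY_COLUMNS = [
    "realization",
    "target",
    "tau",
    "censored",
    "final_error",
    "performance",
    "noiseless_performance",
    "divergent",
]


def trials_table(runs: list[RunResult]) -> pd.DataFrame:
    """Stack per-trial records of several realizations into one long table."""
    frames = []
    for i, run in enumerate(runs):
        df = run.to_frame()
        df.insert(0, "realization", i)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[TRIAL_COLUMNS]


def summary_table(runs: list[RunResult], transient_fraction: float = 0.5) -> pd.DataFrame:
    """Per-realization, per-target summaries (duration, final error, performance).

    Durations are estimated on each target's own presentation series and
    reported in global trial units; performance excludes the first
    ``transient_fraction`` of the run.
    """
    rows = []
    for i, run in enumerate(runs):
        transient = int(transient_fraction * run.n_trials)
        if run.n_trials - transient < 10:
            transient = max(0, run.n_trials - 10)
        perf, nperf = performance_metrics(run, transient)
        m = int(run.target_index.max()) + 1 if run.n_trials else 1
        for j in range(m):
            idx, series = run.target_series(j, noiseless=False)
            if series.size == 0:
                continue
            s = summarize_curve(series)
            tau_global = int(idx[min(s.tau, len(idx) - 1)]) if not s.censored else run.n_trials
            rows.append(
                {
                    "realization": i,
                    "target": j,
                    "tau": tau_global,
                    "censored": s.censored,
                    "final_error": s.final_error,
                    "performance": perf,
                    "noiseless_performance": nperf,
                    "divergent": run.divergent,
                }
            )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def _schema(df: pd.DataFrame, name: str) -> dict:
    return {
        "table": name,
        "schema_version": TABLE_SCHEMA_VERSION,
        "columns": {c: str(df[c].dtype) for c in df.columns},
        "n_rows": int(len(df)),
    }


def write_table(df: pd.DataFrame, path: str | Path, name: str) -> None:
    """Write a CSV with a sidecar JSON schema file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    path.with_suffix(".schema.json").write_text(json.dumps(_schema(df, name), indent=2))


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_manifest(out_dir: str | Path, config_dict: dict, seeds: list[int]) -> Path:
    """Run manifest: config snapshot, per-realization seeds, package version."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config_dict,
        "seeds": [int(s) for s in seeds],
        "package_version": __version__,
        "table_schema_version": TABLE_SCHEMA_VERSION,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=float))
    return path
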