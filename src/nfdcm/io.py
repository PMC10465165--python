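"""Tabular file I/O: run TSVs with sidecar metadata, BIDS-style events,
log-evidence tables.  All round-trips are lossless to float precision."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .generative_model import RoiTimeSeries
from .regions import REGION_LABELS

__all__ = [
    "write_run_tsv",
    "read_run_tsv",
    "write_events",
    "read_events",
    "write_logev",
    "read_logev",
    "write_cohort",
]


class ParseError(ValueError):
    """Malformed tabular artifact."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_run_tsv(run: RoiTimeSeries, path: str | Path) -> None:
    """One row per volume, columns F, ACC, S, SMA (+condition); TR and
    run_id in a sidecar JSON next to the table."""
    path = Path(path)
    df = run.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    meta = {"TR": run.TR, "run_id": run.run_id, "regions": list(run.regions.labels)}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_run_tsv(path: str | Path) -> RoiTimeSeries:
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise ParseError(f"missing TR sidecar {sidecar}; refusing to guess the TR")
    meta = json.loads(sidecar.read_text())
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in REGION_LABELS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing region columns {missing}")
    for c in REGION_LABELS:
        if not np.issubdtype(df[c].dtype, np.number):
            bad = df[pd.to_numeric(df[c], errors="coerce").isna()].index
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise ParseError(f"{path}: non-numeric value in column {c} at line {line}")
    data = df[list(REGION_LABELS)].to_numpy().T
    labels = list(df["condition"]) if "condition" in df.columns else None
    return RoiTimeSeries(
        data=data, TR=float(meta["TR"]), run_id=meta.get("run_id", path.stem),
        condition_labels=labels,
    )


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events[["onset", "duration", "trial_type"]].to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("onset", "duration", "trial_type"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing events column '{col}'")
    for col in ("onset", "duration"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            raise ParseError(
                f"{path}: non-numeric {col} at line {int(np.argmax(bad.to_numpy())) + 2}"
            )
    df = df.sort_values("onset").reset_index(drop=True)
    ends = (df["onset"] + df["duration"]).to_numpy()
    if np.any(df["onset"].to_numpy()[1:] < ends[:-1] - 1e-9):
        raise ParseError(f"{path}: overlapping blocks")
    return df


def write_logev(log_ev: pd.DataFrame, path: str | Path) -> None:
    log_ev.to_csv(path, sep="\t", index_label="subject", float_format="%.17g")


def read_logev(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="subject")
    if not np.all(np.isfinite(df.to_numpy())):
        raise ParseError(f"{path}: non-finite log evidence")
    return df


def write_cohort(cohort, outdir: str | Path) -> None:
    """Per-run TSV + events + a cohort manifest with ground truth."""
    from .synthetic_cohort import design_events

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ev = design_events(cohort.design)
    write_events(ev, outdir / "task-training_events.tsv")
    for sid, runs in cohort.training_runs.items():
        for run in runs:
            write_run_tsv(run, outdir / f"{run.run_id}.tsv")
    for sid, run in cohort.baseline_runs.items():
        write_run_tsv(run, outdir / f"{run.run_id}.tsv")
    for sid, run in cohort.transfer_runs.items():
        write_run_tsv(run, outdir / f"{run.run_id}.tsv")
    (outdir / "cohort_manifest.json").write_text(json.dumps(cohort.manifest(), indent=1))
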