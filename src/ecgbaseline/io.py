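"""Plain-text readers and writers.

Records travel as a CSV/JSON bundle: a signal CSV with one row per sample and
12 lead columns (standard lead names in the header, amplitudes in mV,
full-precision ``%.17g`` floats so round-trips are bit-exact) plus a JSON
sidecar holding the sampling rate, beat onsets, ST windows (0-based,
half-open ``[start, end)``), the seed and the generator parameters needed to
regenerate the record without the CSV.  Metric tables and summary tables are
CSV with frozen column orders.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError
from .evaluation import METRIC_COLUMNS, SummaryTable
from .synthetic import LEAD_NAMES, EcgRecord

__all__ = [
    "RecordBundle",
    "write_record",
    "read_record",
    "write_metrics",
    "read_metrics",
    "write_summary",
]

_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class RecordBundle:
    """Paths of one record on disk (signal CSV + JSON sidecar)."""

    csv_path: Path
    sidecar_path: Path


def _bundle_paths(path) -> RecordBundle:
    base = Path(path)
    if base.suffix == ".csv":
        base = base.with_suffix("")
    return RecordBundle(csv_path=base.with_suffix(".csv"),
                        sidecar_path=base.with_suffix(".json"))


def write_record(record: EcgRecord, path) -> RecordBundle:
    """Write a record bundle; ``path`` may omit the extension."""
    bundle = _bundle_paths(path)
    names = LEAD_NAMES if record.n_leads == len(LEAD_NAMES) else [
        f"lead{i + 1}" for i in range(record.n_leads)
    ]
    frame = pd.DataFrame(record.leads.T, columns=list(names))
    frame.to_csv(bundle.csv_path, index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "fs": record.fs,
        "n_samples": record.n_samples,
        "n_leads": record.n_leads,
        "lead_names": list(names),
        "beat_onsets": record.beat_onsets.tolist(),
        "st_windows": record.st_windows.tolist(),
        "meta": record.meta,
    }
    bundle.sidecar_path.write_text(json.dumps(sidecar, indent=1))
    return bundle


def read_record(path) -> EcgRecord:
    """Read and validate a record bundle written by :func:`write_record`."""
    bundle = _bundle_paths(path)
    if not bundle.csv_path.exists():
        raise ContractError(f"missing signal file {bundle.csv_path}")
    if not bundle.sidecar_path.exists():
        raise ContractError(
            f"missing sidecar {bundle.sidecar_path}: beat/ST annotations are "
            "required for the spline filter and the K-point statistic"
        )
    sidecar = json.loads(bundle.sidecar_path.read_text())
    frame = pd.read_csv(bundle.csv_path, float_precision="round_trip")
    if len(frame) != sidecar["n_samples"]:
        raise ContractError(
            f"{bundle.csv_path}: {len(frame)} rows but sidecar declares "
            f"{sidecar['n_samples']} samples"
        )
    record = EcgRecord(
        leads=frame.to_numpy().T,
        fs=float(sidecar["fs"]),
        beat_onsets=np.asarray(sidecar["beat_onsets"], dtype=int),
        st_windows=np.asarray(sidecar["st_windows"], dtype=int),
        meta=sidecar.get("meta", {}),
    )
    return record


def write_metrics(rows: pd.DataFrame, path) -> Path:
    """Write a metric-row table with the frozen column order."""
    path = Path(path)
    rows.loc[:, METRIC_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_metrics(path) -> pd.DataFrame:
    rows = pd.read_csv(path, float_precision="round_trip")
    missing = set(METRIC_COLUMNS) - set(rows.columns)
    if missing:
        raise ContractError(f"metric table misses columns {sorted(missing)}")
    return rows[METRIC_COLUMNS].astype({"snr_db": float, "elapsed": float})


def write_summary(summary: SummaryTable, path) -> Path:
    """Write the MED/IQR summary (one row per method) as CSV."""
    path = Path(path)
    summary.table.to_csv(path, index_label="filter")
    winners_path = path.with_suffix(".winners.json")
    serializable = {
        crit: {k: v for k, v in w.items() if k != "criterion"}
        for crit, w in summary.winners.items()
    }
    winners_path.write_text(json.dumps(serializable, indent=1, default=float))
    return path
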