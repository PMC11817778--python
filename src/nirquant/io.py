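"""Reading and writing the wide spectra CSV and the result report tables.

Spectra dialect: UTF-8, comma-separated, '.' decimal; header
``sample_id,fA,fB,fC,<wavenumber>,...`` with wavenumbers in descending order
printed to 3 decimal places; one row per sample.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import TARGET_COLUMNS, SpectraSet
from .errors import FormatError, ReportError
from .evaluate import REPORT_COLUMNS

_META_COLS = ("sample_id", "fA", "fB", "fC")


def write_spectra_csv(data: SpectraSet, path) -> Path:
    """Write a SpectraSet in the wide-CSV dialect."""
    path = Path(path)
    header = list(_META_COLS) + [f"{w:.3f}" for w in data.wavenumbers]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(header) + "\n")
        t = data.targets[list(TARGET_COLUMNS)].to_numpy(float)
        for i in range(data.n_samples):
            vals = [data.sample_ids[i]] + [repr(float(v)) for v in t[i]]
            vals += [repr(float(v)) for v in data.absorbance[i]]
            fh.write(",".join(vals) + "\n")
    return path


def read_spectra_csv(path) -> SpectraSet:
    """Read and validate a wide spectra CSV.

    Raises :class:`FormatError` naming the offending column or row on missing
    target columns, a non-descending wavenumber header, NaN cells, or rows
    violating fC = fA + fB (within 1e-6).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str})
    for col in _META_COLS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path.name}")
    wav_cols = [c for c in df.columns if c not in _META_COLS]
    try:
        wavenumbers = np.array([float(c) for c in wav_cols])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavenumber column in {path.name}: {exc}") from None
    if wavenumbers.size >= 2 and not (np.diff(wavenumbers) < 0).all():
        raise FormatError(f"wavenumber header not strictly descending in {path.name}")
    if len(df):
        nan_cols = df.columns[df.isna().any()].tolist()
        if nan_cols:
            col = nan_cols[0]
            row = int(df.index[df[col].isna()][0])
            raise FormatError(f"NaN cell in column {col!r}, row {row} of {path.name}")
        mismatch = (df["fA"] + df["fB"] - df["fC"]).abs() > 1e-6
        if mismatch.any():
            row = int(df.index[mismatch][0])
            raise FormatError(f"fC != fA + fB at row {row} of {path.name}")
    absorbance = df[wav_cols].to_numpy(float).reshape(len(df), len(wav_cols))
    return SpectraSet(wavenumbers, absorbance, df[["fA", "fB", "fC"]],
                      df["sample_id"].tolist())


# ------------------------------------------------------------------ reports


def _format_report(report: pd.DataFrame) -> pd.DataFrame:
    if report is None or len(report) == 0:
        raise ReportError("empty report")
    missing = [c for c in REPORT_COLUMNS if c not in report.columns]
    if missing:
        raise ReportError(f"report missing columns {missing}")
    metric_cols = ["RC2", "RMSEC", "RP2", "RMSEP", "RMSECV"]
    required = [c for c in metric_cols if c != "RMSECV"]
    if report[required].isna().any().any():
        raise ReportError("report has incomplete metric rows")
    out = report[REPORT_COLUMNS].copy()
    for c in metric_cols:
        out[c] = report[c].map(lambda v: f"{v:.4f}" if pd.notna(v) else "")
    return out


def write_report(report: pd.DataFrame, path_base) -> tuple[Path, Path]:
    """Write CSV and JSON twins of a report table, metrics to 4 decimals.

    ``path_base`` may end in ``.csv`` or have no suffix; the JSON twin sits
    next to it.  Returns (csv_path, json_path).
    """
    base = Path(path_base)
    if base.suffix == ".csv":
        base = base.with_suffix("")
    formatted = _format_report(report)
    csv_path = base.with_suffix(".csv")
    formatted.to_csv(csv_path, index=False)
    json_path = base.with_suffix(".json")
    records = formatted.to_dict(orient="records")
    json_path.write_text(json.dumps(records, indent=1) + "\n", encoding="utf-8")
    return csv_path, json_path


def read_report(csv_path) -> pd.DataFrame:
    """Read back a report CSV written by :func:`write_report`."""
    return pd.read_csv(csv_path)
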