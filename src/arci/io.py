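"""Text I/O: R-R interval files, result tables, config files.

The only standard input format is a plain-text R-R column (one interval per
line, optional header, or a CSV with an ``rr`` column) — the de-facto
interchange format in HRV work. Result tables are written as CSV or JSON with
a deterministic column order; undefined index values are serialized as the
explicit token ``"NA"``.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path

import numpy as np
import yaml

from .errors import RRParseError
from .series import TimeSeries
from .simulate import SimulationConfig
from .study import CohortResult, StudyRow

__all__ = [
    "read_rr_series",
    "write_results",
    "read_results",
    "load_config",
    "save_config",
    "convert_mat_cohort",
]

NA_TOKEN = "NA"


def read_rr_series(path: str | Path, units: str = "ms") -> TimeSeries:
    """Read a beat-to-beat R-R interval series from a text/CSV file.

    Values are converted to milliseconds; the sampling period is the mean R-R
    interval in seconds, mapping the beat-domain frequency axis to Hz.

    Parameters
    ----------
    path
        One numeric value per line (an optional single header line is
        skipped), or a CSV whose header names an ``rr`` column.
    units
        "ms" or "s" — the unit the file's numbers are expressed in.
    """
    if units not in ("ms", "s"):
        raise ValueError("units must be 'ms' or 's'")
    path = Path(path)
    lines = path.read_text().splitlines()
    stripped = [(i + 1, ln.strip()) for i, ln in enumerate(lines) if ln.strip()]
    if not stripped:
        raise RRParseError(f"{path}: file is empty")

    rr_col = None
    start = 0
    first = stripped[0][1]
    if "," in first or any(c.isalpha() for c in first):
        header = [h.strip().lower() for h in first.split(",")]
        if "rr" in header:
            rr_col = header.index("rr")
        start = 1  # single header line (with or without an rr column name)
        if start == len(stripped):
            raise RRParseError(f"{path}: no data rows after header")

    values = []
    for lineno, text in stripped[start:]:
        fields = text.split(",") if ("," in text or rr_col is not None) else [text]
        cell = fields[rr_col if rr_col is not None else 0].strip()
        try:
            v = float(cell)
        except ValueError:
            raise RRParseError(f"{path}: non-numeric value {cell!r} at line {lineno}") from None
        if not math.isfinite(v) or v <= 0:
            raise RRParseError(f"{path}: nonpositive R-R interval at line {lineno}")
        values.append(v)

    arr = np.array(values)
    if units == "s":
        arr = arr * 1000.0
    return TimeSeries(arr, sampling_period=float(arr.mean()) / 1000.0, label=path.stem)


def _fmt(value) -> str:
    if value is None:
        return NA_TOKEN
    if isinstance(value, float):
        if math.isnan(value):
            return NA_TOKEN
        return f"{value:.6g}"
    return str(value)


def _study_row_records(rows: list[StudyRow]) -> list[dict]:
    records = []
    for row in rows:
        rec: dict = {
            "label": row.label,
            "n_runs": row.n_runs,
            "n_failed": row.n_failed,
            "flagged": row.flagged,
        }
        for name, true_val in row.true_values.items():
            rec[f"true_{name}"] = true_val
        for name, pct in row.gold_percentiles.items():
            for q, v in pct.items():
                rec[f"gold_{name}_p{q}"] = v
        for meth, per_index in row.mean_percentiles.items():
            for name, pct in per_index.items():
                for q, v in pct.items():
                    rec[f"{meth}_{name}_p{q}"] = v
        for meth, per_index in row.detection_counts.items():
            for name, count in per_index.items():
                rec[f"detect_{meth}_{name}"] = count
        records.append(rec)
    return records


def _cohort_records(result: CohortResult) -> list[dict]:
    records = []
    for row in result.rows:
        rec: dict = {
            "subject": row.subject,
            "task": row.task,
            "order": row.order,
            "f_lf": row.indexes.f_lf,
            "p_lfhf": row.indexes.p_lfhf,
            "s_x": row.indexes.s_x,
        }
        for name in ("f_lf", "p_lfhf", "s_x"):
            summ = row.summaries.get(name)
            for q in (5, 25, 50, 75, 95):
                rec[f"{name}_p{q}"] = None if summ is None else summ.percentiles[q]
            rec[f"{name}_n_defined"] = None if summ is None else summ.n_defined
        records.append(rec)
    return records


def to_records(rows) -> list[dict]:
    """Flatten study rows / cohort results / plain dict rows into records."""
    if isinstance(rows, CohortResult):
        return _cohort_records(rows)
    if isinstance(rows, list) and rows and isinstance(rows[0], StudyRow):
        return _study_row_records(rows)
    if isinstance(rows, list) and all(isinstance(r, dict) for r in rows):
        return rows
    raise TypeError(f"cannot serialize rows of type {type(rows)!r}")


def write_results(rows, path: str | Path, format: str = "csv") -> None:
    """Write a result table with deterministic column order.

    Undefined values become the ``"NA"`` token; floats are rendered at 6
    significant digits (CSV) or kept full precision (JSON).
    """
    records = to_records(rows)
    if not records:
        raise ValueError("rows must be nonempty")
    path = Path(path)
    columns: list[str] = []
    for rec in records:
        for key in rec:
            if key not in columns:
                columns.append(key)
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(columns)
            for rec in records:
                writer.writerow([_fmt(rec.get(c)) for c in columns])
    elif format == "json":
        payload = [
            {
                c: (
                    NA_TOKEN
                    if rec.get(c) is None
                    or (isinstance(rec.get(c), float) and math.isnan(rec[c]))
                    else rec.get(c)
                )
                for c in columns
            }
            for rec in records
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError("format must be 'csv' or 'json'")


def read_results(path: str | Path) -> list[dict]:
    """Read back a JSON result table, mapping the NA token to None."""
    with open(path) as fh:
        payload = json.load(fh)
    return [
        {k: (None if v == NA_TOKEN else v) for k, v in rec.items()} for rec in payload
    ]


def load_config(path: str | Path) -> SimulationConfig:
    """Load a flat key-value (YAML) simulation configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    return SimulationConfig.from_dict(data)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def convert_mat_cohort(
    mat_path: str | Path, out_dir: str | Path, units: str = "ms"
) -> list[Path]:
    """Convert a cohort .mat file (task-named cell arrays of R-R series) into
    the canonical per-subject/task CSV layout consumed by the cohort pipeline.

    Each cell variable (e.g. ``rest``, ``math_silent``, ``math_aloud``)
    becomes files ``<task>_subject<NN>.csv`` with a single ``rr`` column.
    Optional convenience: the core pipeline only reads the CSVs it produces.
    """
    import scipy.io

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mat = scipy.io.loadmat(str(mat_path), squeeze_me=True)
    written: list[Path] = []
    for task, cells in mat.items():
        if task.startswith("__"):
            continue
        for i, rr in enumerate(np.atleast_1d(cells)):
            arr = np.asarray(rr, dtype=float).ravel()
            if units == "s":
                arr = arr * 1000.0
            dest = out_dir / f"{task}_subject{i + 1:02d}.csv"
            with open(dest, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["rr"])
                for v in arr:
                    writer.writerow([f"{v:.6g}"])
            written.append(dest)
    return written
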