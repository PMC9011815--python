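"""Reading and writing of electropherogram traces, sample sheets and result tables.

All on-disk formats are plain comma-separated UTF-8 text with a decimal point,
so files round-trip bit-exactly between writers and readers regardless of
locale. A trace file has a mandatory ``time_s,signal`` header and one row per
sample point; a sample sheet maps trace files to their experimental metadata.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import SampleSheetError, TraceFormatError

#: Minimum number of sample points for a valid trace.
MIN_POINTS = 500

#: Relative tolerance on the uniformity of the time grid.
GRID_RTOL = 1e-9

VALID_ROLES = ("ladder", "blank", "sample")

SHEET_REQUIRED = ("sample_id", "path", "role")
SHEET_OPTIONAL = ("conc_ug_ml", "temp_C", "time_days")


@dataclass
class TraceMeta:
    """Metadata attached to a trace, mirroring one sample-sheet row."""

    sample_id: str = ""
    role: str = "sample"
    conc_ug_ml: float | None = None
    temp_C: float | None = None
    time_days: float | None = None


@dataclass
class Trace:
    """A sampled electropherogram: fluorescence signal on a uniform time grid.

    Parameters
    ----------
    time
        Migration time in seconds, strictly increasing on a uniform grid.
    signal
        Fluorescence in arbitrary detector units, finite everywhere.
    meta
        Sample metadata (id, role, concentration, storage condition).
    """

    time: np.ndarray
    signal: np.ndarray
    meta: TraceMeta = field(default_factory=TraceMeta)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.signal.ndim != 1:
            raise TraceFormatError("time and signal must be one-dimensional")
        if self.time.size != self.signal.size:
            raise TraceFormatError(
                f"time ({self.time.size}) and signal ({self.signal.size}) length mismatch"
            )
        if self.time.size < MIN_POINTS:
            raise TraceFormatError(
                f"trace has {self.time.size} points; at least {MIN_POINTS} required"
            )
        diffs = np.diff(self.time)
        if np.any(diffs <= 0):
            raise TraceFormatError("time grid must be strictly increasing")
        dt = diffs[0]
        if np.any(np.abs(diffs - dt) > GRID_RTOL * dt):
            raise TraceFormatError("time grid must be uniform")
        if not np.all(np.isfinite(self.signal)):
            raise TraceFormatError("signal contains non-finite values")

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return float(self.time[1] - self.time[0])

    @property
    def span(self) -> float:
        """Total duration covered by the grid, in seconds."""
        return float(self.time[-1] - self.time[0])

    def __len__(self) -> int:
        return int(self.time.size)


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace as ``time_s,signal`` CSV; floats use %.17g so the file
    round-trips exactly through :func:`read_trace`."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("time_s,signal\n")
        for t, s in zip(trace.time, trace.signal):
            fh.write(f"{t:.17g},{s:.17g}\n")


def read_trace(path: str | Path, meta: TraceMeta | None = None) -> Trace:
    """Read a 2-column trace file, validating format row by row.

    Malformed rows are reported with their 1-based line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise TraceFormatError(f"trace file not found: {path}")
    try:
        frame = pd.read_csv(path, encoding="utf-8", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TraceFormatError(f"{path}: unreadable as CSV ({exc})") from exc
    cols = [c.strip() for c in frame.columns]
    if len(cols) < 2 or cols[0] != "time_s" or cols[1] != "signal":
        raise TraceFormatError(
            f"{path}: header must be 'time_s,signal', found {list(frame.columns)!r}"
        )
    # parse with Python float (correctly rounded) so %.17g files round-trip
    # bit-exactly; pandas' fast parser is not guaranteed exact
    def _parse(col: pd.Series, name: str) -> np.ndarray:
        vals = np.empty(len(col))
        bad: list[int] = []
        for i, raw in enumerate(col):
            try:
                vals[i] = float(raw)
            except (TypeError, ValueError):
                bad.append(i + 2)  # +1 header line, +1 one-based numbering
        if bad:
            raise TraceFormatError(
                f"{path}: non-numeric {name} cells at line(s) {bad[:10]}"
            )
        return vals

    time = _parse(frame.iloc[:, 0], "time_s")
    signal = _parse(frame.iloc[:, 1], "signal")
    if len(frame) < MIN_POINTS:
        raise TraceFormatError(
            f"{path}: {len(frame)} rows; at least {MIN_POINTS} required"
        )
    if meta is None:
        meta = TraceMeta(sample_id=path.stem)
    try:
        return Trace(time, signal, meta)
    except TraceFormatError as exc:
        raise TraceFormatError(f"{path}: {exc}") from exc


def write_sample_sheet(records: pd.DataFrame, path: str | Path) -> None:
    """Write a sample sheet (columns ``sample_id,path,role,conc_ug_ml,temp_C,time_days``)."""
    cols = [c for c in SHEET_REQUIRED + SHEET_OPTIONAL if c in records.columns]
    records.loc[:, cols].to_csv(path, index=False, encoding="utf-8")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample sheet.

    Returns a DataFrame with one validated record per row, order preserved.
    Roles must be one of ``ladder``, ``blank``, ``sample``; blanks may omit
    concentration / temperature / time. Duplicate sample ids are an error.
    """
    path = Path(path)
    if not path.exists():
        raise SampleSheetError(f"sample sheet not found: {path}")
    frame = pd.read_csv(path, encoding="utf-8")
    for col in SHEET_REQUIRED:
        if col not in frame.columns:
            raise SampleSheetError(f"{path}: missing required column '{col}'")
    roles = frame["role"].astype(str).str.strip()
    bad_roles = sorted(set(roles) - set(VALID_ROLES))
    if bad_roles:
        raise SampleSheetError(
            f"{path}: unknown role(s) {bad_roles}; expected one of {list(VALID_ROLES)}"
        )
    ids = frame["sample_id"].astype(str)
    dup = ids[ids.duplicated()].tolist()
    if dup:
        raise SampleSheetError(f"{path}: duplicate sample_id(s) {sorted(set(dup))}")
    out = frame.copy()
    out["sample_id"] = ids
    out["role"] = roles
    for col in SHEET_OPTIONAL:
        if col in out.columns:
            out[col] = pd.to_numeric(out[col], errors="coerce")
        else:
            out[col] = np.nan
    return out


def meta_from_record(record: pd.Series) -> TraceMeta:
    """Build a :class:`TraceMeta` from one sample-sheet row."""

    def _opt(key: str) -> float | None:
        val = record.get(key)
        if val is None or (isinstance(val, float) and np.isnan(val)):
            return None
        return float(val)

    return TraceMeta(
        sample_id=str(record["sample_id"]),
        role=str(record["role"]),
        conc_ug_ml=_opt("conc_ug_ml"),
        temp_C=_opt("temp_C"),
        time_days=_opt("time_days"),
    )


RESULT_COLUMNS = (
    "sample_id",
    "pct_main",
    "pct_fragments",
    "pct_hmw",
    "total_area",
    "main_size_nt",
    "flags",
)


def results_to_frame(results: Iterable) -> pd.DataFrame:
    """Collect :class:`~ribotrace.integration.IntegrityResult` objects into a
    result table (one row per trace)."""
    rows = []
    for res in results:
        rows.append(
            {
                "sample_id": res.sample_id,
                "pct_main": res.pct_main,
                "pct_fragments": res.pct_fragments,
                "pct_hmw": res.pct_hmw,
                "total_area": res.total_area,
                "main_size_nt": res.main_size_nt,
                "flags": ";".join(res.flags),
            }
        )
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def write_result_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")


def read_result_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, encoding="utf-8")
    if "flags" in frame.columns:
        frame["flags"] = frame["flags"].fillna("")
    return frame


def config_hash(config: dict) -> str:
    """Stable sha256 of a JSON-serialisable config mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()


def write_run_report(path: str | Path, *, config: dict, seed: int | None,
                     payload: dict) -> None:
    """Write the structured JSON run report (config hash, seed, version, results).

    The report is fully deterministic for a given (config, seed, payload):
    no timestamps or host information are recorded.
    """
    from . import __version__

    report = {
        "software": "ribotrace",
        "version": __version__,
        "seed": seed,
        "config_sha256": config_hash(config),
        "config": config,
    }
    report.update(payload)
    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_json_default) + "\n",
        encoding="utf-8",
    )


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
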