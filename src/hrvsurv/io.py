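"""File readers and writers for the package's plain-text formats.

* R-R series: one PPI in milliseconds per line; blank lines and lines
  starting with ``#`` are ignored.
* ECG traces: two whitespace/comma-separated columns (time s, amplitude), or
  a single amplitude column with the sampling rate declared in a header
  comment ``# sampling_rate: 1024``.
* Cohorts: CSV with the column dictionary of
  :data:`hrvsurv.simulate.COHORT_COLUMNS`.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputError, SchemaError, ValidityError
from .simulate import COHORT_COLUMNS
from .spectral import BeatSeries, EcgTrace

__all__ = [
    "read_rr_file",
    "write_rr_file",
    "read_ecg_file",
    "read_cohort_csv",
    "write_cohort_csv",
    "REQUIRED_COHORT_COLUMNS",
]

#: columns a cohort CSV must provide for the analysis pipeline
REQUIRED_COHORT_COLUMNS = (
    "age", "sex", "muscle_power", "cognitive_impairment", "edema", "jaundice",
    "ascites", "ecog_34", "ln_tp", "ln_hfp", "ln_lf_hf",
    "survival_days", "death_observed", "event_7d",
)


def _data_lines(path: Path):
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        yield lineno, line


def read_rr_file(path) -> BeatSeries:
    """Read a plain-text PPI file (ms per line) into a beat series."""
    path = Path(path)
    ppi = []
    for lineno, line in _data_lines(path):
        try:
            value = float(line)
        except ValueError:
            raise InputError(f"{path}:{lineno}: malformed PPI value {line!r}") from None
        if value <= 0:
            raise ValidityError(f"{path}:{lineno}: non-positive PPI {value}")
        ppi.append(value)
    if len(ppi) < 1:
        raise InputError(f"{path}: no PPI values found")
    return BeatSeries.from_ppi(np.array(ppi))


def write_rr_file(beats: BeatSeries, path) -> None:
    path = Path(path)
    header = "# R-R intervals, one per line, milliseconds\n"
    body = "\n".join(f"{v:.6f}" for v in beats.ppi)
    path.write_text(header + body + "\n")


_RATE_RE = re.compile(r"#\s*sampling_rate\s*[:=]\s*([0-9.]+)")


def read_ecg_file(path) -> EcgTrace:
    """Read an ECG trace from two-column (time, amplitude) or single-column
    text; single-column files must declare the sampling rate in a comment."""
    path = Path(path)
    rate = None
    for m in map(_RATE_RE.search, path.read_text().splitlines()):
        if m:
            rate = float(m.group(1))
            break
    rows = []
    for lineno, line in _data_lines(path):
        parts = re.split(r"[,\s]+", line)
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            raise InputError(f"{path}:{lineno}: malformed ECG line {line!r}") from None
    if not rows:
        raise InputError(f"{path}: no samples found")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise InputError(f"{path}: inconsistent column count")
    arr = np.asarray(rows, dtype=float)
    if ncol == 1:
        if rate is None:
            raise InputError(f"{path}: single-column ECG needs '# sampling_rate: <Hz>'")
        return EcgTrace(arr[:, 0], rate)
    if ncol == 2:
        dt = np.diff(arr[:, 0])
        if np.any(dt <= 0) or np.ptp(dt) > 1e-6 * dt.mean():
            raise InputError(f"{path}: time column must be uniform and increasing")
        return EcgTrace(arr[:, 1], 1.0 / float(dt.mean()))
    raise InputError(f"{path}: expected 1 or 2 columns, found {ncol}")


def read_cohort_csv(path, required=REQUIRED_COHORT_COLUMNS) -> pd.DataFrame:
    """Read and schema-check a cohort CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    if (pd.to_numeric(df["survival_days"], errors="coerce") < 0).any():
        raise ValidityError(f"{path}: negative survival_days")
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        # extra columns are carried through untouched, not an error
        pass
    return df


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False, float_format="%.9g")
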