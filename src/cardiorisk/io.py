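"""Readers and writers for the UCI table dialect and plain signal files."""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .ecg import ECGSignal, RPeakSet
from .errors import InvalidInputError
from .preprocess import FEATURE_COLUMNS, TARGET_COLUMN, FeatureTable

logger = logging.getLogger(__name__)

#: Column order of the processed 14-attribute dialect; "?" marks missing.
UCI_COLUMNS = (
    "age", "sex", "cp", "trestbps", "chol", "fbs", "restecg",
    "thalach", "exang", "oldpeak", "slope", "ca", "thal", "num",
)

#: Attributes requiring in-hospital tests, dropped on read.
DROPPED_COLUMNS = ("ca", "thal")


def _looks_like_header(fields) -> bool:
    def numeric(tok: str) -> bool:
        tok = tok.strip()
        if tok in ("", "?"):
            return True
        try:
            float(tok)
            return True
        except ValueError:
            return False

    return not all(numeric(f) for f in fields)


def read_uci_csv(path) -> FeatureTable:
    """Parse a comma-separated patient file in the UCI dialect.

    Accepts the full 14-column order or the already-reduced 12-column
    variant (features + num), with or without a header line; "?" becomes a
    missing value.  A row with the wrong field count raises with its line
    number.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    rows = [(i + 1, [f.strip() for f in r]) for i, r in enumerate(rows)
            if any(f.strip() for f in r)]
    if not rows:
        logger.warning("empty table file %s", path)
        return FeatureTable(
            pd.DataFrame(columns=list(FEATURE_COLUMNS) + [TARGET_COLUMN]), "raw"
        )
    start = 0
    if _looks_like_header(rows[0][1]):
        start = 1
    body = rows[start:]
    if not body:
        logger.warning("header-only table file %s", path)
        return FeatureTable(
            pd.DataFrame(columns=list(FEATURE_COLUMNS) + [TARGET_COLUMN]), "raw"
        )
    width = len(body[0][1])
    if width == len(UCI_COLUMNS):
        columns = UCI_COLUMNS
    elif width == len(FEATURE_COLUMNS) + 1:
        columns = tuple(FEATURE_COLUMNS) + (TARGET_COLUMN,)
    else:
        raise InvalidInputError(
            f"{path}: line {body[0][0]}: expected "
            f"{len(UCI_COLUMNS)} or {len(FEATURE_COLUMNS) + 1} fields, "
            f"got {width}"
        )
    parsed = []
    for lineno, fields in body:
        if len(fields) != width:
            raise InvalidInputError(
                f"{path}: line {lineno}: expected {width} fields, "
                f"got {len(fields)}"
            )
        record = []
        for col, tok in zip(columns, fields):
            if tok in ("?", ""):
                record.append(np.nan)
            else:
                try:
                    record.append(float(tok))
                except ValueError as exc:
                    raise InvalidInputError(
                        f"{path}: line {lineno}: non-numeric value {tok!r} "
                        f"in column {col!r}"
                    ) from exc
        parsed.append(record)
    df = pd.DataFrame(parsed, columns=list(columns))
    df = df.drop(columns=[c for c in DROPPED_COLUMNS if c in df.columns])
    logger.info("read %d record(s), %d column(s) from %s",
                len(df), df.shape[1], path)
    return FeatureTable(df, "raw")


def read_signal(path, fs: float) -> ECGSignal:
    """Read a raw signal: one amplitude per line, or a 2-column
    (sample_index, amplitude) CSV; a header line is sniffed and skipped."""
    if fs <= 0:
        raise InvalidInputError(f"fs must be > 0, got {fs}")
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    rows = [(i + 1, [f.strip() for f in r]) for i, r in enumerate(rows)
            if any(f.strip() for f in r)]
    if not rows:
        raise InvalidInputError(f"{path}: empty signal file")
    if _looks_like_header(rows[0][1]):
        rows = rows[1:]
        if not rows:
            raise InvalidInputError(f"{path}: no samples after header")
    values = []
    for lineno, fields in rows:
        tok = fields[-1]  # amplitude is the sole or last column
        try:
            values.append(float(tok))
        except ValueError as exc:
            raise InvalidInputError(
                f"{path}: line {lineno}: non-numeric sample {tok!r}"
            ) from exc
    return ECGSignal(np.array(values), fs, "raw")


def write_signal(sig: ECGSignal, path) -> None:
    """One amplitude per line."""
    np.savetxt(path, sig.samples, fmt="%.10g")


def write_r_peaks_csv(peaks: RPeakSet, path) -> None:
    """R-peak indices as (index, time_s) CSV."""
    df = pd.DataFrame({"index": peaks.indices, "time_s": peaks.times})
    df.to_csv(path, index=False)


def write_table_csv(table: FeatureTable, path) -> None:
    table.data.to_csv(path, index=False)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
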