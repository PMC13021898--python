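"""Trial-log and parameter file formats.

Trial logs are plain CSV with a leading version comment line, one row per
trial in the canonical column order of :data:`rsk.design.TRIAL_COLUMNS`.
Boolean columns use ``True``/``False`` with empty cells for missing values;
round-tripping a log through :func:`write_trial_log` / :func:`read_trial_log`
preserves values and column order.  Observer parameters travel as JSON.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import TRIAL_COLUMNS
from .observer import ObserverParams

__all__ = [
    "LOG_FORMAT_VERSION",
    "EmptyLogError",
    "LogSchemaError",
    "read_trial_log",
    "write_trial_log",
    "read_observer_params",
    "write_observer_params",
]

LOG_FORMAT_VERSION = 1
_VERSION_PREFIX = "# rsk-trial-log v"

_BOOLEAN_COLUMNS = ("congruent", "congruency_n_minus_1", "correct")
_INT_COLUMNS = ("participant_id", "block_index", "trial_index")
_FLOAT_COLUMNS = ("motion_coherence", "color_coherence", "csi_ms", "rt_ms")
_STRING_COLUMNS = (
    "experiment",
    "task",
    "direction",
    "majority_color",
    "sequence_type",
    "correct_response",
    "response",
)


class EmptyLogError(ValueError):
    """The file contains no trials."""


class LogSchemaError(ValueError):
    """The file is not a readable trial log of a known version."""


def write_trial_log(log: pd.DataFrame, path, extra_header: str | None = None) -> None:
    """Write a trial log CSV with the format-version header.

    Columns are emitted in the canonical order (extra columns, if any, come
    after).  ``extra_header`` adds one more comment line (e.g. a config hash).
    """
    missing = [c for c in TRIAL_COLUMNS if c not in log.columns]
    if missing:
        raise LogSchemaError(f"trial log is missing columns: {missing}")
    extras = [c for c in log.columns if c not in TRIAL_COLUMNS]
    ordered = log[TRIAL_COLUMNS + extras]
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{_VERSION_PREFIX}{LOG_FORMAT_VERSION}\n")
        if extra_header:
            fh.write(f"# {extra_header}\n")
        ordered.to_csv(fh, index=False)


def _coerce_types(df: pd.DataFrame) -> pd.DataFrame:
    for col in _BOOLEAN_COLUMNS:
        if col in df.columns:
            df[col] = (
                df[col]
                .map({True: True, False: False, "True": True, "False": False})
                .astype("boolean")
            )
    for col in _INT_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype(int)
    for col in _FLOAT_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    for col in _STRING_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype("string")
    return df


def read_trial_log(path) -> pd.DataFrame:
    """Read and type-check a trial log written by :func:`write_trial_log`.

    Rejects files with an unknown format version or missing required
    columns (the error names them); an empty file or header-only file raises
    :class:`EmptyLogError`.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise EmptyLogError(f"{path} is empty")
    lines = text.splitlines()
    header = lines[0].strip()
    if not header.startswith(_VERSION_PREFIX):
        raise LogSchemaError(
            f"{path} does not start with a '{_VERSION_PREFIX}<n>' version line"
        )
    try:
        version = int(header[len(_VERSION_PREFIX) :])
    except ValueError:
        raise LogSchemaError(f"unparseable version line: {header!r}") from None
    if version != LOG_FORMAT_VERSION:
        raise LogSchemaError(
            f"unknown trial-log version {version} (supported: {LOG_FORMAT_VERSION})"
        )
    body = "\n".join(l for l in lines[1:] if not l.startswith("#"))
    if not body.strip():
        raise EmptyLogError(f"{path} contains no trials")
    df = pd.read_csv(_io.StringIO(body), keep_default_na=True)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise LogSchemaError(f"trial log is missing columns: {missing}")
    if df.empty:
        raise EmptyLogError(f"{path} contains no trials")
    return _coerce_types(df)


def write_observer_params(params: ObserverParams, path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2) + "\n")


def read_observer_params(path) -> ObserverParams:
    return ObserverParams.from_dict(json.loads(Path(path).read_text()))
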