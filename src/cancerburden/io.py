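"""CSV readers and writers for every pipeline table.

Conventions: UTF-8 CSV with a header row; age bands as ``age_lo``/``age_hi``
columns, an empty ``age_hi`` meaning the open-ended terminal band (held as
``inf`` in memory); stages written as ``0, I, II, III, IV``.  Readers
validate the full invariant set of the target type and fail with messages
naming the file and the offending data rows (0-based, i.e. file line =
row + 2 for the header).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import tables as T

__all__ = ["read_table", "write_table", "TABLE_KINDS"]

_OPEN_BAND_COLS = ("age_hi",)

_VALIDATORS: dict[str, Callable[[pd.DataFrame, str], pd.DataFrame]] = {
    "events": T.validate_event_table,
    "staged_events": T.validate_staged_event_table,
    "burden": T.validate_burden_table,
    "population": T.validate_population_table,
    "life_table": T.validate_life_table,
    "stage_mix": T.validate_stage_mix,
    "treatment_params": T.validate_treatment_params,
    "natural_history": T.validate_natural_history,
    "standard_population": T.validate_standard_population,
    "screening": T.validate_screening_series,
    "rates": T.validate_rate_table,
}

TABLE_KINDS = tuple(_VALIDATORS)

_STRING_COLS = {"county", "cancer_site", "sex", "kind", "stage", "measure"}


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate one pipeline table.

    Parameters
    ----------
    path
        CSV file location.
    kind
        One of :data:`TABLE_KINDS`.

    Raises
    ------
    tables.TableValidationError
        On missing columns, malformed values or any domain-invariant
        breach, with the file name and row indices in the message.
    """
    if kind not in _VALIDATORS:
        raise ValueError(f"unknown table kind '{kind}' (choose from {TABLE_KINDS})")
    path = Path(path)
    dtypes = {c: str for c in _STRING_COLS}
    try:
        df = pd.read_csv(path, dtype=dtypes)
    except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise T.TableValidationError(f"{path}: unreadable CSV ({exc})") from exc
    for col in _OPEN_BAND_COLS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").fillna(math.inf)
    try:
        return _VALIDATORS[kind](df, name=str(path))
    except T.TableValidationError:
        raise
    except Exception as exc:  # malformed cell types surface here
        raise T.TableValidationError(f"{path}: malformed table ({exc})") from exc


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a pipeline table as CSV (open bands as empty ``age_hi``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in _OPEN_BAND_COLS:
        if col in out.columns:
            vals = out[col].astype(float)
            out[col] = vals.replace(math.inf, np.nan)
    out.to_csv(path, index=False)
    return path
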