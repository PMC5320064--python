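"""Shared I/O: CSV schemas, TOML helpers, JSON reports.

Interchange formats are plain CSV with documented headers:

    fermentation series   t_h,X_gL,glc_gL,xyl_gL,ara_gL,la_gL,lignin_gL
    plate OD (long)       well,t_h,od
    UV spectrum           wavelength_nm,absorbance

Missing observations are empty cells and come back as NaN, never zero.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .model import SERIES_COLUMNS

PLATE_COLUMNS = ["well", "t_h", "od"]
SPECTRUM_COLUMNS = ["wavelength_nm", "absorbance"]


class SchemaError(ValueError):
    """Input file does not match any documented schema."""


def _check_numeric(df: pd.DataFrame, cols, path) -> None:
    for c in cols:
        bad = df.index[pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric value in column {c!r}, row {bad[0] + 2}"
            )


def read_series(path):
    """Read a CSV, dispatching on its header.

    Returns ``(kind, df)`` with kind one of 'fermentation', 'plate',
    'spectrum'. Validates numeric cells and time monotonicity; row numbers
    (1-based, header = row 1) appear in error messages.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols == SERIES_COLUMNS:
        _check_numeric(df, SERIES_COLUMNS, path)
        df = df.apply(pd.to_numeric, errors="coerce")
        t = df["t_h"].to_numpy()
        if np.any(pd.isna(t)):
            raise SchemaError(f"{path}: missing time value")
        d = np.diff(t)
        if np.any(d <= 0):
            i = int(np.nonzero(d <= 0)[0][0])
            kind = "duplicated" if d[i] == 0 else "non-monotone"
            raise SchemaError(f"{path}: {kind} time point at row {i + 3}")
        return "fermentation", df
    if cols == PLATE_COLUMNS:
        _check_numeric(df, ["t_h", "od"], path)
        df["t_h"] = pd.to_numeric(df["t_h"])
        df["od"] = pd.to_numeric(df["od"])
        for well, grp in df.groupby("well"):
            d = np.diff(grp["t_h"].to_numpy())
            if np.any(d <= 0):
                raise SchemaError(f"{path}: non-increasing times in well {well}")
        return "plate", df
    if cols == SPECTRUM_COLUMNS:
        _check_numeric(df, SPECTRUM_COLUMNS, path)
        df = df.apply(pd.to_numeric)
        if np.any(np.diff(df["wavelength_nm"].to_numpy()) <= 0):
            raise SchemaError(f"{path}: wavelengths must be strictly increasing")
        return "spectrum", df
    raise SchemaError(f"{path}: unknown header {cols}")


def write_series(df: pd.DataFrame, path) -> None:
    """Write a series CSV; NaN becomes an empty cell."""
    df.to_csv(path, index=False, na_rep="")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        # JSON has no Infinity/NaN; encode as strings for lossless reports
        return {"__nonfinite__": repr(obj)}
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    return obj


def write_report(result, path) -> None:
    """Serialize a result (dataclass / dict / DataFrame) as deterministic JSON."""
    with open(path, "w") as fh:
        json.dump(_jsonable(result), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# -- minimal TOML writer (flat scalar tables, one nesting level) ---------


def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float, np.floating, np.integer)):
        return repr(float(v)) if isinstance(v, (float, np.floating)) else str(int(v))
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_scalar(x) for x in v) + "]"
    raise TypeError(f"cannot TOML-serialize {type(v)}")


def _toml_table(prefix: str, d: dict, out: list) -> None:
    scalars = {k: v for k, v in d.items() if not isinstance(v, dict)}
    subtables = {k: v for k, v in d.items() if isinstance(v, dict)}
    if scalars and prefix:
        out.append(f"[{prefix}]")
    for k, v in scalars.items():
        out.append(f"{k} = {_toml_scalar(v)}")
    for k, v in subtables.items():
        if prefix or scalars:
            out.append("")
        _toml_table(f"{prefix}.{k}" if prefix else k, v, out)


def dumps_toml(d: dict) -> str:
    """Serialize nested dicts of scalars as TOML (readable by tomllib)."""
    out: list[str] = []
    _toml_table("", d, out)
    return "\n".join(out) + "\n"


def dump_toml(d: dict, path) -> None:
    Path(path).write_text(dumps_toml(d))


def load_toml(path) -> dict:
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)
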