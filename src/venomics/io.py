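"""CSV readers/writers for the pipeline's table dialects.

All tables are comma-separated, UTF-8, '.' decimal, header mandatory.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .antivenomics import SERIES_COLUMNS
from .bioassay import DOSE_COLUMNS
from .composition import PEAK_TABLE_COLUMNS

__all__ = [
    "read_peak_table",
    "write_peak_table",
    "read_composition",
    "write_composition",
    "read_antivenomics",
    "write_antivenomics",
    "read_dose_table",
    "write_dose_table",
    "read_mhd_table",
    "read_edema_table",
]

COMPOSITION_COLUMNS = ["species", "family", "mass_percent", "molar_percent"]
MHD_COLUMNS = ["dose_ug", "area_cm2"]
EDEMA_COLUMNS = ["time_h", "test_mm", "control_mm"]


def _read(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty CSV") from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def _write(df: pd.DataFrame, path: str | Path, columns: list[str]) -> None:
    extra = [c for c in df.columns if c not in columns]
    df[columns + extra].to_csv(path, index=False, encoding="utf-8")


def read_peak_table(path: str | Path) -> pd.DataFrame:
    return _read(path, PEAK_TABLE_COLUMNS)


def write_peak_table(df: pd.DataFrame, path: str | Path) -> None:
    _write(df, path, PEAK_TABLE_COLUMNS)


def read_composition(path: str | Path) -> pd.DataFrame:
    return _read(path, COMPOSITION_COLUMNS)


def write_composition(df: pd.DataFrame, path: str | Path) -> None:
    _write(df, path, COMPOSITION_COLUMNS)


def read_antivenomics(path: str | Path) -> pd.DataFrame:
    df = _read(path, SERIES_COLUMNS[:4])
    if "control_retained_pct" not in df.columns:
        df["control_retained_pct"] = 0.0
    return df


def write_antivenomics(df: pd.DataFrame, path: str | Path) -> None:
    _write(df, path, SERIES_COLUMNS)


def read_dose_table(path: str | Path) -> pd.DataFrame:
    return _read(path, DOSE_COLUMNS)


def write_dose_table(df: pd.DataFrame, path: str | Path) -> None:
    extra = [c for c in ("units",) if c in df.columns]
    _write(df, path, DOSE_COLUMNS + extra)


def read_mhd_table(path: str | Path) -> pd.DataFrame:
    return _read(path, MHD_COLUMNS)


def read_edema_table(path: str | Path) -> pd.DataFrame:
    return _read(path, EDEMA_COLUMNS)
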