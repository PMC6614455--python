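"""Reading and writing SMLM localization tables.

The on-disk dialect is a plain CSV (comma separated, header row, UTF-8,
``.`` decimal) with columns ``x, y, z`` (coordinates), ``frame``
(acquisition frame index) and optionally ``photons``.  Column aliases used
by common localization software exports (``x [nm]``, ``x_nm``, ...) are
recognised.  Coordinates are nanometres internally; micrometre input is
converted on read.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("x", "y", "z", "frame")
OPTIONAL_COLUMNS = ("photons",)

#: alias -> canonical column name (aliases compared lower-case, stripped)
COLUMN_ALIASES = {
    "x [nm]": "x", "x[nm]": "x", "x_nm": "x", "xnm": "x", "x (nm)": "x",
    "y [nm]": "y", "y[nm]": "y", "y_nm": "y", "ynm": "y", "y (nm)": "y",
    "z [nm]": "z", "z[nm]": "z", "z_nm": "z", "znm": "z", "z (nm)": "z",
    "frame index": "frame", "frame_idx": "frame", "t": "frame",
    "intensity": "photons", "intensity [photon]": "photons",
    "photon count": "photons",
}


def _canonical(name: str) -> str:
    key = name.strip().lower()
    return COLUMN_ALIASES.get(key, key)


def read_localizations(path: str | Path, units: str = "nm") -> pd.DataFrame:
    """Read a localization CSV into a blink table.

    Parameters
    ----------
    path : str or Path
        CSV file with at least columns x, y, z, frame (aliases accepted).
    units : {"nm", "um"}
        Units of the coordinate columns on disk.  "um" multiplies
        coordinates by 1000 so the returned table is always in nm.

    Returns
    -------
    pandas.DataFrame
        Columns x, y, z (float, nm), frame (int) and photons if present.
    """
    if units not in ("nm", "um"):
        raise ValueError(f"units must be 'nm' or 'um', got {units!r}")
    path = Path(path)
    try:
        table = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path} is empty; returning an empty blink table")
        return empty_blink_table()
    table.columns = [_canonical(c) for c in table.columns]
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"required column {col!r} missing from {path}")
    keep = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in table.columns]
    table = table[keep]
    if len(table) == 0:
        warnings.warn(f"{path} has a header but no rows")
        return empty_blink_table()
    for col in ("x", "y", "z"):
        values = pd.to_numeric(table[col], errors="coerce")
        if values.isna().any():
            raise ValueError(f"non-numeric value in coordinate column {col!r}")
        table[col] = values.astype(float)
    table["frame"] = pd.to_numeric(table["frame"], errors="coerce").fillna(0).astype(int)
    if (table["frame"] < 0).any():
        raise ValueError("frame indices must be non-negative")
    if not np.isfinite(table[["x", "y", "z"]].to_numpy()).all():
        raise ValueError("non-finite coordinates in localization file")
    if units == "um":
        table[["x", "y", "z"]] *= 1000.0
    return table.reset_index(drop=True)


def write_localizations(table: pd.DataFrame, path: str | Path,
                        header_comment: str | None = None) -> None:
    """Write a blink/molecule table as CSV, optionally with a # comment line."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        # %.17g round-trips IEEE doubles exactly
        table.to_csv(fh, index=False, float_format="%.17g")


def empty_blink_table() -> pd.DataFrame:
    return pd.DataFrame({"x": pd.Series(dtype=float),
                         "y": pd.Series(dtype=float),
                         "z": pd.Series(dtype=float),
                         "frame": pd.Series(dtype=int)})


def blink_coordinates(blinks) -> np.ndarray:
    """Coerce a blink table (DataFrame or array-like) to an (n, 3) float array."""
    if isinstance(blinks, pd.DataFrame):
        pts = blinks[["x", "y", "z"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(blinks, dtype=float)
        if pts.ndim == 1 and pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("expected an (n, 3) coordinate array or a blink table")
    return pts
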