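"""Delimited-text readers/writers and packaged reference tables.

All files are comma-separated UTF-8 with a mandatory header row.  Missing
Likert cells are encoded as empty cells or ``NA`` (both accepted on read).
Country codes are matched case-insensitively and stored upper-case.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import (
    DEFAULT_SCHEMA,
    INDEX_NAMES,
    LIKERT_MAX,
    LIKERT_MIN,
    ItemSchema,
    canonical_item,
)

_NA_VALUES = ["", "NA", "NaN", "nan"]
_FLOAT_FMT = "%.12g"  # lossless round-trip at 12 significant digits

FIXTURE_NAMES = ("table1", "table2", "table3")


def read_responses(path: str | Path, schema: ItemSchema = DEFAULT_SCHEMA) -> pd.DataFrame:
    """Read a respondent table: one row per questionnaire.

    Expects a ``country`` column plus one column per analysed item (canonical
    or free-text header).  Columns for dropped items are accepted and removed.
    Observed item values must be integers in [1, 5]; missing cells are kept
    as NaN.

    Returns
    -------
    pandas.DataFrame
        Columns ``country`` followed by the eight analysed items (float64,
        NaN = missing), in schema order.
    """
    df = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False)
    if df.empty:
        raise ValueError(f"empty response file: {path}")
    df.columns = [canonical_item(c) for c in df.columns]
    if "country" not in df.columns:
        raise ValueError("response file lacks a 'country' column")
    df = df.drop(columns=[c for c in schema.dropped_items if c in df.columns])
    missing_cols = [c for c in schema.items if c not in df.columns]
    extra_cols = [c for c in df.columns if c not in ("country",) + schema.items]
    if missing_cols or extra_cols:
        raise ValueError(
            f"unexpected column set: missing {missing_cols or 'none'}, "
            f"unknown {extra_cols or 'none'}"
        )
    df = df[["country"] + list(schema.items)].copy()
    df["country"] = df["country"].astype(str).str.strip().str.upper()
    if (df["country"] == "").any():
        row = int(np.argmax((df["country"] == "").to_numpy()))
        raise ValueError(f"empty country code at row {row}")
    for col in schema.items:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.notna() & (
            (vals < LIKERT_MIN) | (vals > LIKERT_MAX) | (vals != np.round(vals))
        )
        unparsed = df[col].notna() & vals.isna()
        if bad.any() or unparsed.any():
            row = int(np.argmax((bad | unparsed).to_numpy()))
            raise ValueError(
                f"invalid Likert value {df[col].iloc[row]!r} at row {row}, "
                f"column {col!r} (expected integer in "
                f"[{LIKERT_MIN}, {LIKERT_MAX}] or missing)"
            )
        df[col] = vals.astype(float)
    return df


def write_responses(df: pd.DataFrame, path: str | Path) -> None:
    """Write a respondent table; missing cells become empty fields."""
    df.to_csv(path, index=False, na_rep="", float_format="%g")


def read_index_table(path: str | Path) -> pd.DataFrame:
    """Read the country-index table (country x CO2, EPI, GBI, NIS, LPI).

    Returns a DataFrame indexed by upper-case country code.
    """
    df = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False)
    cols = {c.strip().upper(): c for c in df.columns}
    if "COUNTRY" not in cols:
        raise ValueError("index table lacks a 'country' column")
    missing = [n for n in INDEX_NAMES if n not in cols]
    if missing:
        raise ValueError(f"index table lacks columns {missing}")
    out = pd.DataFrame(
        {n: pd.to_numeric(df[cols[n]], errors="coerce") for n in INDEX_NAMES}
    )
    out.index = pd.Index(
        df[cols["COUNTRY"]].astype(str).str.strip().str.upper(), name="country"
    )
    if out.index.duplicated().any():
        dups = sorted(set(out.index[out.index.duplicated()]))
        raise ValueError(f"duplicated country codes in index table: {dups}")
    return out


def write_index_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=True, float_format=_FLOAT_FMT)


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged reference table.

    ``table1``: per-country sample sizes and main-item mean/SD summaries for
    the 37 surveyed countries (n sums to 4441).  ``table2``: the eight
    published response-type profiles (main-item and discrimination mean/SD).
    ``table3``: the published Spearman screen (r, p) of response-type
    proportions against the five country indices.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    ref = resources.files("resptypes.fixtures") / f"{name}.csv"
    with resources.as_file(ref) as p:
        df = pd.read_csv(p)
    if name == "table1":
        return df.set_index("country")
    return df.set_index("type_id")


def write_fingerprints(fingerprints: pd.DataFrame, path: str | Path) -> None:
    """Write a country x response-type proportion matrix."""
    if fingerprints.empty:
        raise ValueError("refusing to write an empty fingerprint set")
    fingerprints.to_csv(path, index=True, float_format=_FLOAT_FMT)


def read_fingerprints(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str).str.upper()
    df.index.name = "country"
    df.columns = [int(c) for c in df.columns]
    return df


def write_correlations(cells: pd.DataFrame, path: str | Path) -> None:
    """Write the association screen in long form (one row per type x index)."""
    if cells.empty:
        raise ValueError("refusing to write an empty correlation table")
    cells.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_correlations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
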