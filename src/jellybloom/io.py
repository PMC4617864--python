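"""CSV table I/O with schema validation.

All tables are headered UTF-8 CSV with ISO dates and '.' decimals — the
formats a monitoring program would actually deposit.  Readers validate the
schema and key uniqueness and raise errors naming the offending column or
key rather than propagating pandas internals.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import ENV_VARS

__all__ = [
    "read_sites",
    "read_env_daily",
    "read_counts",
    "write_table",
]


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[c]):
            out[c] = pd.DatetimeIndex(out[c]).strftime("%Y-%m-%d")
    # %.17g round-trips float64 exactly; reruns and resumed runs then see
    # bit-identical inputs
    out.to_csv(path, index=False, float_format="%.17g")
    return path


def _require_columns(df: pd.DataFrame, cols, what: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing column(s): {missing}")


def read_sites(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["site_id", "x", "y", "dist_canyon"], "site table")
    if df["site_id"].duplicated().any():
        dup = df.loc[df["site_id"].duplicated(), "site_id"].iloc[0]
        raise ValueError(f"duplicate site_id {dup!r} in site table")
    if (df["dist_canyon"] < 0).any():
        raise ValueError("dist_canyon must be >= 0")
    if not np.all(np.isfinite(df[["x", "y"]].to_numpy(float))):
        raise ValueError("site coordinates must be finite")
    return df


def read_env_daily(path, season=((5, 1), (9, 30))) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    _require_columns(df, ["site_id", "date"] + ENV_VARS, "environmental table")
    dup = df.duplicated(subset=["site_id", "date"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise ValueError(
            f"duplicate (site, date) record: site {row['site_id']} on "
            f"{row['date'].date()}"
        )
    if df[ENV_VARS].isna().any().any():
        bad = df[ENV_VARS].columns[df[ENV_VARS].isna().any()].tolist()
        raise ValueError(f"missing values in environmental column(s): {bad}")
    if season is not None:
        (m0, d0), (m1, d1) = season
        md = list(zip(pd.DatetimeIndex(df["date"]).month, pd.DatetimeIndex(df["date"]).day))
        out_of_season = [
            t for t in md if not ((m0, d0) <= t <= (m1, d1))
        ]
        if out_of_season:
            raise ValueError(
                f"dates outside the {m0:02d}-{d0:02d}..{m1:02d}-{d1:02d} "
                f"season window, e.g. month-day {out_of_season[0]}"
            )
    return df


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["site_id", "year", "month", "count"], "count table")
    dup = df.duplicated(subset=["site_id", "year", "month"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise ValueError(
            f"duplicate (site, year, month) record: "
            f"({row['site_id']}, {row['year']}, {row['month']})"
        )
    if (df["count"] < 0).any():
        raise ValueError("counts must be >= 0")
    days = df.apply(
        lambda r: pd.Timestamp(int(r["year"]), int(r["month"]), 1).days_in_month,
        axis=1,
    )
    if (df["count"] > days).any():
        raise ValueError("count exceeds the number of days in its month")
    return df
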