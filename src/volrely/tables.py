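"""Canonical long-format volume table.

Every stage of the pipeline consumes and produces a single tidy schema: one
row per (subject, method, ROI, session) volume observation. The hemisphere is
part of the ROI label (``hippocampus_L`` / ``hippocampus_R``) and the two
hemispheres are always analyzed as separate ROIs.
"""

from __future__ import annotations

import pandas as pd

#: Exact column order of the canonical volume table.
COLUMNS = ["subject_id", "method", "roi", "session", "time_months", "volume"]

#: Columns forming the unique key of a record.
KEY_COLUMNS = ["subject_id", "method", "roi", "session"]


class VolumeTableError(ValueError):
    """A volume table violates the schema contract."""


def validate_volume_table(df: pd.DataFrame, *, require_positive: bool = True) -> pd.DataFrame:
    """Validate a DataFrame against the volume-table contract.

    Checks column names/order, key uniqueness, numeric dtypes, non-negative
    times and (optionally) strictly positive volumes. Returns the validated
    frame with canonical column order; raises :class:`VolumeTableError` with
    a row-numbered message otherwise. Row numbers are 1-based data rows
    (header excluded), matching what a user sees in the CSV.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise VolumeTableError(f"missing required column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in COLUMNS]
    if extra:
        raise VolumeTableError(f"unexpected column(s): {', '.join(extra)}")
    df = df[COLUMNS]

    for col in ("time_months", "volume"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0]) + 1
            raise VolumeTableError(f"row {row}, column {col!r}: missing value")
        if bad.any():
            row = int(df.index[bad][0]) + 1
            raise VolumeTableError(
                f"row {row}, column {col!r}: malformed numeric value {df[col][bad].iloc[0]!r}"
            )
        df = df.assign(**{col: coerced.astype(float)})

    neg_t = df["time_months"] < 0
    if neg_t.any():
        row = int(df.index[neg_t][0]) + 1
        raise VolumeTableError(f"row {row}, column 'time_months': negative time")

    if require_positive:
        nonpos = df["volume"] <= 0
        if nonpos.any():
            row = int(df.index[nonpos][0]) + 1
            raise VolumeTableError(
                f"row {row}, column 'volume': non-positive volume "
                f"{df['volume'][nonpos].iloc[0]!r}"
            )

    dup = df.duplicated(subset=KEY_COLUMNS, keep=False)
    if dup.any():
        first = df.loc[dup, KEY_COLUMNS].iloc[0]
        row = int(df.index[dup][0]) + 1
        key = tuple(first)
        raise VolumeTableError(f"row {row}: duplicate key {key} (subject_id, method, roi, session)")

    return df.reset_index(drop=True)
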