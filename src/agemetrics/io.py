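"""Long-format estimates tables: schema validation and CSV round-trip.

Key columns: location_id, year, sex, age_group_start, age_group_end, label
(cause or risk; '_all' for all-cause aggregates), measure, value; optional
draw_0..draw_{N-1} columns.  Open-ended age groups are stored with an empty
age_group_end in CSV and ``inf`` in memory.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = [
    "location_id",
    "year",
    "sex",
    "age_group_start",
    "age_group_end",
    "label",
    "measure",
    "value",
]

KEY_COLUMNS = ["location_id", "year", "sex", "age_group_start", "label", "measure"]

MEASURES = frozenset(
    {
        "mx", "deaths", "prevalence", "yld_rate", "yll", "yld", "daly",
        "sdi", "haq", "exposure", "paf", "sev", "hale", "le",
    }
)


def validate_estimates(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    bad = ~df["measure"].isin(MEASURES)
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise ValueError(
            f"unknown measure {df['measure'].iloc[row]!r} at row {row}; "
            f"allowed: {sorted(MEASURES)}"
        )
    dups = df.duplicated(subset=KEY_COLUMNS)
    if dups.any():
        row = int(np.nonzero(dups.to_numpy())[0][0])
        key = df.loc[df.index[row], KEY_COLUMNS].to_dict()
        raise ValueError(f"duplicate key at row {row}: {key}")
    return df


def read_estimates(path: str) -> pd.DataFrame:
    """Read and validate a long-format estimates CSV."""
    df = pd.read_csv(path)
    if "age_group_end" in df.columns:
        df["age_group_end"] = df["age_group_end"].fillna(math.inf)
    return validate_estimates(df)


def write_estimates(df: pd.DataFrame, path: str) -> None:
    """Validate and write; open-ended ages serialise as empty cells."""
    validate_estimates(df)
    out = df.copy()
    out["age_group_end"] = out["age_group_end"].replace(math.inf, np.nan)
    out.to_csv(path, index=False)
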