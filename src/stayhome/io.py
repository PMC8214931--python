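"""Tidy-CSV input/output with column-level schema validation.

All pipeline tables are plain CSVs with ISO-8601 dates. Readers check for
required columns, parse and validate dates and numeric fields, and raise
:class:`SchemaError` naming the offending column so the CLI can exit with a
useful message.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from stayhome.covariates import PolicyCalendar


class SchemaError(ValueError):
    """A required column is missing or cannot be parsed."""


SCHEMAS = {
    "mesh": {
        "required": [
            "mesh_id", "prefecture", "age_group", "gender", "date",
            "nighttime_pop", "daytime_pop",
        ],
        "dates": ["date"],
        "numeric": ["nighttime_pop", "daytime_pop"],
    },
    "panel": {
        "required": ["prefecture", "age_group", "gender", "date", "y", "weight"],
        "dates": ["date"],
        "numeric": ["y", "weight"],
    },
    "epi": {
        "required": ["prefecture", "date", "new_infections", "deaths"],
        "dates": ["date"],
        "numeric": ["new_infections", "deaths"],
    },
    "calendar": {
        "required": ["prefecture", "policy", "start", "end"],
        "dates": ["start", "end"],
        "numeric": [],
    },
    "rain": {
        "required": ["prefecture", "date", "rain"],
        "dates": ["date"],
        "numeric": ["rain"],
    },
    "holidays": {"required": ["date"], "dates": ["date"], "numeric": []},
    "weights": {
        "required": ["prefecture", "age_group", "gender", "weight"],
        "dates": [],
        "numeric": ["weight"],
    },
    "severity": {
        "required": ["age_group", "period", "severe_rate"],
        "dates": [],
        "numeric": ["severe_rate"],
    },
    "regions": {"required": ["prefecture", "region"], "dates": [], "numeric": []},
}


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate one of the pipeline's tidy CSV tables."""
    schema = SCHEMAS[kind]
    df = pd.read_csv(path)
    missing = [c for c in schema["required"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col in schema["dates"]:
        try:
            df[col] = pd.to_datetime(df[col], format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: column '{col}' has malformed dates") from exc
    for col in schema["numeric"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().sum() > df[col].isna().sum():
            raise SchemaError(f"{path}: column '{col}' is not numeric")
        df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy CSV with ISO dates, deterministically ordered columns."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def calendar_to_frame(cal: PolicyCalendar) -> pd.DataFrame:
    """Flatten a policy calendar to (prefecture, policy, start, end) rows."""
    rows = []
    for policy in ("emergency", "school_closure"):
        for pref, ivals in getattr(cal, policy).items():
            for s, e in ivals:
                rows.append(
                    {"prefecture": pref, "policy": policy, "start": s, "end": e}
                )
    return pd.DataFrame(rows).sort_values(["policy", "prefecture"]).reset_index(drop=True)


def calendar_from_frame(
    df: pd.DataFrame,
    rain: pd.DataFrame | None = None,
    holidays: pd.DatetimeIndex | None = None,
) -> PolicyCalendar:
    """Rebuild a policy calendar from its tidy CSV form.

    The CSV stores *active* intervals (inclusive start/end), i.e. the
    day-after-declaration and day-before-reopening conventions are applied
    before writing.
    """
    cal = PolicyCalendar(
        rain=rain,
        holidays=holidays if holidays is not None else pd.DatetimeIndex([]),
    )
    prefs = df["prefecture"].unique()
    cal.emergency = {p: [] for p in prefs}
    cal.school_closure = {p: [] for p in prefs}
    for _, row in df.iterrows():
        policy = row["policy"]
        if policy not in ("emergency", "school_closure"):
            raise SchemaError(f"unknown policy '{policy}'")
        getattr(cal, policy).setdefault(row["prefecture"], []).append(
            (pd.Timestamp(row["start"]), pd.Timestamp(row["end"]))
        )
    return cal
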