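"""Regression covariates: trailing moving averages, arcsinh transforms,
policy dummies, rain dummy, and the weekday vs. weekend/holiday split.

Counts of new infections and deaths are first smoothed with a trailing 7-day
moving average (people respond to the weekly trend, not the daily print) and
then passed through the inverse hyperbolic sine, arcsinh(x) = ln(x + sqrt(x^2
+ 1)), which behaves like log for large counts but is defined at zero — many
prefecture-days report zero deaths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def arcsinh(x):
    """Inverse hyperbolic sine, ln(x + sqrt(x^2 + 1)). Odd, arcsinh(0) = 0."""
    return np.arcsinh(x)


def trailing_ma7(series: pd.Series) -> pd.Series:
    """Trailing 7-day moving average (days t-6 ... t, inclusive).

    The series must be indexed by a gap-free daily ``DatetimeIndex``. The
    first six days average over the available prefix rather than being
    dropped; in the study design the baseline weeks are all zero, so the
    choice is inert at the defaults.
    """
    idx = series.index
    if not isinstance(idx, pd.DatetimeIndex):
        raise TypeError("series must be indexed by dates")
    if len(idx) > 1:
        deltas = np.diff(idx.values).astype("timedelta64[D]").astype(int)
        if (deltas != 1).any():
            raise ValueError("calendar has gaps; daily contiguous series required")
    return series.rolling(window=7, min_periods=1).mean()


def build_epi_panel(epi: pd.DataFrame) -> pd.DataFrame:
    """Attach ma7 and arcsinh columns to a (prefecture, date) epidemic panel.

    Input columns: prefecture, date, new_infections, deaths. Output adds
    ma7_infections, ma7_deaths, m (= arcsinh ma7 infections) and
    n (= arcsinh ma7 deaths).
    """
    required = {"prefecture", "date", "new_infections", "deaths"}
    missing = required - set(epi.columns)
    if missing:
        raise ValueError(f"epidemic panel missing columns: {sorted(missing)}")
    if (epi["new_infections"] < 0).any() or (epi["deaths"] < 0).any():
        raise ValueError("counts must be nonnegative")
    out = epi.sort_values(["prefecture", "date"]).copy()
    out["date"] = pd.to_datetime(out["date"])

    def _per_pref(g: pd.DataFrame) -> pd.DataFrame:
        s = g.set_index("date")
        g = g.copy()
        g["ma7_infections"] = trailing_ma7(s["new_infections"]).to_numpy()
        g["ma7_deaths"] = trailing_ma7(s["deaths"]).to_numpy()
        return g

    out = (
        out.groupby("prefecture", group_keys=False, sort=False)[out.columns]
        .apply(_per_pref)
        .reset_index(drop=True)
    )
    out["m"] = arcsinh(out["ma7_infections"])
    out["n"] = arcsinh(out["ma7_deaths"])
    return out


@dataclass
class PolicyCalendar:
    """Active policy intervals per prefecture plus rain flags and holidays.

    ``emergency`` and ``school_closure`` map prefecture -> list of inclusive
    (start, end) Timestamps during which the dummy is 1. For a state of
    emergency the active interval runs from the day AFTER the declaration
    through the lifting day; for school closures it runs from the closure
    date through the day BEFORE reopening. Use :meth:`add_emergency` /
    :meth:`add_school_closure` to apply those conventions from event dates.
    """

    emergency: dict[str, list[tuple[pd.Timestamp, pd.Timestamp]]] = field(
        default_factory=dict
    )
    school_closure: dict[str, list[tuple[pd.Timestamp, pd.Timestamp]]] = field(
        default_factory=dict
    )
    rain: pd.DataFrame | None = None  # columns prefecture, date, rain (0/1)
    holidays: pd.DatetimeIndex = field(default_factory=lambda: pd.DatetimeIndex([]))

    def add_emergency(self, prefecture: str, declared, lifted) -> None:
        """Record a state of emergency; active day-after-declaration .. lifting day."""
        start = pd.Timestamp(declared) + pd.Timedelta(days=1)
        end = pd.Timestamp(lifted)
        self.emergency.setdefault(prefecture, []).append((start, end))

    def add_school_closure(self, prefecture: str, closed, reopened) -> None:
        """Record a school closure; active closure date .. day before reopening."""
        start = pd.Timestamp(closed)
        end = pd.Timestamp(reopened) - pd.Timedelta(days=1)
        self.school_closure.setdefault(prefecture, []).append((start, end))

    def merged(self, policy: str, max_gap: int = 0) -> dict[str, list[tuple]]:
        """Intervals with gaps of at most ``max_gap`` days merged.

        Mirrors the convention that a brief reopening between two school
        closures is not treated as a reopening.
        """
        raw = getattr(self, policy)
        out: dict[str, list[tuple]] = {}
        for pref, ivals in raw.items():
            ivals = sorted(ivals)
            merged: list[list[pd.Timestamp]] = []
            for s, e in ivals:
                if merged and (s - merged[-1][1]).days <= max_gap + 1:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[pref] = [(s, e) for s, e in merged]
        return out


def build_dummies(
    calendar: PolicyCalendar,
    index: pd.DataFrame,
    merge_gap: int = 0,
) -> pd.DataFrame:
    """0/1 policy dummies aligned to a (prefecture, date) index frame.

    ``index`` needs prefecture and date columns; every prefecture appearing
    there must be covered by the calendar (a prefecture with no intervals is
    represented by an empty list, which is valid and yields zeros — but a
    prefecture absent from both policy maps entirely is an error).
    """
    prefs = set(index["prefecture"].unique())
    known = set(calendar.emergency) | set(calendar.school_closure)
    unknown = prefs - known
    if unknown:
        raise KeyError(
            f"prefectures missing from the policy calendar: {sorted(unknown)}"
        )
    out = index[["prefecture", "date"]].copy()
    out["date"] = pd.to_datetime(out["date"])
    for policy, col in (("emergency", "emergency"), ("school_closure", "school_closure")):
        intervals = calendar.merged(policy, max_gap=merge_gap)
        flag = np.zeros(len(out), dtype=bool)
        for pref, ivals in intervals.items():
            mask_pref = (out["prefecture"] == pref).to_numpy()
            for s, e in ivals:
                flag |= mask_pref & (out["date"] >= s).to_numpy() & (
                    out["date"] <= e
                ).to_numpy()
        out[col] = flag.astype(float)
    if calendar.rain is not None:
        rain = calendar.rain.copy()
        rain["date"] = pd.to_datetime(rain["date"])
        out = out.merge(rain, on=["prefecture", "date"], how="left")
        out["rain"] = out["rain"].fillna(0.0)
    else:
        out["rain"] = 0.0
    return out


def split_weekday(
    panel: pd.DataFrame, holidays: pd.DatetimeIndex
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a panel into weekday rows and weekend/holiday rows.

    Saturdays, Sundays and listed public holidays form the weekend/holiday
    subset; the two outputs are disjoint and exhaustive.
    """
    dates = pd.to_datetime(panel["date"])
    is_weekend = dates.dt.weekday >= 5
    is_holiday = dates.isin(pd.DatetimeIndex(holidays))
    mask = (is_weekend | is_holiday).to_numpy()
    return panel.loc[~mask].copy(), panel.loc[mask].copy()


def is_weekend_holiday(dates: pd.DatetimeIndex, holidays: pd.DatetimeIndex) -> np.ndarray:
    """Boolean mask: Saturday, Sunday, or listed holiday."""
    dates = pd.DatetimeIndex(dates)
    return (dates.weekday >= 5) | dates.isin(pd.DatetimeIndex(holidays))
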