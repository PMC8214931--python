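"""Second-stage regressions: elasticity of the information effect with
respect to the age-specific severe-illness rate.

The first stage yields per-age coefficients beta on the (arcsinh of the)
number of new infections. The second stage regresses arcsinh(beta_a) on
arcsinh(theta_a), where theta_a is the severe-illness rate of age group a,
giving the elasticity eta = d ln beta / d ln theta in the large-value
regime; arcsinh is used instead of log because estimated betas can be
negative. The weekly variant interacts arcsinh(theta) with week dummies
(plus per-week constants and a women dummy) to trace eta over time, with
heteroskedasticity-robust (HC3) standard errors and 90% error bands
(estimate +/- 1.645 x robust SE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from stayhome.covariates import arcsinh

DEFAULT_EXCLUDE = ("15-19",)


@dataclass
class SeverityTable:
    """Age-specific severe-illness and fatality rates by observation period.

    Rates are reported for two surveillance periods, "Jan-Apr" and
    "Jun-Aug". For dates in between and after, the published convention is
    imputed: May uses the mean of the two periods; September onward carries
    the Jun-Aug value forward.
    """

    table: pd.DataFrame  # columns: age_group, period, severe_rate, fatality_rate

    def __post_init__(self) -> None:
        need = {"age_group", "period", "severe_rate"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"severity table missing columns: {sorted(missing)}")
        bad = self.table[
            (self.table["severe_rate"] < 0) | (self.table["severe_rate"] > 1)
        ]
        if not bad.empty:
            raise ValueError("severe rates must lie in [0, 1]")

    @classmethod
    def from_csv(cls, path) -> "SeverityTable":
        return cls(pd.read_csv(path))

    def _period_values(self, rate_col: str) -> tuple[pd.Series, pd.Series]:
        t = self.table.set_index(["age_group", "period"])[rate_col]
        jan_apr = t.xs("Jan-Apr", level="period")
        jun_aug = t.xs("Jun-Aug", level="period")
        return jan_apr, jun_aug

    def rate(self, age_group: str, month: int, rate_col: str = "severe_rate") -> float:
        """Severe-illness (or fatality) rate applicable in calendar month."""
        jan_apr, jun_aug = self._period_values(rate_col)
        if month <= 4:
            return float(jan_apr[age_group])
        if month == 5:
            return float((jan_apr[age_group] + jun_aug[age_group]) / 2.0)
        return float(jun_aug[age_group])

    def rates_for_dates(
        self, age_groups, dates, rate_col: str = "severe_rate"
    ) -> pd.DataFrame:
        dates = pd.DatetimeIndex(dates)
        rows = [
            {"age_group": a, "date": d, "theta": self.rate(a, d.month, rate_col)}
            for a in age_groups
            for d in dates
        ]
        return pd.DataFrame(rows)


@dataclass
class ElasticityFit:
    """Result of a second-stage elasticity regression."""

    eta: float
    se: float
    const: float
    const_se: float
    transform: str = "arcsinh"
    women_coef: float | None = None
    women_se: float | None = None
    per_week: pd.DataFrame | None = None
    nobs: int = 0

    def error_band(self, crit: float = 1.645) -> pd.DataFrame:
        """Per-week eta band: estimate +/- crit x robust SE."""
        if self.per_week is None:
            raise ValueError("no per-week paths in this fit")
        pw = self.per_week
        return pd.DataFrame(
            {
                "week": pw["week"],
                "eta": pw["eta"],
                "lo": pw["eta"] - crit * pw["eta_se"],
                "hi": pw["eta"] + crit * pw["eta_se"],
            }
        )


def _transform(x: np.ndarray, how: str) -> np.ndarray:
    if how == "arcsinh":
        return arcsinh(x)
    if how == "log10":
        return np.log10(x)
    raise ValueError("transform must be 'arcsinh' or 'log10'")


def estimate_eta(
    betas: pd.Series,
    theta: pd.Series,
    exclude: tuple[str, ...] = DEFAULT_EXCLUDE,
    transform: str = "arcsinh",
) -> ElasticityFit:
    """Pooled elasticity: OLS slope of arcsinh(beta_a) on arcsinh(theta_a).

    ``betas`` and ``theta`` are indexed by age group. The 15-19 group is
    excluded by default (outings of school-age youths mostly reflect
    parental and school decisions, not their own risk response).
    ``transform='log10'`` gives the per-decade alternative reading.
    """
    keep = [a for a in betas.index if a not in exclude and a in theta.index]
    if len(keep) < 3:
        raise ValueError("need at least 3 age groups after exclusions")
    th = theta.loc[keep].to_numpy(dtype=float)
    if len(np.unique(th)) < 2:
        raise ValueError("need at least 2 distinct severity values")
    y = arcsinh(betas.loc[keep].to_numpy(dtype=float))
    x = _transform(th, transform)
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit(cov_type="HC3")
    return ElasticityFit(
        eta=float(res.params[1]),
        se=float(res.bse[1]),
        const=float(res.params[0]),
        const_se=float(res.bse[0]),
        transform=transform,
        nobs=int(res.nobs),
    )


def weekly_second_stage(
    betas: pd.DataFrame,
    severity: SeverityTable,
    exclude: tuple[str, ...] = DEFAULT_EXCLUDE,
    women_label: str = "women",
) -> ElasticityFit:
    """Week-by-week elasticity with per-week constants and a women dummy.

    ``betas`` is a long table (gender, age_group, week, beta) of first-stage
    coefficients on the number of new infections, one per gender x age x
    week. Each week's severe-illness rate follows the imputation rules of
    the severity table (keyed on the week's start month). The pooled OLS
    uses week dummies, arcsinh(theta) x week interactions and a women
    dummy, with HC3 robust standard errors (per-week subsamples are small,
    and the milder corrections under-cover there). Weeks with an incomplete
    gender x age complement raise an error naming them.
    """
    need = {"gender", "age_group", "week", "beta"}
    missing = need - set(betas.columns)
    if missing:
        raise ValueError(f"beta table missing columns: {sorted(missing)}")
    df = betas[~betas["age_group"].isin(exclude)].copy()
    if df.empty:
        raise ValueError("no rows left after age exclusions")
    df["week"] = pd.to_datetime(df["week"])
    weeks = np.sort(df["week"].unique())
    n_cells = df["gender"].nunique() * df["age_group"].nunique()
    counts = df.dropna(subset=["beta"]).groupby("week").size()
    bad = [
        str(pd.Timestamp(wk).date())
        for wk in weeks
        if counts.get(pd.Timestamp(wk), 0) < n_cells
    ]
    if bad:
        raise ValueError(f"weeks with missing first-stage betas: {bad}")
    df["theta"] = [
        severity.rate(a, pd.Timestamp(wk).month)
        for a, wk in zip(df["age_group"], df["week"])
    ]
    y = arcsinh(df["beta"].to_numpy(dtype=float))
    x_theta = arcsinh(df["theta"].to_numpy(dtype=float))
    wcodes = pd.Categorical(df["week"], categories=weeks).codes
    W = len(weeks)
    n = len(df)
    const_block = np.zeros((n, W))
    const_block[np.arange(n), wcodes] = 1.0
    slope_block = const_block * x_theta[:, None]
    women = (df["gender"] == women_label).to_numpy(dtype=float)
    X = np.hstack([const_block, slope_block, women[:, None]])
    names = (
        [f"const@{pd.Timestamp(wk).date()}" for wk in weeks]
        + [f"eta@{pd.Timestamp(wk).date()}" for wk in weeks]
        + ["women"]
    )
    res = sm.OLS(y, pd.DataFrame(X, columns=names)).fit(cov_type="HC3")
    per_week = pd.DataFrame(
        {
            "week": pd.DatetimeIndex(weeks),
            "eta": [res.params[f"eta@{pd.Timestamp(wk).date()}"] for wk in weeks],
            "eta_se": [res.bse[f"eta@{pd.Timestamp(wk).date()}"] for wk in weeks],
            "const": [res.params[f"const@{pd.Timestamp(wk).date()}"] for wk in weeks],
            "const_se": [res.bse[f"const@{pd.Timestamp(wk).date()}"] for wk in weeks],
        }
    )
    return ElasticityFit(
        eta=float(per_week["eta"].mean()),
        se=float(np.sqrt((per_week["eta_se"] ** 2).mean() / len(per_week))),
        const=float(per_week["const"].mean()),
        const_se=float(np.sqrt((per_week["const_se"] ** 2).mean() / len(per_week))),
        women_coef=float(res.params["women"]),
        women_se=float(res.bse["women"]),
        per_week=per_week,
        nobs=int(res.nobs),
    )


def beta_differences(
    paths: pd.DataFrame,
    reference: str = "20-29",
    comparisons: tuple[str, ...] = ("70-79", "60-69", "50-59"),
) -> pd.DataFrame:
    """Pointwise differences of time-varying coefficients between age groups.

    ``paths`` is long-format (age_group, date, coef, se) — optionally with
    extra grouping columns such as gender or sample, which are carried
    through. SEs of the differences use the independent-fit approximation
    sqrt(se_a^2 + se_ref^2).
    """
    need = {"age_group", "date", "coef", "se"}
    missing = need - set(paths.columns)
    if missing:
        raise ValueError(f"paths table missing columns: {sorted(missing)}")
    extra = [
        c for c in paths.columns if c not in need | {"age_group"}
    ]
    key = ["date"] + extra
    ref = paths[paths["age_group"] == reference]
    if ref.empty:
        raise ValueError(f"reference age group {reference!r} absent")
    out = []
    for comp in comparisons:
        sub = paths[paths["age_group"] == comp]
        merged = sub.merge(ref, on=key, suffixes=("", "_ref"))
        merged = merged.assign(
            contrast=f"{comp}-{reference}",
            diff=merged["coef"] - merged["coef_ref"],
            diff_se=np.sqrt(merged["se"] ** 2 + merged["se_ref"] ** 2),
        )
        out.append(merged[key + ["contrast", "diff", "diff_se"]])
    return pd.concat(out, ignore_index=True)


def weekly_beta_table(
    panel: pd.DataFrame,
    spec,
    holidays: pd.DatetimeIndex,
    sample: str = "weekend_holiday",
) -> pd.DataFrame:
    """First-stage weekly coefficients on new infections per gender x age.

    Runs the time-varying fit with ISO-week interaction bins for every
    gender x age cell on the requested weekday/weekend subset and returns a
    long (gender, age_group, week, beta, se) table ready for
    :func:`weekly_second_stage`.
    """
    from stayhome.covariates import split_weekday
    from stayhome.panel import fit_time_varying

    weekday, weekend = split_weekday(panel, holidays)
    sub = {"all": panel, "weekday": weekday, "weekend_holiday": weekend}[sample]
    rows = []
    for (gender, age), cell in sub.groupby(["gender", "age_group"], sort=True):
        res = fit_time_varying(cell, spec, freq="W")
        p = res.paths
        for wk, r in p.iterrows():
            rows.append(
                {
                    "gender": gender,
                    "age_group": age,
                    "week": wk,
                    "beta": r["coef_m"],
                    "se": r["se_m"],
                }
            )
    return pd.DataFrame(rows)
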