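"""Decompose the fitted stay-at-home measure into behavioral channels.

The fitted model splits the measure into an intervention effect (policy
dummies: state of emergency, school closure), an information effect
(responses to arcsinh-transformed new infections and deaths plus the
age-specific time effects), a cell fixed effect, the rain control, and a
residual. Contributions are computed from the fit's own (unsmoothed)
coefficients, so the accounting identity

    total = intervention + information + fixed_effect + other + residual

holds exactly on every row ("other" carries controls like rain that belong
to neither headline channel).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from stayhome.covariates import is_weekend_holiday
from stayhome.panel import FitResult, _factor_codes

CHANNEL_MAP = {
    "emergency": "emergency",
    "school_closure": "school",
    "m": "infections",
    "n": "deaths",
    "rain": "rain",
}
INTERVENTION = ("school", "emergency")
INFORMATION = ("infections", "deaths", "time_effect")


def split_fe_components(
    fit: FitResult, baseline: pd.DatetimeIndex, tol: float = 1e-12, max_iter: int = 2000
) -> tuple[np.ndarray, np.ndarray]:
    """Split the absorbed effect per row into cell and time components.

    The absorbed component (per-row ``fe_fitted``) is decomposed additively
    into a level per first factor (the cell/prefecture effect mu) and a
    level per second factor (the day or day x region effect gamma). The
    split is only identified up to a constant within each connected
    component, so gamma is normalized to have zero weighted mean over the
    baseline window within every level-group of the second factor's region
    part; the constant moves into mu. With a single absorbed factor the
    whole component is attributed to mu.
    """
    df = fit.index
    g = fit.fe_fitted.astype(float)
    w = fit.weights if fit.weights is not None else np.ones(len(g))
    factors = fit.spec.fe_factors
    if len(factors) == 1:
        return g.copy(), np.zeros_like(g)
    c1, L1 = _factor_codes(df, factors[0])
    c2, L2 = _factor_codes(df, factors[1])
    sw1 = np.bincount(c1, weights=w, minlength=L1)
    sw2 = np.bincount(c2, weights=w, minlength=L2)
    mu = np.zeros(L1)
    gamma = np.zeros(L2)
    for _ in range(max_iter):
        gamma_new = np.bincount(c2, weights=w * (g - mu[c1]), minlength=L2) / sw2
        mu_new = np.bincount(c1, weights=w * (g - gamma_new[c2]), minlength=L1) / sw1
        delta = max(np.max(np.abs(gamma_new - gamma)), np.max(np.abs(mu_new - mu)))
        mu, gamma = mu_new, gamma_new
        if delta < tol:
            break
    # normalize gamma: zero weighted mean over baseline rows, per region when
    # the second factor is a (date, region) interaction
    dates = pd.to_datetime(df["date"])
    in_base = dates.isin(pd.DatetimeIndex(baseline)).to_numpy()
    if isinstance(factors[1], tuple) and "region" in factors[1] and "region" in df:
        group = df["region"].astype(str).to_numpy()
    else:
        group = np.full(len(df), "_all_")
    mu_row = mu[c1]
    gamma_row = gamma[c2]
    for gname in pd.unique(group):
        rows = group == gname
        brows = rows & in_base
        if not brows.any():
            continue
        shift = np.average(gamma_row[brows], weights=w[brows])
        gamma_row = np.where(rows, gamma_row - shift, gamma_row)
        mu_row = np.where(rows, mu_row + shift, mu_row)
    return mu_row, gamma_row


def decompose(
    fit: FitResult,
    baseline: pd.DatetimeIndex,
    target_prefecture: str | None = None,
    sample: str = "weekday",
    holidays: pd.DatetimeIndex | None = None,
    aggregate: bool = False,
) -> pd.DataFrame:
    """Per-date decomposition of the measure into named channels.

    Reports a single prefecture (``target_prefecture``) or, with
    ``aggregate=True``, the weight-averaged national series. ``sample``
    filters to weekdays (default, matching the seasonal-noise convention),
    weekends/holidays, or ``"all"``; weekday filtering needs ``holidays``.

    Output columns: date, total, intervention, information, school,
    emergency, infections, deaths, time_effect, rain, other, fixed_effect,
    residual.
    """
    if fit.contrib is None:
        raise ValueError("fit carries no channel contributions")
    required = [r for r in ("m", "n") if r in fit.spec.regressors]
    for r in required:
        if r not in fit.contrib.columns:
            raise ValueError(f"fit is missing the contribution of term '{r}'")
    df = fit.index.copy().reset_index(drop=True)
    df["date"] = pd.to_datetime(df["date"])
    mu_row, gamma_row = split_fe_components(fit, baseline)
    parts = pd.DataFrame({"date": df["date"]})
    for col in fit.contrib.columns:
        parts[CHANNEL_MAP.get(col, col)] = fit.contrib[col].to_numpy()
    for ch in ("school", "emergency", "infections", "deaths", "rain"):
        if ch not in parts:
            parts[ch] = 0.0
    parts["time_effect"] = gamma_row
    parts["fixed_effect"] = mu_row
    parts["residual"] = fit.resid
    named = set(CHANNEL_MAP.values()) | {"time_effect", "fixed_effect", "residual"}
    extra = [c for c in parts.columns if c not in named and c != "date"]
    parts["other"] = parts[extra].sum(axis=1) + parts["rain"] if extra else parts["rain"]
    parts["intervention"] = parts[list(INTERVENTION)].sum(axis=1)
    parts["information"] = parts[list(INFORMATION)].sum(axis=1)
    parts["total"] = (
        parts["intervention"]
        + parts["information"]
        + parts["other"]
        + parts["fixed_effect"]
        + parts["residual"]
    )
    mask = np.ones(len(df), dtype=bool)
    if target_prefecture is not None:
        if target_prefecture not in set(df["prefecture"]):
            raise KeyError(f"prefecture {target_prefecture!r} not in the fit")
        mask &= (df["prefecture"] == target_prefecture).to_numpy()
    if sample != "all":
        if holidays is None:
            raise ValueError("weekday/weekend filtering requires the holiday list")
        wh = is_weekend_holiday(pd.DatetimeIndex(df["date"]), holidays)
        mask &= wh if sample == "weekend_holiday" else ~wh
    out = parts.loc[mask]
    cols = [
        "total", "intervention", "information", "school", "emergency",
        "infections", "deaths", "time_effect", "rain", "other",
        "fixed_effect", "residual",
    ]
    if aggregate or target_prefecture is None:
        w = (fit.weights if fit.weights is not None else np.ones(len(df)))[mask]
        agg = out.copy()
        agg["_w"] = w
        def wavg(gr: pd.DataFrame) -> pd.Series:
            return pd.Series(
                {c: np.average(gr[c], weights=gr["_w"]) for c in cols}
            )
        res = agg.groupby("date").apply(wavg, include_groups=False).reset_index()
        return res
    if df.loc[mask, ["prefecture", "date"]].duplicated().any():
        # several demographic cells of one prefecture: weight-average them
        w = (fit.weights if fit.weights is not None else np.ones(len(df)))[mask]
        agg = out.copy()
        agg["_w"] = w
        def wavg2(gr: pd.DataFrame) -> pd.Series:
            return pd.Series(
                {c: np.average(gr[c], weights=gr["_w"]) for c in cols}
            )
        return agg.groupby("date").apply(wavg2, include_groups=False).reset_index()
    return out[["date"] + cols].sort_values("date").reset_index(drop=True)
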