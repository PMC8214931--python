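"""Two-way fixed-effects weighted panel regression with cluster-robust SEs.

The estimating equation for the stay-at-home measure y of age group a in
prefecture r on day t is

    y_art = mu_ar + alpha1 * D_rt(emergency) + alpha2 * D_rt(school closure)
            + beta1 * m_rt + beta2 * n_rt + (rain term) + gamma_at + eps_art

where m and n are arcsinh-transformed 7-day averages of new infections and
deaths. Fixed effects (prefecture; day x region) are absorbed by weighted
alternating projections (iterated within-transformation), the remaining
coefficients are estimated by weighted least squares with phone-owner
weights, and the covariance is the cluster-robust sandwich with the standard
finite-cluster correction. The "time-varying" variant interacts m (and
optionally n) with day dummies to trace out per-date coefficient paths,
which are smoothed for display with a centered 11-day moving average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

Factor = str | tuple[str, ...]

_STAR_CUTS = ((2.5758293035489004, "***"), (1.959963984540054, "**"),
              (1.6448536269514722, "*"))


def _stars(z: float) -> str:
    az = abs(z)
    for cut, s in _STAR_CUTS:
        if az > cut:
            return s
    return ""


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what, and how to absorb and cluster.

    ``fe_factors`` entries are column names or tuples of column names (a
    tuple denotes the interaction of the columns, e.g. ``("date",
    "region")`` for day x region effects). ``cluster_factor`` defaults to
    prefecture: treatment varies at the prefecture level.
    """

    dependent: str = "y"
    regressors: tuple[str, ...] = ("school_closure", "emergency", "m", "n", "rain")
    fe_factors: tuple[Factor, ...] = ("prefecture", ("date", "region"))
    cluster_factor: str = "prefecture"
    weight: str | None = "weight"
    time_varying: tuple[str, ...] = ()
    smooth_window: int = 11


@dataclass
class FitResult:
    """Point estimates, cluster-robust covariance and bookkeeping of one fit."""

    coef: pd.Series
    se: pd.Series
    vcov: pd.DataFrame
    stars: pd.Series
    nobs: int
    adj_r2: float
    n_clusters: int
    df_absorbed: int
    spec: ModelSpec
    resid: np.ndarray
    fitted: np.ndarray
    fe_fitted: np.ndarray  # absorbed-effect component per row
    index: pd.DataFrame  # id columns of the rows used, original order
    weights: np.ndarray | None = None
    contrib: pd.DataFrame | None = None  # per-row contribution of each channel
    paths: pd.DataFrame | None = None  # per-date coefficient paths (time-varying)
    unidentified_dates: dict[str, list] = field(default_factory=dict)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        """Cluster-robust confidence intervals using t(G-1) critical values."""
        crit = stats.t.ppf(0.5 + level / 2, df=max(self.n_clusters - 1, 1))
        return pd.DataFrame(
            {"lo": self.coef - crit * self.se, "hi": self.coef + crit * self.se}
        )

    def tidy(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.coef.index,
                "estimate": self.coef.to_numpy(),
                "se": self.se.to_numpy(),
                "stars": self.stars.to_numpy(),
                "nobs": self.nobs,
                "adj_r2": self.adj_r2,
            }
        )


def _factor_codes(df: pd.DataFrame, factor: Factor) -> tuple[np.ndarray, int]:
    if isinstance(factor, tuple):
        key = df[list(factor)].astype(str).agg("|".join, axis=1)
    else:
        key = df[factor]
    codes, uniq = pd.factorize(key, sort=True)
    return codes.astype(np.int64), len(uniq)


def _indicator(codes: np.ndarray, ngroups: int) -> sp.csr_matrix:
    n = len(codes)
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, ngroups)
    )


def _demean(
    M: np.ndarray,
    w: np.ndarray,
    factors: list[tuple[sp.csr_matrix, np.ndarray]],
    tol: float = 1e-12,
    max_iter: int = 5000,
) -> np.ndarray:
    """Weighted projection of the columns of M off the span of FE dummies.

    Alternating weighted group-demeaning over the factors; converges to the
    exact weighted least-squares projection. ``factors`` holds (indicator,
    group weight sums) pairs.
    """
    M = M.copy()
    scale = np.sqrt((w[:, None] * M * M).sum(axis=0))
    scale = np.maximum(scale, 1.0)
    if len(factors) == 1:
        S, sw = factors[0]
        means = (S.T @ (M * w[:, None])) / sw[:, None]
        return M - S @ means
    for _ in range(max_iter):
        delta = 0.0
        for S, sw in factors:
            means = (S.T @ (M * w[:, None])) / sw[:, None]
            adj = S @ means
            M -= adj
            delta = max(delta, float(np.max(np.abs(adj) / scale[None, :])))
        if delta < tol:
            break
    return M


def _absorbed_rank(df: pd.DataFrame, factors: Sequence[Factor]) -> int:
    """Rank of the absorbed dummy span.

    One factor: its number of levels. Two factors: L1 + L2 - C with C the
    number of connected components of the bipartite level graph (union-find).
    More factors fall back on the standard lower-bound correction.
    """
    codes = [_factor_codes(df, f) for f in factors]
    if len(codes) == 1:
        return codes[0][1]
    c1, L1 = codes[0]
    c2, L2 = codes[1]
    parent = np.arange(L1 + L2)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in zip(c1, L1 + c2):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    comps = len({find(i) for i in range(L1 + L2)})
    rank = L1 + L2 - comps
    for c, L in codes[2:]:
        rank += L - 1
    return rank


def cluster_vcov(
    X: np.ndarray,
    resid: np.ndarray,
    weights: np.ndarray,
    clusters: np.ndarray,
    df_k: int | None = None,
) -> np.ndarray:
    """Cluster-robust sandwich covariance for a WLS fit.

    ``X`` are the (FE-demeaned) regressors, ``resid`` the residuals,
    ``weights`` the WLS weights, ``clusters`` group labels. The meat sums
    score blocks s_g = sum_{i in g} w_i x_i e_i over clusters; the
    finite-sample factor is G/(G-1) * (N-1)/(N-K) with K the total model
    dimension (``df_k``; defaults to the number of columns of X).
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    codes, uniq = pd.factorize(clusters)
    G = len(uniq)
    if G < 2:
        raise ValueError("cluster-robust covariance needs at least 2 clusters")
    A = X.T @ (X * weights[:, None])
    Ainv = np.linalg.pinv(A)
    U = X * (weights * resid)[:, None]
    # cluster score sums, vectorized over clusters
    Ssum = np.zeros((G, k))
    np.add.at(Ssum, codes, U)
    meat = Ssum.T @ Ssum
    K = k if df_k is None else df_k
    if n - K <= 0:
        raise ValueError("no residual degrees of freedom")
    c = (G / (G - 1)) * ((n - 1) / (n - K))
    V = c * (Ainv @ meat @ Ainv)
    return 0.5 * (V + V.T)


def _prepare(panel: pd.DataFrame, spec: ModelSpec, columns: Sequence[str]):
    cols = [spec.dependent, *columns]
    fe_cols: list[str] = []
    for f in spec.fe_factors:
        fe_cols += list(f) if isinstance(f, tuple) else [f]
    need = set(cols) | set(fe_cols) | {spec.cluster_factor}
    if spec.weight is not None:
        need.add(spec.weight)
    missing = need - set(panel.columns)
    if missing:
        raise KeyError(f"panel missing columns: {sorted(missing)}")
    df = panel.dropna(subset=cols).reset_index(drop=True)
    w = (
        df[spec.weight].to_numpy(dtype=float)
        if spec.weight is not None
        else np.ones(len(df))
    )
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    return df, w


def _solve_wls(
    df: pd.DataFrame,
    w: np.ndarray,
    spec: ModelSpec,
    columns: list[str],
    drop_unidentified: bool,
):
    y = df[spec.dependent].to_numpy(dtype=float)
    X = df[columns].to_numpy(dtype=float)
    factors = []
    for f in spec.fe_factors:
        codes, ng = _factor_codes(df, f)
        S = _indicator(codes, ng)
        sw = np.asarray(S.T @ w).ravel()
        if np.any(sw <= 0):
            raise ValueError("a fixed-effect level has zero total weight")
        factors.append((S, sw))
    M = np.column_stack([y, X])
    Mt = _demean(M, w, factors)
    yt, Xt = Mt[:, 0], Mt[:, 1:]

    norm_orig = np.sqrt((w[:, None] * X * X).sum(axis=0))
    norm_t = np.sqrt((w[:, None] * Xt * Xt).sum(axis=0))
    dead = norm_t <= 1e-8 * np.maximum(norm_orig, 1.0)
    kept = [c for c, d in zip(columns, dead) if not d]
    dropped = [c for c, d in zip(columns, dead) if d]
    if dropped and not drop_unidentified:
        raise ValueError(
            "regressors collinear with the absorbed fixed effects: "
            + ", ".join(dropped)
        )
    Xk = Xt[:, ~dead]
    if Xk.shape[1]:
        ws = np.sqrt(w)
        sv = np.linalg.svd(ws[:, None] * Xk, compute_uv=False)
        if sv[-1] <= 1e-10 * sv[0]:
            # name the culprits via pivoted QR on the weighted design
            from scipy.linalg import qr

            _, R, piv = qr(ws[:, None] * Xk, mode="economic", pivoting=True)
            diag = np.abs(np.diag(R))
            bad = [kept[piv[i]] for i in range(len(diag)) if diag[i] <= 1e-10 * diag[0]]
            raise ValueError(f"perfectly collinear regressors: {', '.join(bad)}")
    A = Xk.T @ (Xk * w[:, None])
    b = Xk.T @ (w * yt)
    beta = np.linalg.solve(A, b) if Xk.shape[1] else np.zeros(0)
    resid = yt - Xk @ beta
    return y, X, yt, Xk, beta, resid, kept, dropped


def fit(
    panel: pd.DataFrame,
    spec: ModelSpec,
    drop_unidentified: bool = False,
    vcov: str = "cr1",
) -> FitResult:
    """Estimate the fixed-effects WLS model described by ``spec``.

    The coefficient vector is invariant to whether fixed effects are
    absorbed by within-transformation or entered as explicit dummies
    (Frisch-Waugh); the absorbed route scales to day x region designs.

    ``vcov`` selects the covariance estimator: ``"cr1"`` (default) is the
    cluster-robust sandwich with the G/(G-1)*(N-1)/(N-K) correction, the
    convention behind conventional coefficient tables; ``"cr3"`` is the
    leave-one-cluster-out jackknife, preferred for confidence intervals
    when few clusters carry the identifying variation (with a handful of
    treated clusters the CR1 sandwich is biased downward and its intervals
    under-cover).
    """
    if vcov not in ("cr1", "cr3"):
        raise ValueError("vcov must be 'cr1' or 'cr3'")
    columns = list(spec.regressors)
    df, w = _prepare(panel, spec, columns)
    y, X, yt, Xk, beta, resid, kept, dropped = _solve_wls(
        df, w, spec, columns, drop_unidentified
    )
    df_abs = _absorbed_rank(df, spec.fe_factors)
    k_tot = df_abs + len(kept)
    n = len(df)
    clusters = df[spec.cluster_factor].to_numpy()
    if vcov == "cr3":
        V = _jackknife_vcov(df, spec, kept, pd.Series(beta, index=kept),
                            drop_unidentified)
    else:
        V = cluster_vcov(Xk, resid, w, clusters, df_k=k_tot)
    se = np.sqrt(np.diag(V))
    wmean = np.average(y, weights=w)
    tss = float(np.sum(w * (y - wmean) ** 2))
    rss = float(np.sum(w * resid**2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k_tot) if n > k_tot else np.nan

    coef = pd.Series(beta, index=kept, name="estimate")
    for c in dropped:
        coef.loc[c] = np.nan
    coef = coef.reindex([c for c in columns if c in coef.index])
    se_s = pd.Series(se, index=kept).reindex(coef.index)
    stars = pd.Series(
        [
            _stars(b / s) if np.isfinite(b) and s > 0 else ""
            for b, s in zip(coef, se_s)
        ],
        index=coef.index,
    )
    contrib = pd.DataFrame(
        {c: coef[c] * X[:, columns.index(c)] if c in kept else np.zeros(len(df))
         for c in columns}
    )
    Xfull_beta = X[:, [columns.index(c) for c in kept]] @ beta
    fe_fitted = y - Xfull_beta - resid
    id_cols = [
        c
        for c in ("prefecture", "age_group", "gender", "date", "region")
        if c in df.columns
    ]
    return FitResult(
        coef=coef,
        se=se_s,
        vcov=pd.DataFrame(V, index=kept, columns=kept),
        stars=stars,
        nobs=n,
        adj_r2=adj,
        n_clusters=len(pd.unique(clusters)),
        df_absorbed=df_abs,
        spec=spec,
        resid=resid,
        fitted=y - resid,
        fe_fitted=fe_fitted,
        index=df[id_cols].copy(),
        weights=w,
        contrib=contrib,
    )


def _jackknife_vcov(
    df: pd.DataFrame,
    spec: ModelSpec,
    kept: list[str],
    beta_full: pd.Series,
    drop_unidentified: bool,
) -> np.ndarray:
    """CV3: V = (G-1)/G * sum_g (b_{-g} - b)(b_{-g} - b)'."""
    groups = pd.unique(df[spec.cluster_factor])
    G = len(groups)
    if G < 2:
        raise ValueError("jackknife covariance needs at least 2 clusters")
    devs = []
    for g in groups:
        sub = df[df[spec.cluster_factor] != g]
        r = fit(sub, spec, drop_unidentified=True, vcov="cr1")
        devs.append(r.coef.reindex(kept).to_numpy() - beta_full.to_numpy())
    D = np.array(devs)
    if np.isnan(D).any():
        # a regressor unidentified in some leave-one-out sample contributes
        # no information; treat its deviation as zero there
        D = np.nan_to_num(D)
    return (G - 1) / G * (D.T @ D)


def fit_time_varying(
    panel: pd.DataFrame,
    spec: ModelSpec,
    report_from=None,
    freq: str = "D",
) -> FitResult:
    """Fit with per-date coefficients for the variables in ``spec.time_varying``.

    Each listed variable (m and/or n) is interacted with day dummies; the
    remaining regressors keep a single coefficient. Dates whose interaction
    column is collinear with the absorbed effects (e.g. no within-region
    cross-prefecture variation, or the variable is identically zero that
    day) are flagged as unidentified and reported as NaN, never as silent
    zeros. ``result.paths`` holds the raw per-date estimates, their
    cluster-robust SEs, and centered moving-average smoothed paths
    (window ``spec.smooth_window``, shrinking at the edges);
    ``report_from`` truncates the path report to dates >= that date.
    """
    if freq not in ("D", "W"):
        raise ValueError("freq must be 'D' (daily) or 'W' (ISO-week bins)")
    tv = list(spec.time_varying) or ["m"]
    base = [r for r in spec.regressors if r not in tv]
    df, w = _prepare(panel, spec, base + tv)
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"])
    if freq == "W":
        period = df["date"] - pd.to_timedelta(df["date"].dt.weekday, unit="D")
    else:
        period = df["date"]
    dates = np.sort(period.unique())
    dcodes = pd.Categorical(period, categories=dates).codes
    onehot = np.zeros((len(df), len(dates)))
    onehot[np.arange(len(df)), dcodes] = 1.0
    columns: list[str] = list(base)
    blocks = [df[base].to_numpy(dtype=float)] if base else []
    for v in tv:
        blocks.append(onehot * df[v].to_numpy(dtype=float)[:, None])
        columns += [f"{v}@{pd.Timestamp(d).date()}" for d in dates]
    Xall = np.hstack(blocks)
    inter_names = columns[len(base):]
    inter_df = pd.DataFrame(
        Xall[:, len(base):], columns=inter_names, index=df.index
    )
    work = pd.concat([df.drop(columns=tv), inter_df], axis=1)
    y, X, yt, Xk, beta, resid, kept, dropped = _solve_wls(
        work, w, spec, columns, drop_unidentified=True
    )
    df_abs = _absorbed_rank(df, spec.fe_factors)
    k_tot = df_abs + len(kept)
    clusters = df[spec.cluster_factor].to_numpy()
    V = cluster_vcov(Xk, resid, w, clusters, df_k=k_tot)
    se = np.sqrt(np.diag(V))
    coef = pd.Series(beta, index=kept)
    se_s = pd.Series(se, index=kept)

    paths = pd.DataFrame(index=pd.DatetimeIndex(dates, name="date"))
    unidentified: dict[str, list] = {}
    for v in tv:
        est, ses = [], []
        missing = []
        for d in dates:
            name = f"{v}@{pd.Timestamp(d).date()}"
            if name in coef.index:
                est.append(coef[name])
                ses.append(se_s[name])
            else:
                est.append(np.nan)
                ses.append(np.nan)
                missing.append(pd.Timestamp(d))
        paths[f"coef_{v}"] = est
        paths[f"se_{v}"] = ses
        paths[f"smooth_{v}"] = (
            paths[f"coef_{v}"]
            .rolling(spec.smooth_window, center=True, min_periods=1)
            .mean()
        )
        unidentified[v] = missing
    if report_from is not None:
        paths = paths.loc[paths.index >= pd.Timestamp(report_from)]

    n = len(df)
    wmean = np.average(y, weights=w)
    tss = float(np.sum(w * (y - wmean) ** 2))
    rss = float(np.sum(w * resid**2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k_tot) if n > k_tot else np.nan
    stars = pd.Series(
        [_stars(b / s) if s > 0 else "" for b, s in zip(coef, se_s)],
        index=coef.index,
    )
    col_idx = {c: j for j, c in enumerate(columns)}
    Xfull_beta = Xall[:, [col_idx[c] for c in kept]] @ beta
    fe_fitted = y - Xfull_beta - resid
    # channel contributions: base regressors individually, each time-varying
    # variable collapsed over its per-period interaction columns
    contrib = pd.DataFrame(
        {c: (coef[c] * Xall[:, col_idx[c]] if c in kept else np.zeros(len(df)))
         for c in base}
    )
    for v in tv:
        total = np.zeros(len(df))
        for d in dates:
            name = f"{v}@{pd.Timestamp(d).date()}"
            if name in coef.index:
                total += coef[name] * Xall[:, col_idx[name]]
        contrib[v] = total
    id_cols = [
        c
        for c in ("prefecture", "age_group", "gender", "date", "region")
        if c in df.columns
    ]
    return FitResult(
        coef=coef,
        se=se_s,
        vcov=pd.DataFrame(V, index=kept, columns=kept),
        stars=stars,
        nobs=n,
        adj_r2=adj,
        n_clusters=len(pd.unique(clusters)),
        df_absorbed=df_abs,
        spec=spec,
        resid=resid,
        fitted=y - resid,
        fe_fitted=fe_fitted,
        index=df[id_cols].copy(),
        weights=w,
        contrib=contrib,
        paths=paths,
        unidentified_dates=unidentified,
    )


def fit_all_cells(
    panel: pd.DataFrame,
    spec: ModelSpec,
    holidays: pd.DatetimeIndex,
    samples: tuple[str, ...] = ("weekday", "weekend_holiday"),
) -> pd.DataFrame:
    """One fit per (gender, age group, weekday|weekend/holiday) subset.

    Returns a tidy long table (gender, age_group, sample, term, estimate,
    se, stars, nobs, adj_r2). An empty subset raises rather than being
    skipped silently.
    """
    from stayhome.covariates import split_weekday

    weekday, weekend = split_weekday(panel, holidays)
    subsets = {"all": panel, "weekday": weekday, "weekend_holiday": weekend}
    rows = []
    for gender in sorted(panel["gender"].unique()):
        for age in sorted(panel["age_group"].unique()):
            for sample in samples:
                sub = subsets[sample]
                cell = sub[(sub["gender"] == gender) & (sub["age_group"] == age)]
                if cell.empty:
                    raise ValueError(
                        f"empty subset: gender={gender}, age={age}, sample={sample}"
                    )
                res = fit(cell, spec)
                t = res.tidy()
                t.insert(0, "sample", sample)
                t.insert(0, "age_group", age)
                t.insert(0, "gender", gender)
                rows.append(t)
    return pd.concat(rows, ignore_index=True)
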