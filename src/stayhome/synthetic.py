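"""Synthetic study world with known true parameters.

Generates everything the pipeline consumes — staggered policy calendars,
multi-wave epidemic counts with many zero cells, rain flags, phone-owner
weights, a severity table, and mesh-level nighttime/daytime population
counts — on top of a hidden behavior layer y* built from the same model the
estimator fits (policy dummies, arcsinh-transformed 7-day-average epidemic
covariates, age-specific time effects, rain, Gaussian noise).

Mesh counts are constructed so that the measured stay-at-home index
reproduces y* exactly when noise is off: each residential mesh sends out
half of its nighttime population in normal times, and daily leavers scale as
L_t = L_base * (1 - y*/100). The behavior layer is centered per cell over
the baseline window at generation time, which is what makes the round trip
through the baseline-deviation measure an identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from stayhome.config import TrueParams, WorldConfig, load_holidays
from stayhome.covariates import PolicyCalendar, build_dummies, build_epi_panel

logger = logging.getLogger(__name__)

CELL = ["prefecture", "age_group", "gender"]

#: Baseline share of a residential mesh's nighttime population that leaves
#: home in normal times; 0.5 guarantees the residential detector's premise
#: (baseline daytime = 0.5 x nighttime < 0.8 x nighttime).
BASE_LEAVE_RATE = 0.5


@dataclass
class SyntheticWorld:
    """Bundle of generated inputs plus the hidden truth for test harnesses."""

    config: WorldConfig
    params: TrueParams
    panel: pd.DataFrame  # cell-level panel: y (= y*), weight, covariates
    epi: pd.DataFrame  # prefecture x date raw counts
    calendar: PolicyCalendar
    weights: pd.DataFrame  # cell -> phone-owner weight
    severity: pd.DataFrame  # age_group x period severe/fatality rates
    region_of: pd.Series
    mesh: pd.DataFrame | None = None
    leavers_true: pd.DataFrame | None = None
    manifest: dict | None = None


def _post_baseline_frac(config: WorldConfig) -> tuple[pd.Timestamp, int]:
    """Anchor for event timing: first post-baseline day and span length."""
    first = pd.Timestamp(config.baseline_end) + pd.Timedelta(days=1)
    span = (pd.Timestamp(config.end) - first).days
    if span < 1:
        raise ValueError("study window has no post-baseline days")
    return first, span


def _frac_date(config: WorldConfig, u: float) -> pd.Timestamp:
    first, span = _post_baseline_frac(config)
    return first + pd.Timedelta(days=int(round(u * span)))


def wave_shape(config: WorldConfig) -> np.ndarray:
    """Deterministic multi-wave intensity shape over the study calendar.

    Zero during the baseline window; the product of this shape with a
    prefecture scale gives the Poisson mean of daily new infections.
    """
    dates = config.dates
    first, span = _post_baseline_frac(config)
    u = np.asarray((dates - first).days, dtype=float) / span
    centers, amps, widths = (0.24, 0.62, 0.97), (1.0, 1.6, 1.2), (0.05, 0.08, 0.06)
    shape = np.zeros(len(dates))
    for c, a, wd in zip(centers, amps, widths):
        shape += a * np.exp(-((u - c) ** 2) / (2 * wd**2))
    shape[u < 0] = 0.0
    return shape


def epidemic_curves(
    config: WorldConfig,
    seed: int | None = None,
    wave_amplitude: float = 1.0,
    ifr: float = 0.02,
    death_lag: int = 14,
    scales: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-prefecture daily new infections and deaths.

    Infections are Poisson draws around 2-3 Gaussian-shaped waves with a
    prefecture-specific scale (heavily right-skewed across prefectures, so
    many small prefectures show long runs of zeros, mimicking the sparsity
    of prefecture-level death counts). Deaths are Poisson around ifr x
    lagged expected infections. Everything is exactly zero during the
    baseline window.
    """
    if wave_amplitude < 0 or ifr < 0:
        raise ValueError("wave parameters must be nonnegative")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    dates = config.dates
    shape = wave_shape(config)
    if scales is None:
        scales = rng.lognormal(mean=np.log(8.0), sigma=1.2, size=config.n_prefectures)
    elif len(scales) != config.n_prefectures:
        raise ValueError("scales must have one entry per prefecture")
    rows = []
    for pref, sc in zip(config.prefectures, scales):
        lam = wave_amplitude * sc * shape
        inf = rng.poisson(lam)
        lam_death = np.zeros_like(lam)
        if death_lag < len(lam):
            lam_death[death_lag:] = ifr * lam[:-death_lag] if death_lag else ifr * lam
        deaths = rng.poisson(lam_death)
        rows.append(
            pd.DataFrame(
                {
                    "prefecture": pref,
                    "date": dates,
                    "new_infections": inf,
                    "deaths": deaths,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def staggered_policies(config: WorldConfig, seed: int | None = None) -> PolicyCalendar:
    """Policy calendar with early/late emergency adoption and staggered lifting.

    A minority of prefectures declare a state of emergency early, the rest
    about a week later; lifting happens in three batches. School closures
    start near-simultaneously (one early-mover prefecture) and reopening is
    widely staggered across prefectures.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    prefs = config.prefectures
    cal = PolicyCalendar(
        emergency={p: [] for p in prefs},
        school_closure={p: [] for p in prefs},
        holidays=load_holidays(),
    )
    # event anchors sit at fixed fractions of the post-baseline span, but the
    # gaps between them are absolute day counts mirroring the historical
    # calendar: declarations 9 days apart, liftings +7/+11 days after the
    # first batch, school reopening spread over ~8 weeks
    end = pd.Timestamp(config.end)
    declare_early = _frac_date(config, 0.22)
    declare_late = min(declare_early + pd.Timedelta(days=9), end)
    lift1 = _frac_date(config, 0.35)
    lift_dates = [
        min(lift1 + pd.Timedelta(days=d), end) for d in (0, 7, 11)
    ]
    # early-adopter share and lifting-batch shares mirror the historical
    # 7/47 declarations and 39/3/5 lifting split, preserved proportionally
    # at any panel scale (each later batch keeps at least one prefecture)
    n_early = max(1, round(7 / 47 * config.n_prefectures))
    early = set(rng.choice(prefs, size=n_early, replace=False))
    n3 = max(1, round(5 / 47 * config.n_prefectures))
    n2 = max(1, round(3 / 47 * config.n_prefectures))
    if n2 + n3 >= config.n_prefectures:
        n2, n3 = 0, max(0, config.n_prefectures - 1)
    lift_assign = np.zeros(len(prefs), dtype=int)
    order = rng.permutation(len(prefs))
    lift_assign[order[:n3]] = 2
    lift_assign[order[n3:n3 + n2]] = 1
    close_all = _frac_date(config, 0.10)
    close_early_mover = close_all - pd.Timedelta(days=4)
    reopen_anchor = _frac_date(config, 0.225)
    reopen_spread = min(56, (end - reopen_anchor).days)
    start = pd.Timestamp(config.start)
    base_end = pd.Timestamp(config.baseline_end)
    for i, p in enumerate(prefs):
        declared = declare_early if p in early else declare_late
        lifted = lift_dates[lift_assign[i]]
        if declared <= base_end:
            raise ValueError("policy window overlaps the baseline window")
        cal.add_emergency(p, declared, lifted)
        closed = close_early_mover if i == 0 else close_all
        if closed <= base_end:
            raise ValueError("school-closure window overlaps the baseline window")
        reopen = reopen_anchor + pd.Timedelta(days=int(rng.integers(0, reopen_spread + 1)))
        cal.add_school_closure(p, closed, reopen)
        if closed < start or lifted > pd.Timestamp(config.end):
            raise ValueError("policy interval outside the study window")
    return cal


def _gamma_path(config: WorldConfig) -> np.ndarray:
    """Smooth common time-effect shape: 0 in baseline, humps with the waves."""
    dates = config.dates
    first, span = _post_baseline_frac(config)
    u = np.asarray((dates - first).days, dtype=float) / span
    s = 1.0 * np.exp(-((u - 0.30) ** 2) / (2 * 0.10**2)) + 0.6 * np.exp(
        -((u - 0.70) ** 2) / (2 * 0.12**2)
    )
    s[u < 0] = 0.0
    return s


def generate_world(
    config: WorldConfig,
    params: TrueParams | None = None,
    make_meshes: bool = True,
    count_noise: bool = False,
) -> SyntheticWorld:
    """Generate a full synthetic study world (deterministic under the seed).

    The behavior layer is built on exactly the covariates the pipeline
    constructs (trailing 7-day MA, then arcsinh), so with ``noise_sd = 0``
    and ``count_noise = False`` the mesh-derived stay-at-home measure
    reproduces the hidden y* to machine precision.
    """
    params = (params or TrueParams()).for_n_ages(len(config.age_groups))
    rng = np.random.default_rng(config.seed)
    region_of = config.region_of()
    dates = config.dates
    n_days = len(dates)

    epi = epidemic_curves(config, seed=int(rng.integers(2**31 - 1)))
    calendar = staggered_policies(config, seed=int(rng.integers(2**31 - 1)))
    # rain: independent Bernoulli(0.3) per prefecture-day
    rain_rows = []
    for p in config.prefectures:
        rain_rows.append(
            pd.DataFrame(
                {
                    "prefecture": p,
                    "date": dates,
                    "rain": rng.binomial(1, 0.3, size=n_days).astype(float),
                }
            )
        )
    calendar.rain = pd.concat(rain_rows, ignore_index=True)

    epi_panel = build_epi_panel(epi)
    index = epi_panel[["prefecture", "date"]]
    dummies = build_dummies(calendar, index)
    cov = epi_panel.merge(dummies, on=["prefecture", "date"])
    cov["region"] = cov["prefecture"].map(region_of)

    gamma_shape = pd.Series(_gamma_path(config), index=dates)
    base_mask = cov["date"].isin(config.baseline_dates)

    # phone-owner weights: fixed per cell, log-normal across cells
    cells = pd.MultiIndex.from_product(
        [config.prefectures, config.age_groups, config.genders], names=CELL
    ).to_frame(index=False)
    cells["weight"] = rng.lognormal(mean=11.0, sigma=0.5, size=len(cells))

    panels = []
    for ia, age in enumerate(config.age_groups):
        for gender in config.genders:
            df = cov.copy()
            df["age_group"] = age
            df["gender"] = gender
            g = gamma_shape.loc[df["date"]].to_numpy() * params.gamma_scale[ia]
            y_raw = (
                params.mu
                + params.alpha1[ia] * df["emergency"].to_numpy()
                + params.alpha2[ia] * df["school_closure"].to_numpy()
                + params.beta1[ia] * df["m"].to_numpy()
                + params.beta2[ia] * df["n"].to_numpy()
                + params.rain_coef * df["rain"].to_numpy()
                + g
            )
            if params.noise_sd > 0:
                y_raw = y_raw + rng.normal(0.0, params.noise_sd, size=len(df))
            df["y_raw"] = y_raw
            panels.append(df)
    panel = pd.concat(panels, ignore_index=True)
    base_mean = (
        panel[panel["date"].isin(config.baseline_dates)]
        .groupby(CELL)["y_raw"]
        .mean()
        .rename("base_mean")
    )
    panel = panel.merge(base_mean.reset_index(), on=CELL)
    panel["y"] = panel["y_raw"] - panel["base_mean"]
    n_clipped = int((panel["y"].abs() >= 100).sum())
    if n_clipped:
        logger.warning("behavior layer clipped on %d rows", n_clipped)
        panel["y"] = panel["y"].clip(-99.999, 99.999)
    panel = panel.drop(columns=["y_raw", "base_mean"]).merge(cells, on=CELL)

    # identification diagnostics: policy dummies should vary across
    # prefectures within a region on some dates
    chk = panel.drop_duplicates(["prefecture", "date"])
    var_within = (
        chk.groupby(["region", "date"])["emergency"].nunique() > 1
    ).any()
    if not var_within:
        logger.warning(
            "emergency dummy shows no within-region variation on any date; "
            "the intervention effect is only weakly identified"
        )

    severity = _severity_table(config, params)

    mesh = None
    leavers_true = None
    if make_meshes:
        mesh, leavers_true = _make_meshes(config, panel, rng, count_noise)

    manifest = {
        "seed": config.seed,
        "n_prefectures": config.n_prefectures,
        "n_regions": config.n_regions,
        "n_days": n_days,
        "noise_sd": params.noise_sd,
        "count_noise": bool(count_noise),
        "clipped_rows": n_clipped,
        "true_params": {
            "alpha1": params.alpha1.tolist(),
            "alpha2": params.alpha2.tolist(),
            "beta1": params.beta1.tolist(),
            "beta2": params.beta2.tolist(),
            "rain_coef": params.rain_coef,
            "theta": params.theta.tolist(),
        },
    }
    return SyntheticWorld(
        config=config,
        params=params,
        panel=panel,
        epi=epi,
        calendar=calendar,
        weights=cells,
        severity=severity,
        region_of=region_of,
        mesh=mesh,
        leavers_true=leavers_true,
        manifest=manifest,
    )


def _severity_table(config: WorldConfig, params: TrueParams) -> pd.DataFrame:
    """Age x period severe-illness and fatality rates (synthetic stand-in).

    Two observation periods are reported, mirroring surveillance snapshots;
    later periods are left to the imputation rules of the second stage.
    """
    rows = []
    for ia, age in enumerate(config.age_groups):
        for period, factor in (("Jan-Apr", 1.2), ("Jun-Aug", 0.8)):
            theta = float(np.clip(params.theta[ia] * factor, 0.0, 1.0))
            rows.append(
                {
                    "age_group": age,
                    "period": period,
                    "severe_rate": theta,
                    "fatality_rate": theta / 3.0,
                }
            )
    return pd.DataFrame(rows)


def _make_meshes(
    config: WorldConfig,
    panel: pd.DataFrame,
    rng: np.random.Generator,
    count_noise: bool,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mesh-level night/day counts consistent with the behavior layer."""
    mesh_rows = []
    leaver_rows = []
    dates = config.dates
    n_days = len(dates)
    for (pref, age, gender), grp in panel.groupby(CELL, sort=True):
        grp = grp.sort_values("date")
        y = grp["y"].to_numpy()
        if np.any(y <= -100):
            raise ValueError(
                f"infeasible mesh construction for cell ({pref},{age},{gender}): "
                "behavior layer implies negative daytime population"
            )
        night = rng.uniform(500.0, 1500.0, size=config.meshes_per_cell)
        total_leave_base = 0.0
        for k in range(config.meshes_per_cell):
            leave_base = BASE_LEAVE_RATE * night[k]
            total_leave_base += leave_base
            leave = leave_base * (1.0 - y / 100.0)
            day = night[k] - leave
            nt = np.full(n_days, night[k])
            if count_noise:
                nt = rng.poisson(nt).astype(float)
                day = rng.poisson(np.maximum(day, 0.0)).astype(float)
            mesh_rows.append(
                pd.DataFrame(
                    {
                        "mesh_id": f"{pref}-{age}-{gender}-r{k}",
                        "prefecture": pref,
                        "age_group": age,
                        "gender": gender,
                        "date": dates,
                        "nighttime_pop": nt,
                        "daytime_pop": day,
                    }
                )
            )
        # decoys: daytime exceeds nighttime every day -> never residential
        for k in range(config.n_decoy_meshes):
            nd = rng.uniform(200.0, 600.0)
            dd = nd * rng.uniform(1.2, 1.6)
            nt = np.full(n_days, nd)
            dy = np.full(n_days, dd)
            if count_noise:
                nt = rng.poisson(nt).astype(float)
                dy = rng.poisson(dy).astype(float)
            mesh_rows.append(
                pd.DataFrame(
                    {
                        "mesh_id": f"{pref}-{age}-{gender}-d{k}",
                        "prefecture": pref,
                        "age_group": age,
                        "gender": gender,
                        "date": dates,
                        "nighttime_pop": nt,
                        "daytime_pop": dy,
                    }
                )
            )
        leaver_rows.append(
            pd.DataFrame(
                {
                    "prefecture": pref,
                    "age_group": age,
                    "gender": gender,
                    "date": dates,
                    "leavers": total_leave_base * (1.0 - y / 100.0),
                }
            )
        )
    mesh = pd.concat(mesh_rows, ignore_index=True)
    leavers_true = pd.concat(leaver_rows, ignore_index=True)
    return mesh, leavers_true
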