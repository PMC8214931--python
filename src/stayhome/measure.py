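"""Stay-at-home measure from mesh-level nighttime/daytime population counts.

Three steps per prefecture x age group x gender cell:

1. *Residential detection* — over a pre-pandemic baseline window, a mesh is
   residential if its mean daytime population is strictly smaller than a
   threshold (default 0.8) times its mean nighttime population.
2. *Leaver counting* — within residential meshes, daily home-leavers are
   nighttime minus daytime population, summed over meshes.
3. *Baseline deviation* — the measure is the percentage deviation of daily
   leavers from the baseline ("normal times") mean, multiplied by -1, so
   positive values mean more staying home.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CELL = ["prefecture", "age_group", "gender"]

MESH_COLUMNS = [
    "mesh_id", "prefecture", "age_group", "gender", "date",
    "nighttime_pop", "daytime_pop",
]


def _check_mesh_frame(mesh: pd.DataFrame) -> pd.DataFrame:
    missing = set(MESH_COLUMNS) - set(mesh.columns)
    if missing:
        raise ValueError(f"mesh frame missing columns: {sorted(missing)}")
    out = mesh.copy()
    out["date"] = pd.to_datetime(out["date"])
    return out


def detect_residential(
    mesh: pd.DataFrame,
    baseline: pd.DatetimeIndex,
    threshold: float = 0.8,
    per_cell: bool = True,
) -> pd.DataFrame:
    """Residential mesh ids per demographic cell from baseline mesh-days.

    A mesh is residential iff mean(daytime) < threshold * mean(nighttime)
    over the baseline window (strict inequality; a mesh with zero nighttime
    population is never residential). With ``per_cell=False`` the decision
    pools all demographic cells of a mesh.

    Returns a frame of (mesh_id, prefecture, age_group, gender) rows for the
    residential set (cell columns collapsed when pooled).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    mesh = _check_mesh_frame(mesh)
    base = mesh[mesh["date"].isin(pd.DatetimeIndex(baseline))]
    if base.empty:
        raise ValueError("baseline window contains no mesh-days")
    keys = (["mesh_id"] + CELL) if per_cell else ["mesh_id", "prefecture"]
    means = base.groupby(keys, sort=False)[["nighttime_pop", "daytime_pop"]].mean()
    resid = means[means["daytime_pop"] < threshold * means["nighttime_pop"]]
    return resid.reset_index()[keys]


def count_leavers(
    mesh: pd.DataFrame,
    residential: pd.DataFrame,
    floor_negative: bool = False,
) -> pd.DataFrame:
    """Daily home-leavers per cell, summed over residential meshes.

    Leavers per mesh-day are nighttime minus daytime population. Negative
    per-mesh values (daytime exceeding nighttime on a particular day) are
    retained by default for aggregation-level consistency;
    ``floor_negative=True`` clips them at zero. Dates on which a cell has no
    residential mesh-day are absent from the output (logged).
    """
    mesh = _check_mesh_frame(mesh)
    keys = [c for c in residential.columns if c in mesh.columns]
    sub = mesh.merge(residential[keys], on=keys, how="inner")
    leave = (sub["nighttime_pop"] - sub["daytime_pop"]).to_numpy(dtype=float)
    if floor_negative:
        leave = np.maximum(leave, 0.0)
    sub = sub.assign(leavers=leave)
    out = (
        sub.groupby(CELL + ["date"], sort=True, as_index=False)["leavers"].sum()
    )
    n_expected = mesh.groupby(CELL + ["date"]).ngroups
    if len(out) < n_expected:
        logger.info(
            "count_leavers: %d cell-dates have no residential mesh and are absent",
            n_expected - len(out),
        )
    return out


def compute_measure(
    leavers: pd.DataFrame,
    baseline: pd.DatetimeIndex,
    weights: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Stay-at-home measure y (percentage points) per cell and date.

    y = -100 * (L_t - Lbar) / Lbar with Lbar the cell's mean daily leaver
    count over the baseline window. Positive y means more staying home than
    in normal times. ``weights`` (cell -> phone-owner count) are merged in
    when given.
    """
    lv = leavers.copy()
    lv["date"] = pd.to_datetime(lv["date"])
    base = lv[lv["date"].isin(pd.DatetimeIndex(baseline))]
    if base.empty:
        raise ValueError("no leaver observations inside the baseline window")
    lbar = base.groupby(CELL)["leavers"].mean().rename("lbar")
    bad = lbar[lbar <= 0]
    if not bad.empty:
        raise ValueError(
            "baseline mean leavers not positive for cells: "
            + ", ".join(map(str, bad.index.tolist()[:5]))
        )
    out = lv.merge(lbar.reset_index(), on=CELL, how="left")
    if out["lbar"].isna().any():
        missing = out.loc[out["lbar"].isna(), CELL].drop_duplicates()
        raise ValueError(
            f"cells without baseline observations: {missing.to_records(index=False)[:5]}"
        )
    out["y"] = -100.0 * (out["leavers"] - out["lbar"]) / out["lbar"]
    out = out.drop(columns=["lbar", "leavers"])
    if weights is not None:
        out = out.merge(weights, on=CELL, how="left")
        if out["weight"].isna().any():
            raise ValueError("weights missing for some cells")
    return out


def aggregate_all_ages(panel: pd.DataFrame) -> pd.DataFrame:
    """Prefecture-level measure: phone-owner-weighted mean of y over cells.

    Requires a ``weight`` column; the output weight is the summed cell
    weight, matching a prefecture-level weighted regression.
    """
    if "weight" not in panel.columns:
        raise ValueError("panel must carry a weight column to aggregate")
    df = panel.copy()
    df["wy"] = df["y"] * df["weight"]
    g = df.groupby(["prefecture", "date"], as_index=False)[["wy", "weight"]].sum()
    g["y"] = g["wy"] / g["weight"]
    return g.drop(columns="wy")
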