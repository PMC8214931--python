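"""Study-frame configuration and true-parameter containers.

``WorldConfig`` pins down the geography and calendar of a (synthetic or real)
study world: prefectures grouped into regions, seven age groups, two genders,
a daily calendar with a pre-pandemic baseline window used as "normal times".
``TrueParams`` holds the behavioral parameters of the data-generating model:
intervention effects (percentage points per policy dummy), information
effects (pp per unit of arcsinh-transformed infections/deaths), age-specific
time-effect paths, and the age profile of the severe-illness rate.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AGE_GROUPS = ("15-19", "20-29", "30-39", "40-49", "50-59", "60-69", "70-79")
GENDERS = ("men", "women")

#: Default study window mirroring a Jan 6 - Nov 15 daily calendar (315 days).
STUDY_START = "2020-01-06"
STUDY_END = "2020-11-15"
#: "Normal times" baseline: January 6-31, before the outbreak.
BASELINE_START = "2020-01-06"
BASELINE_END = "2020-01-31"


def load_holidays() -> pd.DatetimeIndex:
    """Japanese 2020 national holidays (including observed substitutes)."""
    ref = importlib.resources.files("stayhome.data") / "holidays_japan_2020.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, parse_dates=["date"])
    return pd.DatetimeIndex(df["date"]).sort_values()


def load_regions() -> pd.Series:
    """Prefecture -> region mapping (editable 7-region grouping of Japan)."""
    ref = importlib.resources.files("stayhome.data") / "regions_japan.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return df.set_index("prefecture")["region"]


@dataclass(frozen=True)
class WorldConfig:
    """Geography and calendar of a study world.

    Parameters
    ----------
    n_prefectures, n_regions
        Prefectures are assigned to regions in contiguous blocks
        (a surjection; ``n_regions <= n_prefectures``).
    age_groups, genders
        Demographic cell labels.
    start, end
        Inclusive daily calendar bounds (ISO dates).
    baseline_start, baseline_end
        The "normal times" sub-window; must precede all epidemic and policy
        activity.
    meshes_per_cell
        Residential meshes generated per prefecture x age x gender cell.
    n_decoy_meshes
        Non-residential meshes (daytime > nighttime) added per cell to
        exercise the residential detector.
    """

    n_prefectures: int = 47
    n_regions: int = 7
    age_groups: tuple[str, ...] = AGE_GROUPS
    genders: tuple[str, ...] = GENDERS
    start: str = STUDY_START
    end: str = STUDY_END
    baseline_start: str = BASELINE_START
    baseline_end: str = BASELINE_END
    meshes_per_cell: int = 6
    n_decoy_meshes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions > self.n_prefectures:
            raise ValueError("n_regions must not exceed n_prefectures")
        if self.n_prefectures < 1 or self.n_regions < 1:
            raise ValueError("need at least one prefecture and one region")
        if len(self.age_groups) < 1 or len(self.genders) < 1:
            raise ValueError("need at least one age group and one gender")
        if self.meshes_per_cell < 1:
            raise ValueError("meshes_per_cell must be >= 1")
        dates = self.dates
        base = self.baseline_dates
        if len(base) == 0:
            raise ValueError("baseline window is empty")
        if base[0] < dates[0] or base[-1] > dates[-1]:
            raise ValueError("baseline window must lie inside the study window")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")

    @property
    def baseline_dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.baseline_start, self.baseline_end, freq="D")

    @property
    def n_days(self) -> int:
        return len(self.dates)

    @property
    def prefectures(self) -> list[str]:
        return [f"P{i:02d}" for i in range(self.n_prefectures)]

    def region_of(self) -> pd.Series:
        """Prefecture -> region labels, contiguous blocks of prefectures."""
        idx = np.floor(
            np.arange(self.n_prefectures) * self.n_regions / self.n_prefectures
        ).astype(int)
        return pd.Series(
            [f"R{i}" for i in idx], index=self.prefectures, name="region"
        )


def _default_theta() -> np.ndarray:
    # Synthetic stand-in severe-illness profile: strongly increasing in age,
    # with the oldest group roughly two orders of magnitude above the 20s.
    return np.array([0.0008, 0.001, 0.003, 0.009, 0.025, 0.06, 0.15])


@dataclass(frozen=True)
class TrueParams:
    """True parameters of the behavior layer (units: percentage points).

    ``alpha1`` is the state-of-emergency effect, ``alpha2`` the
    school-closure effect, ``beta1``/``beta2`` the responses to
    arcsinh-transformed 7-day-average new infections/deaths, ``gamma_scale``
    scales an age-specific smooth time-effect path, ``theta`` is the
    severe-illness probability per age group.
    """

    alpha1: np.ndarray = field(
        default_factory=lambda: np.array([9.9, 10.3, 8.4, 6.5, 7.7, 7.6, 6.9])
    )
    alpha2: np.ndarray = field(
        default_factory=lambda: np.array([23.8, 4.5, 2.6, 5.3, 4.7, 3.1, 4.3])
    )
    beta1: np.ndarray = field(
        default_factory=lambda: np.array([1.27, 0.30, 0.69, 0.75, 0.63, 0.82, 1.18])
    )
    beta2: np.ndarray = field(
        default_factory=lambda: np.array([0.7, 2.5, 2.7, 2.3, 2.4, 1.8, 1.4])
    )
    gamma_scale: np.ndarray = field(
        default_factory=lambda: np.array([8.0, 7.0, 7.5, 8.0, 8.5, 9.0, 10.0])
    )
    mu: float = 0.0
    rain_coef: float = 0.7
    noise_sd: float = 2.0
    theta: np.ndarray = field(default_factory=_default_theta)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if np.any(self.theta < 0) or np.any(self.theta > 1):
            raise ValueError("theta must lie in [0, 1]")

    def for_n_ages(self, n: int) -> "TrueParams":
        """Truncate/adapt the age-indexed arrays to ``n`` age groups."""
        def cut(a: np.ndarray) -> np.ndarray:
            if len(a) >= n:
                return np.asarray(a, dtype=float)[:n]
            reps = int(np.ceil(n / len(a)))
            return np.tile(np.asarray(a, dtype=float), reps)[:n]

        return TrueParams(
            alpha1=cut(self.alpha1),
            alpha2=cut(self.alpha2),
            beta1=cut(self.beta1),
            beta2=cut(self.beta2),
            gamma_scale=cut(self.gamma_scale),
            mu=self.mu,
            rain_coef=self.rain_coef,
            noise_sd=self.noise_sd,
            theta=cut(self.theta),
        )
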