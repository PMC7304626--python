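"""Heat-unit accumulation and piecewise-linear leaf/tiller growth models.

Leaf age and tiller number are modelled as linear functions of accumulated
heat units (HU, °C·d), capped at line-specific maxima.  Tillering starts
only after a fixed HU threshold (default 800 °C·d); before it the plant is
a single culm (Till = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class WeatherSeries:
    """Daily weather for one environment.

    dates: consecutive calendar days.
    t_mean: daily mean air temperature, °C.
    par: daily photosynthetically active radiation, MJ m⁻²
        (0.5 × global solar radiation).
    day_length: photoperiod, hours (attached from latitude).
    latitude: degrees north.
    """

    dates: pd.DatetimeIndex
    t_mean: np.ndarray
    par: np.ndarray
    day_length: np.ndarray | None = None
    latitude: float = float("nan")

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.t_mean = np.asarray(self.t_mean, dtype=float)
        self.par = np.asarray(self.par, dtype=float)
        if self.day_length is not None:
            self.day_length = np.asarray(self.day_length, dtype=float)
        n = len(self.dates)
        if not (len(self.t_mean) == len(self.par) == n):
            raise ValueError("weather columns must have equal length")
        if n > 1:
            deltas = np.diff(self.dates.values).astype("timedelta64[D]")
            if not (deltas == np.timedelta64(1, "D")).all():
                gap = self.dates[np.argmax(deltas != np.timedelta64(1, "D")) + 1]
                raise ValueError(f"weather dates not consecutive near {gap.date()}")
        if np.any(self.par < 0):
            raise ValueError("PAR must be non-negative")

    def __len__(self) -> int:
        return len(self.dates)

    def index_of(self, date) -> int:
        date = pd.Timestamp(date)
        if not (self.dates[0] <= date <= self.dates[-1]):
            raise ValueError(
                f"date {date.date()} outside weather range "
                f"[{self.dates[0].date()}, {self.dates[-1].date()}]")
        return int((date - self.dates[0]).days)

    def slice_from(self, start_date) -> "WeatherSeries":
        i = self.index_of(start_date)
        return WeatherSeries(
            self.dates[i:], self.t_mean[i:], self.par[i:],
            None if self.day_length is None else self.day_length[i:],
            self.latitude)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"date": self.dates.strftime("%Y-%m-%d"),
                           "t_mean": self.t_mean, "par": self.par})
        if self.day_length is not None:
            df["day_length"] = self.day_length
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, latitude: float = float("nan")
                   ) -> "WeatherSeries":
        dates = pd.DatetimeIndex(pd.to_datetime(df["date"]))
        dl = df["day_length"].to_numpy() if "day_length" in df else None
        return cls(dates, df["t_mean"].to_numpy(), df["par"].to_numpy(),
                   dl, latitude)


@dataclass
class GrowthParams:
    """Per-line growth-curve parameters.

    delta_leaf: leaf-age increase per °C·d.
    leaf_max: final leaf age (cap).
    delta_till: tiller increase per °C·d.
    till_max: maximum tiller count (cap).
    delta_ll: increase of final leaf-blade length per leaf age, m.
    """

    delta_leaf: float
    leaf_max: float
    delta_till: float
    till_max: float
    delta_ll: float

    def __post_init__(self) -> None:
        for name in ("delta_leaf", "leaf_max", "delta_till", "till_max",
                     "delta_ll"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.leaf_max < 1 or self.till_max < 1:
            raise ValueError("leaf_max and till_max must be >= 1")

    TRAITS = ("delta_leaf", "leaf_max", "delta_till", "till_max", "delta_ll")


def heat_units(weather: WeatherSeries, start_date, mode: str = "simple"
               ) -> np.ndarray:
    """Cumulative heat units (°C·d) per day from ``start_date``.

    mode='simple': ∑ T_mean;  mode='base8': ∑ max(0, T_mean − 8).
    Element i is the sum over days 0..i of the sliced series.
    """
    if mode not in ("simple", "base8"):
        raise ValueError("mode must be 'simple' or 'base8'")
    w = weather.slice_from(start_date)
    t = w.t_mean if mode == "simple" else np.maximum(0.0, w.t_mean - 8.0)
    return np.cumsum(t)


def growth_curves(params: GrowthParams, hu: np.ndarray,
                  tiller_hu_threshold: float = 800.0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Daily leaf age and tiller number from cumulative heat units.

    Leaf_i = min(ΔLeaf·HU_i, Leaf_MAX).  Till_i = 1 while HU_i ≤ threshold,
    afterwards min(ΔTill·HU_i, Till_MAX).  The jump at the threshold is a
    deliberate feature of the piecewise model, not smoothed.
    """
    hu = np.asarray(hu, dtype=float)
    leaf = np.minimum(params.delta_leaf * hu, params.leaf_max)
    till = np.where(hu <= tiller_hu_threshold, 1.0,
                    np.minimum(params.delta_till * hu, params.till_max))
    return leaf, till


def fit_growth_params(obs: pd.DataFrame, weather: WeatherSeries,
                      start_date, leaf_len_5: float, leaf_len_11: float,
                      leaf_max: float, till_max: float,
                      mode: str = "simple") -> GrowthParams:
    """Estimate growth parameters for one line from longitudinal observations.

    ``obs`` has columns (date, trait, value) with trait in
    {'leaf_age', 'tillers'}.  ΔLeaf and ΔTill are OLS slopes of value versus
    cumulative heat units at the observation dates (intercept estimated and
    discarded); the maxima are end-of-season measurements supplied by the
    caller; ΔLL = (len₁₁ − len₅)/6 from the 5th and 11th leaf-blade lengths.
    """
    hu = heat_units(weather, start_date, mode=mode)
    w0 = weather.index_of(start_date)

    def slope(trait: str) -> float:
        sub = obs[obs["trait"] == trait].dropna(subset=["value"])
        if len(sub) < 2:
            raise ValueError(f"need >=2 observations of {trait}")
        idx = np.array([weather.index_of(d) - w0 for d in
                        pd.to_datetime(sub["date"])])
        x = hu[idx]
        if len(np.unique(x)) < 2:
            raise ValueError(f"observations of {trait} need >=2 distinct "
                             "heat-unit values")
        return float(np.polyfit(x, sub["value"].to_numpy(dtype=float), 1)[0])

    return GrowthParams(
        delta_leaf=max(0.0, slope("leaf_age")),
        leaf_max=leaf_max,
        delta_till=max(0.0, slope("tillers")),
        till_max=till_max,
        delta_ll=(leaf_len_11 - leaf_len_5) / 6.0,
    )
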