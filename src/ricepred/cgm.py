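"""Daily biomass simulation from growth traits, heading date and weather.

Biomass accumulates daily as IRUE · TRF_RUE(T) · FINT(LAI) · PAR until the
termination of seed growth (TSG), the day when post-heading degree-days
reach a fixed threshold (630 °C·d).  LAI is reconstructed from the leaf-age
and tiller curves: each successive leaf on a tiller is longer by ΔLL, its
area proportional to the squared length, so one tiller's leaf area is
β · Σ_{l≤LeafAge} (l·ΔLL)².  The simulated total BM_TSG is mapped onto
observed biomass by a single multiplicative coefficient τ absorbing
everything the model leaves out (nutrition, water, disease).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CGMConstants
from .growth import GrowthParams, WeatherSeries, growth_curves, heat_units


@dataclass
class SimulationResult:
    """Per-day trajectories and the end-of-season biomass of one line.

    Day 0 is the growth start date (sowing/emergence proxy); ``heading_day``
    and ``tsg_day`` are indices into the daily arrays.  ``bm_tsg`` is the
    cumulative biomass (g m⁻²) at TSG.
    """

    lai: np.ndarray
    fint: np.ndarray
    trf_rue: np.ndarray
    rue: np.ndarray
    increment: np.ndarray
    cumulative: np.ndarray
    heading_day: int
    tsg_day: int
    bm_tsg: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lai": self.lai, "fint": self.fint, "trf_rue": self.trf_rue,
            "rue": self.rue, "increment": self.increment,
            "cumulative": self.cumulative,
        })


def trf_rue(t):
    """Temperature modifier of radiation-use efficiency, in [0, 1].

    0 at or below 10 °C, rising linearly to 1 at 25 °C, flat to 32 °C, then
    falling linearly to 0 at 42 °C.
    """
    t = np.asarray(t, dtype=float)
    out = np.select(
        [(t > 10) & (t <= 25), (t > 25) & (t <= 32), (t > 32) & (t < 42)],
        [(t - 10.0) / 15.0, 1.0, (42.0 - t) / 10.0],
        default=0.0,
    )
    return float(out) if out.ndim == 0 else out


def canopy_lai(leaf_age, tillers, delta_ll: float,
               constants: CGMConstants = CGMConstants()):
    """Leaf area index from leaf age, tiller count and leaf-length slope.

    LAI = β_leaf · Till · Σ_{l=1}^{LeafAge} (l·ΔLL)² / S_ground, with the
    fractional last leaf pro-rated: a leaf age of n + φ contributes
    φ·((n+1)·ΔLL)² for the emerging leaf.  ΔLL in metres makes LAI
    dimensionless (m²/m²).
    """
    leaf_age = np.asarray(leaf_age, dtype=float)
    tillers = np.asarray(tillers, dtype=float)
    if np.any(leaf_age < 0) or np.any(tillers < 0):
        raise ValueError("leaf_age and tillers must be >= 0")
    n = np.floor(leaf_age)
    frac = leaf_age - n
    # Σ_{l=1}^{n} l² = n(n+1)(2n+1)/6
    sum_sq = n * (n + 1.0) * (2.0 * n + 1.0) / 6.0
    area_one_tiller = delta_ll ** 2 * (sum_sq + frac * (n + 1.0) ** 2)
    lai = constants.beta_leaf * tillers * area_one_tiller / constants.s_ground
    return float(lai) if lai.ndim == 0 else lai


def fint(lai, k: float = 0.6):
    """Fraction of PAR intercepted by the canopy: 1 − exp(−k·LAI)."""
    lai = np.asarray(lai, dtype=float)
    out = 1.0 - np.exp(-k * lai)
    return float(out) if out.ndim == 0 else out


def simulate_biomass(growth: GrowthParams, heading_day: int,
                     weather: WeatherSeries, start_date,
                     constants: CGMConstants = CGMConstants(),
                     heat_unit_mode: str = "simple") -> SimulationResult:
    """Simulate daily biomass from growth start until TSG.

    heading_day: 1-based day count after the growth start (the phenology
    module's convention).  TSG is the first day on which the degree-day
    sum over days strictly after heading reaches the configured threshold.
    Raises if the weather series ends before TSG, reporting the °C·d
    deficit.
    """
    w = weather.slice_from(start_date)
    hu = heat_units(w, w.dates[0], mode=heat_unit_mode)
    if not (1 <= heading_day <= len(w)):
        raise ValueError(f"heading_day {heading_day} outside weather range "
                         f"(1..{len(w)})")
    h_idx = heading_day - 1
    post = np.cumsum(w.t_mean[h_idx + 1:])
    threshold = constants.seed_growth_degree_days
    reached = np.nonzero(post >= threshold)[0]
    if len(reached) == 0:
        deficit = threshold - (post[-1] if len(post) else 0.0)
        raise ValueError("weather series too short: seed growth needs "
                         f"{deficit:.1f} more degree-days after heading")
    tsg = h_idx + 1 + int(reached[0])

    leaf, till = growth_curves(growth, hu, constants.tiller_hu_threshold)
    lai = canopy_lai(leaf, till, growth.delta_ll, constants)
    f_i = fint(lai, constants.k)
    trf = trf_rue(w.t_mean)
    rue = constants.irue * trf
    inc = rue * f_i * w.par
    inc[tsg + 1:] = 0.0  # seed growth terminated
    cum = np.cumsum(inc)
    return SimulationResult(lai, f_i, trf, rue, inc, cum,
                            h_idx, tsg, float(cum[tsg]))


def estimate_tau(bm_observed, bm_tsg) -> float:
    """Scaling coefficient τ: mean over lines of observed/simulated biomass.

    Lines with non-positive simulated biomass are excluded (warned); if all
    are excluded the estimate is undefined and an error is raised.
    """
    obs = np.asarray(bm_observed, dtype=float)
    sim = np.asarray(bm_tsg, dtype=float)
    if obs.shape != sim.shape:
        raise ValueError("observed and simulated vectors differ in length")
    ok = np.isfinite(obs) & np.isfinite(sim) & (sim > 0)
    if not ok.all():
        n_bad = int((~ok).sum())
        if n_bad == len(obs):
            raise ValueError("tau undefined: no line has positive simulated "
                             "biomass")
        warnings.warn(f"estimate_tau: excluded {n_bad} line(s) with "
                      "non-positive or missing biomass")
    return float(np.mean(obs[ok] / sim[ok]))
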