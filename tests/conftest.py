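"""Shared fixtures: toy marker matrices, constant weather, cached scenarios."""

import numpy as np
import pandas as pd
import pytest

from ricepred.config import Config
from ricepred.gp import MarkerMatrix
from ricepred.growth import WeatherSeries
from ricepred.phenology import elm_fit
from ricepred.synthetic import SyntheticScenario, sim_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def marker_factory():
    """Build a toy MarkerMatrix of i.i.d. ±1 RIL-style codes."""

    def make(n_lines: int, n_markers: int, seed: int = 0,
             codes: np.ndarray | None = None) -> MarkerMatrix:
        if codes is None:
            codes = np.random.default_rng(seed).choice(
                [-1.0, 1.0], size=(n_lines, n_markers))
        return MarkerMatrix(
            [f"L{i:03d}" for i in range(n_lines)],
            [f"M{j:03d}" for j in range(n_markers)],
            np.ones(n_markers, dtype=int),
            np.arange(n_markers, dtype=float),
            codes)

    return make


@pytest.fixture
def const_weather():
    """Constant-condition weather series factory (t, par, day length)."""

    def make(t: float = 30.0, par: float = 10.0, day_len: float = 9.0,
             days: int = 250, start: str = "2020-05-01") -> WeatherSeries:
        dates = pd.date_range(start, periods=days, freq="D")
        return WeatherSeries(dates, np.full(days, float(t)),
                             np.full(days, float(par)),
                             np.full(days, float(day_len)), 36.0)

    return make


@pytest.fixture(scope="session")
def default_sim():
    """Default-scale synthetic experiment (123 RILs, 2 environments)."""
    return sim_dataset(SyntheticScenario(seed=11))


@pytest.fixture(scope="session")
def zero_noise_sim():
    """Noise-free, h²=1 scenario: the exact closed-loop oracle."""
    return sim_dataset(SyntheticScenario(seed=3).zero_noise())


@pytest.fixture(scope="session")
def small_sim():
    """Down-scaled experiment for fast pipeline tests (30 lines)."""
    sc = SyntheticScenario(seed=7, n_lines=30, n_markers=72,
                           met_panel_size=24, met_trials=4)
    return sim_dataset(sc)


@pytest.fixture(scope="session")
def default_config():
    return Config(seed=11, latitude={"2014": 36.01, "2015": 36.01})


@pytest.fixture(scope="session")
def default_elm(default_sim, default_config):
    """ELM trained on the MET panel's parameter table."""
    _, truth = default_sim
    return elm_fit(truth.panel_gene_codes, truth.panel_dvr.to_numpy(),
                   default_config.elm, seed=11)
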