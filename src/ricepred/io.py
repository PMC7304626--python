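"""Tabular input loading, validation, and writing.

All inputs are plain CSV with a header row and ISO-8601 dates.  A dataset
bundle on disk consists of:

    genotypes.csv            marker, chromosome, position_cm, <line>, ...
    phenotypes_<env>.csv     line, <trait>, ...
    growth_obs_<env>.csv     line, date, trait, value
    weather_<env>.csv        date, t_mean, par[, day_length]
    met.csv (optional)       line, trial, latitude, sowing_date, heading_date
    met_weather_<trial>.csv  date, t_mean, par[, day_length]
    gene_markers.json        {gene: marker_id}
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import Config
from .gp import MarkerMatrix
from .growth import WeatherSeries
from .phenology import METData, METRecord, day_length


@dataclass
class Dataset:
    """All inputs of one experiment, validated and cross-referenced."""

    genotypes: MarkerMatrix
    phenotypes: dict[str, pd.DataFrame]
    growth_obs: dict[str, pd.DataFrame] = field(default_factory=dict)
    weather: dict[str, WeatherSeries] = field(default_factory=dict)
    met: METData | None = None
    gene_marker_map: dict[str, str] | None = None
    sowing_dates: dict[str, pd.Timestamp] = field(default_factory=dict)

    def validate(self) -> None:
        lines = set(self.genotypes.line_ids)
        for env, pheno in self.phenotypes.items():
            unknown = set(pheno.index) - lines
            if unknown:
                raise ValueError(
                    f"phenotype table {env!r} names line(s) absent from the "
                    f"genotypes: {sorted(unknown)[:5]}")
            if env not in self.weather:
                raise ValueError(f"environment {env!r} has no weather series")
        for env, obs in self.growth_obs.items():
            unknown = set(obs["line"]) - lines
            if unknown:
                raise ValueError(
                    f"growth observations {env!r} name line(s) absent from "
                    f"the genotypes: {sorted(unknown)[:5]}")
            w = self.weather.get(env)
            if w is not None and len(obs):
                dates = pd.to_datetime(obs["date"])
                if dates.min() < w.dates[0] or dates.max() > w.dates[-1]:
                    raise ValueError(
                        f"growth observation dates in {env!r} fall outside "
                        "the weather range")

    @property
    def environments(self) -> list[str]:
        return list(self.phenotypes)


def _read_weather_csv(path: Path, latitude: float,
                      twilight_angle: float) -> WeatherSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    dates = pd.DatetimeIndex(pd.to_datetime(df["date"]))
    if len(dates) > 1:
        deltas = np.diff(dates.values).astype("timedelta64[D]")
        bad = np.nonzero(deltas != np.timedelta64(1, "D"))[0]
        if len(bad):
            missing = dates[bad[0]] + pd.Timedelta(days=1)
            raise ValueError(f"weather file {path.name}: missing calendar "
                             f"day {missing.date()}")
    if "day_length" in df:
        dl = df["day_length"].to_numpy(dtype=float)
    else:
        dl = day_length(latitude, dates.dayofyear.to_numpy(), twilight_angle)
    return WeatherSeries(dates, df["t_mean"].to_numpy(dtype=float),
                         df["par"].to_numpy(dtype=float), dl, latitude)


def load_markers(path: Path) -> MarkerMatrix:
    """Genotype CSV: rows are markers, line columns follow the metadata.

    Codes: +1 / −1 homozygotes, 0 het; blank cells are missing and imputed
    to the per-marker mean of observed codes.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    meta_cols = ["marker", "chromosome", "position_cm"]
    line_cols = [c for c in df.columns if c not in meta_cols]
    codes = df[line_cols].to_numpy(dtype=float).T  # lines × markers
    col_mean = np.nanmean(codes, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(codes))
    codes[nan_r, nan_c] = col_mean[nan_c]
    return MarkerMatrix(line_cols, df["marker"].tolist(),
                        df["chromosome"].to_numpy(),
                        df["position_cm"].to_numpy(dtype=float), codes)


def load_dataset(directory: str | Path, config: Config) -> Dataset:
    """Load and validate a dataset bundle from ``directory``."""
    directory = Path(directory)
    geno_path = directory / "genotypes.csv"
    if not geno_path.exists():
        raise FileNotFoundError(geno_path)
    markers = load_markers(geno_path)

    phenotypes: dict[str, pd.DataFrame] = {}
    growth_obs: dict[str, pd.DataFrame] = {}
    weather: dict[str, WeatherSeries] = {}
    for p in sorted(directory.glob("phenotypes_*.csv")):
        env = p.stem.removeprefix("phenotypes_")
        phenotypes[env] = pd.read_csv(p, index_col="line",
                                      float_precision="round_trip")
    for p in sorted(directory.glob("growth_obs_*.csv")):
        env = p.stem.removeprefix("growth_obs_")
        growth_obs[env] = pd.read_csv(p, float_precision="round_trip")
    for p in sorted(directory.glob("weather_*.csv")):
        env = p.stem.removeprefix("weather_")
        lat = config.latitude.get(env, float("nan"))
        weather[env] = _read_weather_csv(p, lat, config.twilight_angle)

    met = None
    met_path = directory / "met.csv"
    if met_path.exists():
        met_df = pd.read_csv(met_path)
        records = []
        for _, row in met_df.iterrows():
            trial = str(row["trial"])
            wpath = directory / f"met_weather_{trial}.csv"
            w = _read_weather_csv(wpath, float(row["latitude"]),
                                  config.twilight_angle)
            hd = row.get("heading_date")
            records.append(METRecord(
                str(row["line"]), trial, float(row["latitude"]),
                pd.Timestamp(row["sowing_date"]),
                None if pd.isna(hd) else pd.Timestamp(hd), w))
        met = METData(records)

    gene_map = None
    gm_path = directory / "gene_markers.json"
    if gm_path.exists():
        gene_map = json.loads(gm_path.read_text())

    sowing: dict[str, pd.Timestamp] = {}
    sow_path = directory / "sowing_dates.json"
    if sow_path.exists():
        sowing = {k: pd.Timestamp(v)
                  for k, v in json.loads(sow_path.read_text()).items()}

    ds = Dataset(markers, phenotypes, growth_obs, weather, met, gene_map,
                 sowing)
    ds.validate()
    return ds


def write_dataset(ds: Dataset, directory: str | Path) -> None:
    """Write a dataset bundle; numeric cells round-trip exactly via repr."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    g = ds.genotypes
    meta = pd.DataFrame({"marker": g.marker_ids, "chromosome": g.chromosome,
                         "position_cm": g.position})
    geno = pd.concat([meta, pd.DataFrame(g.codes.T, columns=g.line_ids)],
                     axis=1)
    geno.to_csv(directory / "genotypes.csv", index=False,
                float_format="%.17g")
    for env, pheno in ds.phenotypes.items():
        pheno.to_csv(directory / f"phenotypes_{env}.csv",
                     float_format="%.17g")
    for env, obs in ds.growth_obs.items():
        obs.to_csv(directory / f"growth_obs_{env}.csv", index=False,
                   float_format="%.17g")
    for env, w in ds.weather.items():
        w.to_frame().to_csv(directory / f"weather_{env}.csv", index=False,
                            float_format="%.17g")
    if ds.met is not None:
        rows = []
        for r in ds.met.records:
            rows.append({"line": r.line_id, "trial": r.trial_id,
                         "latitude": r.latitude,
                         "sowing_date": r.sowing_date.date(),
                         "heading_date": "" if r.heading_date is None
                         else r.heading_date.date()})
        pd.DataFrame(rows).to_csv(directory / "met.csv", index=False)
        seen = set()
        for r in ds.met.records:
            if r.trial_id not in seen:
                seen.add(r.trial_id)
                r.weather.to_frame().to_csv(
                    directory / f"met_weather_{r.trial_id}.csv",
                    index=False, float_format="%.17g")
    if ds.gene_marker_map is not None:
        (directory / "gene_markers.json").write_text(
            json.dumps(ds.gene_marker_map, indent=2))
    if ds.sowing_dates:
        (directory / "sowing_dates.json").write_text(json.dumps(
            {k: str(v.date()) for k, v in ds.sowing_dates.items()},
            indent=2))
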