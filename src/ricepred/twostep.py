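"""Integrated two-step biomass predictors.

Step 1 predicts the intermediate growth traits (ΔLeaf, Leaf_MAX, ΔTill,
Till_MAX, ΔLL) from markers by genomic prediction, and heading date either
by the DVR phenology route (ELM genotype→parameter map, then DVS
simulation under the target environment's weather) or by a direct-GP
fallback.  Step 2 turns the intermediates into biomass, either
mechanistically (IntCGM: the daily crop growth model plus a single
training-estimated scale τ) or statistically (IntML1: multiple regression;
IntML2: random forest with mtry = 2).

Because step 1 reads only markers and training-line phenotypes, no
phenotype of a prediction-target line ever influences its own prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .cgm import estimate_tau, simulate_biomass
from .config import CGMConstants, Config
from .gp import MarkerMatrix, fit_gp, predict_gp
from .growth import GrowthParams, WeatherSeries
from .io import Dataset
from .phenology import DVRParams, ELMModel, elm_predict, simulate_dvs_heading

GROWTH_TRAITS = list(GrowthParams.TRAITS)
FEATURES = GROWTH_TRAITS + ["heading_day"]


@dataclass
class IntermediateTraitSet:
    """Per-line predicted intermediate traits.

    table: index = line ids; columns = the five growth parameters,
    ``heading_day`` (days after sowing; NaN where the DVS simulation never
    reached heading), and optionally ``harvest_index``.
    """

    table: pd.DataFrame
    heading_source: str  # 'dvr' or 'gp'

    def __post_init__(self) -> None:
        if self.heading_source not in ("dvr", "gp"):
            raise ValueError("heading_source must be 'dvr' or 'gp'")
        missing = [c for c in FEATURES if c not in self.table.columns]
        if missing:
            raise ValueError(f"intermediate table lacks columns: {missing}")


def dvr_heading_days(markers: MarkerMatrix, elm: ELMModel,
                     gene_marker_map: dict[str, str],
                     weather: WeatherSeries, sowing_date,
                     config: Config) -> pd.Series:
    """Predict heading day (days after sowing) for every line via ELM + DVS."""
    params = elm_predict(elm, markers, gene_marker_map, config.pso)
    emergence = pd.Timestamp(sowing_date) + pd.Timedelta(
        days=config.emergence_offset_days)
    out = {}
    for line, row in params.iterrows():
        res = simulate_dvs_heading(DVRParams(*row), weather, emergence,
                                   config.dvr)
        out[line] = (np.nan if not res.headed
                     else res.heading_day + config.emergence_offset_days)
    return pd.Series(out, name="heading_day")


def fit_trait_models(dataset: Dataset, train_lines: list[str],
                     train_env: str, config: Config,
                     traits: list[str] | None = None,
                     seed: int = 0) -> dict:
    """One GP model per intermediate trait, trained on ``train_lines`` only."""
    pheno = dataset.phenotypes[train_env]
    m_train = dataset.genotypes.subset(train_lines)
    return {trait: fit_gp(m_train,
                          pheno.loc[train_lines, trait].to_numpy(),
                          method=config.gp.method,
                          cv_folds=config.gp.cv_folds, seed=seed)
            for trait in (traits or GROWTH_TRAITS)}


def predict_intermediate_traits(dataset: Dataset, train_lines: list[str],
                                predict_lines: list[str], train_env: str,
                                config: Config,
                                elm: ELMModel | None = None,
                                weather_target: WeatherSeries | None = None,
                                sowing_target=None,
                                heading_source: str = "dvr",
                                include_harvest_index: bool = False,
                                seed: int = 0,
                                heading_days: pd.Series | None = None,
                                trait_models: dict | None = None
                                ) -> IntermediateTraitSet:
    """Step 1: one GP model per intermediate trait, heading via DVR or GP.

    GP models are trained only on ``train_lines`` phenotypes of
    ``train_env``; predictions are made for ``predict_lines`` from markers
    alone.  With heading_source='dvr', the heading day is simulated under
    ``weather_target`` (which may belong to a different year than the
    training phenotypes — that is the untested-environment scheme).
    """
    pheno = dataset.phenotypes[train_env]
    m_train = dataset.genotypes.subset(train_lines)
    m_pred = dataset.genotypes.subset(predict_lines)

    cols = {}
    traits = list(GROWTH_TRAITS)
    if include_harvest_index:
        traits.append("harvest_index")
    if trait_models is None:
        trait_models = fit_trait_models(dataset, train_lines, train_env,
                                        config, traits, seed)
    for trait in traits:
        cols[trait] = predict_gp(trait_models[trait], m_pred)

    if heading_days is not None:
        # precomputed (e.g. once per CV run: the DVR route is fold-free)
        cols["heading_day"] = heading_days.loc[predict_lines].to_numpy()
    elif heading_source == "dvr":
        if elm is None or dataset.gene_marker_map is None:
            raise ValueError("DVR heading requires an ELM model and a "
                             "gene→marker map")
        if weather_target is None or sowing_target is None:
            raise ValueError("DVR heading requires target weather and "
                             "sowing date")
        hd = dvr_heading_days(m_pred, elm, dataset.gene_marker_map,
                              weather_target, sowing_target, config)
        cols["heading_day"] = hd.loc[predict_lines].to_numpy()
    else:
        model = fit_gp(m_train,
                       pheno.loc[train_lines, "heading_day"].to_numpy(),
                       method=config.gp.method, cv_folds=config.gp.cv_folds,
                       seed=seed)
        cols["heading_day"] = predict_gp(model, m_pred)

    return IntermediateTraitSet(pd.DataFrame(cols, index=predict_lines),
                                heading_source)


def simulate_from_intermediates(table: pd.DataFrame,
                                weather: WeatherSeries, sowing_date,
                                constants: CGMConstants = CGMConstants()
                                ) -> pd.Series:
    """BM_TSG per line from an intermediate-trait table (NaN if no heading)."""
    out = {}
    for line, row in table.iterrows():
        hd = row["heading_day"]
        if not np.isfinite(hd):
            out[line] = np.nan
            continue
        growth = GrowthParams(*(float(row[t]) for t in GROWTH_TRAITS))
        sim = simulate_biomass(growth, int(round(hd)), weather, sowing_date,
                               constants)
        out[line] = sim.bm_tsg
    return pd.Series(out, name="bm_tsg")


def intcgm_predict(intermediates_test: IntermediateTraitSet,
                   weather_target: WeatherSeries, sowing_target,
                   constants: CGMConstants = CGMConstants(),
                   tau: float | None = None,
                   intermediates_train: IntermediateTraitSet | None = None,
                   bm_observed_train: pd.Series | None = None,
                   weather_train: WeatherSeries | None = None,
                   sowing_train=None) -> tuple[pd.Series, float]:
    """Step 2, mechanistic: simulate biomass and scale by τ.

    τ is either supplied or estimated as the mean observed/simulated ratio
    on the training lines under the *training* environment — prediction
    targets contribute nothing to it.  Lines whose DVS simulation never
    reached heading carry NaN predictions (excluded from metrics upstream).
    """
    if tau is None:
        if (intermediates_train is None or bm_observed_train is None
                or weather_train is None or sowing_train is None):
            raise ValueError("either tau or the full training source "
                             "(intermediates, biomass, weather, sowing) "
                             "is required")
        sim_train = simulate_from_intermediates(
            intermediates_train.table, weather_train, sowing_train,
            constants)
        aligned = bm_observed_train.loc[sim_train.index]
        tau = estimate_tau(aligned.to_numpy(), sim_train.to_numpy())
    sim = simulate_from_intermediates(intermediates_test.table,
                                      weather_target, sowing_target,
                                      constants)
    return tau * sim, float(tau)


def intml_predict(intermediates_train: IntermediateTraitSet,
                  bm_observed_train: pd.Series,
                  intermediates_test: IntermediateTraitSet,
                  variant: str = "ml1", seed: int = 0,
                  n_estimators: int = 500) -> pd.Series:
    """Step 2, statistical: regress biomass on the intermediate vector.

    ml1: ordinary least squares (minimum-norm solution when the design is
    rank deficient).  ml2: random forest with max_features = 2 (mtry = 2),
    other hyperparameters at library defaults apart from the tree count,
    which follows the common 500-tree convention.
    """
    if len(intermediates_train.table) < 10:
        raise ValueError("need >= 10 training lines")
    xtr = intermediates_train.table[FEATURES].to_numpy(dtype=float)
    xte = intermediates_test.table[FEATURES].to_numpy(dtype=float)
    y = bm_observed_train.loc[intermediates_train.table.index] \
        .to_numpy(dtype=float)
    ok = np.all(np.isfinite(xtr), axis=1) & np.isfinite(y)
    xtr, y = xtr[ok], y[ok]
    te_ok = np.all(np.isfinite(xte), axis=1)

    pred = np.full(len(xte), np.nan)
    if variant.lower() == "ml1":
        a = np.hstack([xtr, np.ones((len(xtr), 1))])
        coef, *_ = np.linalg.lstsq(a, y, rcond=None)
        pred[te_ok] = np.hstack([xte[te_ok],
                                 np.ones((te_ok.sum(), 1))]) @ coef
    elif variant.lower() == "ml2":
        rf = RandomForestRegressor(n_estimators=n_estimators,
                                   max_features=2, random_state=seed)
        rf.fit(xtr, y)
        if te_ok.any():
            pred[te_ok] = rf.predict(xte[te_ok])
    else:
        raise ValueError("variant must be 'ml1' or 'ml2'")
    return pd.Series(pred, index=intermediates_test.table.index,
                     name="biomass_pred")


def panicle_predict(biomass_pred: pd.Series,
                    harvest_index_pred: pd.Series) -> pd.Series:
    """Panicle weight = biomass × harvest index, elementwise."""
    return (biomass_pred * harvest_index_pred.loc[biomass_pred.index]) \
        .rename("panicle_weight")
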