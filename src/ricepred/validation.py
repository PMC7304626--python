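"""Cross-validation among genotypes under tested/untested environment schemes.

Folds partition the line set; each fold is predicted from models trained on
the remaining folds only.  In the tested scheme training phenotypes and
validation weather come from the same year; in the untested scheme the
training phenotypes come from one year and the validation lines are
predicted (and scored) under the other year's weather and observations.
Per replicate, out-of-fold predictions are pooled before computing the
three accuracy statistics: Pearson r, RMSE, and the slope of the OLS
regression of observed on predicted values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Config
from .gp import fit_gp, predict_gp
from .io import Dataset
from .phenology import ELMModel
from .twostep import (IntermediateTraitSet, dvr_heading_days,
                      fit_trait_models, intcgm_predict, intml_predict,
                      predict_intermediate_traits)

MODELS = ("gp", "intcgm", "intml1", "intml2")


def kfold_split(line_ids: list[str], k: int,
                rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition into k folds with sizes differing by at most one."""
    n = len(line_ids)
    if n < k:
        raise ValueError(f"cannot split {n} lines into {k} folds")
    perm = rng.permutation(n)
    return [np.asarray(line_ids, dtype=object)[idx]
            for idx in np.array_split(perm, k)]


def metrics(observed, predicted) -> tuple[float, float, float]:
    """(r, RMSE, slope) of observed versus predicted.

    slope regresses observed on predicted (predicted is the regressor), so
    shrunken predictions give slopes above 1 and inflated ones below 1.
    Constant predictions leave r and slope undefined (NaN); RMSE is always
    computed.  Non-finite pairs are dropped.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    ok = np.isfinite(obs) & np.isfinite(pred)
    obs, pred = obs[ok], pred[ok]
    if len(obs) < 3:
        raise ValueError("need >= 3 paired finite values")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if np.ptp(pred) == 0:
        return float("nan"), rmse, float("nan")
    r = float(np.corrcoef(obs, pred)[0, 1])
    slope = float(np.cov(obs, pred, bias=True)[0, 1] / np.var(pred))
    return r, rmse, slope


@dataclass
class CVResult:
    """Per-replicate accuracy of one model × scheme × environment cell."""

    model: str
    scheme: str
    train_env: str
    target_env: str
    replicate: int
    r: float
    rmse: float
    slope: float
    n_lines: int
    n_flagged: int  # lines excluded (e.g. DVS never reached heading)


def cross_validate(dataset: Dataset, model: str, scheme: str,
                   train_env: str, target_env: str, config: Config,
                   replicates: int | None = None,
                   seed: int | None = None,
                   elm: ELMModel | None = None,
                   heading_source: str = "dvr") -> pd.DataFrame:
    """Replicated k-fold cross-validation among genotypes.

    Returns one row per replicate with pooled-prediction metrics.  The
    heading-date step (ELM → DVS simulation) depends only on markers and
    weather, never on fold membership, so it is computed once per call.
    """
    model = model.lower()
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if scheme not in ("tested", "untested"):
        raise ValueError("scheme must be 'tested' or 'untested'")
    if scheme == "untested" and train_env == target_env:
        raise ValueError("untested scheme requires train_env != target_env")
    if scheme == "tested" and train_env != target_env:
        raise ValueError("tested scheme requires train_env == target_env")
    replicates = config.cv.replicates if replicates is None else replicates
    seed = config.seed if seed is None else seed

    lines = list(dataset.genotypes.line_ids)
    obs_target = dataset.phenotypes[target_env]["biomass"]
    k = config.cv.k
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31 - 1))
                   for s in ss.spawn(replicates)]

    hd_train = hd_target = None
    if model != "gp" and heading_source == "dvr":
        if elm is None or dataset.gene_marker_map is None:
            raise ValueError("DVR heading requires an ELM model and a "
                             "gene→marker map")
        hd_target = dvr_heading_days(
            dataset.genotypes, elm, dataset.gene_marker_map,
            dataset.weather[target_env], dataset.sowing_dates[target_env],
            config)
        hd_train = hd_target if scheme == "tested" else dvr_heading_days(
            dataset.genotypes, elm, dataset.gene_marker_map,
            dataset.weather[train_env], dataset.sowing_dates[train_env],
            config)

    rows = []
    for rep, rep_seed in enumerate(child_seeds):
        rng = np.random.default_rng(rep_seed)
        folds = kfold_split(lines, k, rng)
        pred = pd.Series(np.nan, index=lines, dtype=float)
        for fold in folds:
            test = list(fold)
            train = [l for l in lines if l not in set(test)]
            pred.loc[test] = _predict_fold(
                dataset, model, train, test, train_env, target_env,
                config, elm, heading_source, rep_seed, hd_train, hd_target)
        obs = obs_target.loc[lines]
        ok = np.isfinite(pred.to_numpy())
        r, rmse, slope = metrics(obs.to_numpy()[ok], pred.to_numpy()[ok])
        rows.append(CVResult(model, scheme, train_env, target_env, rep,
                             r, rmse, slope, int(ok.sum()),
                             int((~ok).sum())))
    return pd.DataFrame([vars(c) for c in rows])


def _predict_fold(dataset: Dataset, model: str, train: list[str],
                  test: list[str], train_env: str, target_env: str,
                  config: Config, elm: ELMModel | None,
                  heading_source: str, seed: int,
                  hd_train: pd.Series | None = None,
                  hd_target: pd.Series | None = None) -> np.ndarray:
    pheno_train = dataset.phenotypes[train_env]
    if model == "gp":
        m = fit_gp(dataset.genotypes.subset(train),
                   pheno_train.loc[train, "biomass"].to_numpy(),
                   method=config.gp.method, cv_folds=config.gp.cv_folds,
                   seed=seed)
        return predict_gp(m, dataset.genotypes.subset(test))

    w_train = dataset.weather[train_env]
    w_target = dataset.weather[target_env]
    sow_train = dataset.sowing_dates[train_env]
    sow_target = dataset.sowing_dates[target_env]
    models = fit_trait_models(dataset, train, train_env, config, seed=seed)
    inter_test = predict_intermediate_traits(
        dataset, train, test, train_env, config, elm, w_target, sow_target,
        heading_source, seed=seed, heading_days=hd_target,
        trait_models=models)
    inter_train = predict_intermediate_traits(
        dataset, train, train, train_env, config, elm, w_train, sow_train,
        heading_source, seed=seed, heading_days=hd_train,
        trait_models=models)
    if model == "intcgm":
        pred, _ = intcgm_predict(
            inter_test, w_target, sow_target, config.cgm,
            intermediates_train=inter_train,
            bm_observed_train=pheno_train.loc[train, "biomass"],
            weather_train=w_train, sowing_train=sow_train)
        return pred.loc[test].to_numpy()
    variant = "ml1" if model == "intml1" else "ml2"
    pred = intml_predict(inter_train, pheno_train.loc[train, "biomass"],
                         inter_test, variant=variant, seed=seed)
    return pred.loc[test].to_numpy()


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sd of each metric per model × scheme × environment cell."""
    keys = ["model", "scheme", "train_env", "target_env"]
    agg = results.groupby(keys).agg(
        r_mean=("r", "mean"), r_sd=("r", "std"),
        rmse_mean=("rmse", "mean"), rmse_sd=("rmse", "std"),
        slope_mean=("slope", "mean"), slope_sd=("slope", "std"),
        n_replicates=("replicate", "count"))
    return agg.reset_index()
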