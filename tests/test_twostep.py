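"""Integrated predictors: step-1 trait prediction, IntCGM, IntML, panicle."""

import numpy as np
import pandas as pd
import pytest

from ricepred.config import Config
from ricepred.twostep import (FEATURES, GROWTH_TRAITS, IntermediateTraitSet,
                              dvr_heading_days, intcgm_predict, intml_predict,
                              panicle_predict, predict_intermediate_traits)
from ricepred.validation import kfold_split, metrics


def _table(rng, n=40, heading=100.0):
    idx = [f"L{i:03d}" for i in range(n)]
    return pd.DataFrame({
        "delta_leaf": rng.uniform(0.008, 0.014, n),
        "leaf_max": rng.uniform(12, 16, n),
        "delta_till": rng.uniform(0.012, 0.02, n),
        "till_max": rng.uniform(15, 25, n),
        "delta_ll": rng.uniform(0.04, 0.06, n),
        "heading_day": rng.uniform(heading - 10, heading + 10, n),
    }, index=idx)


class TestIntML:
    def test_ml1_recovers_exact_linear_map(self, rng):
        tr = IntermediateTraitSet(_table(rng, 40), "gp")
        te = IntermediateTraitSet(_table(rng, 15), "gp")
        w = rng.normal(size=len(FEATURES))
        y_tr = pd.Series(tr.table[FEATURES].to_numpy() @ w + 5.0,
                         index=tr.table.index)
        y_te = te.table[FEATURES].to_numpy() @ w + 5.0
        pred = intml_predict(tr, y_tr, te, "ml1")
        assert np.abs(pred.to_numpy() - y_te).max() < 1e-6

    def test_ml1_invariant_to_column_order(self, rng):
        tr = IntermediateTraitSet(_table(rng, 30), "gp")
        te = IntermediateTraitSet(_table(rng, 10), "gp")
        y = pd.Series(rng.normal(1000, 100, 30), index=tr.table.index)
        p1 = intml_predict(tr, y, te, "ml1")
        tr2 = IntermediateTraitSet(tr.table[list(reversed(FEATURES))], "gp")
        te2 = IntermediateTraitSet(te.table[list(reversed(FEATURES))], "gp")
        p2 = intml_predict(tr2, y, te2, "ml1")
        assert np.allclose(p1.to_numpy(), p2.to_numpy())

    def test_ml2_beats_ml1_on_interaction_signal(self):
        # biomass with a heading × ΔTill interaction: the forest should win
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            tr = IntermediateTraitSet(_table(rng, 80), "gp")
            te = IntermediateTraitSet(_table(rng, 40), "gp")

            def gen(t):
                x = t.table
                inter = ((x["heading_day"] - 100) / 10
                         * (x["delta_till"] - 0.016) / 0.004)
                return pd.Series(1000 + 120 * inter
                                 + rng.normal(0, 20, len(x)),
                                 index=x.index)

            y_tr, y_te = gen(tr), gen(te)
            p1 = intml_predict(tr, y_tr, te, "ml1")
            p2 = intml_predict(tr, y_tr, te, "ml2", seed=seed,
                               n_estimators=200)
            r1 = np.corrcoef(y_te, p1)[0, 1]
            r2 = np.corrcoef(y_te, p2)[0, 1]
            wins += int(r2 > r1)
        assert wins >= 16

    def test_too_few_training_lines_rejected(self, rng):
        tr = IntermediateTraitSet(_table(rng, 5), "gp")
        y = pd.Series(np.ones(5), index=tr.table.index)
        with pytest.raises(ValueError, match=">= 10"):
            intml_predict(tr, y, tr, "ml1")


class TestPanicle:
    def test_product_value(self):
        bm = pd.Series([1000.0], index=["a"])
        hi = pd.Series([0.45], index=["a"])
        assert panicle_predict(bm, hi).iloc[0] == pytest.approx(450.0)

    def test_zero_harvest_index_annihilates(self):
        bm = pd.Series([1234.0], index=["a"])
        hi = pd.Series([0.0], index=["a"])
        assert panicle_predict(bm, hi).iloc[0] == 0.0

    def test_bilinear(self, rng):
        idx = list("abcd")
        bm = pd.Series(rng.uniform(500, 1500, 4), index=idx)
        hi = pd.Series(rng.uniform(0.3, 0.5, 4), index=idx)
        assert np.allclose(panicle_predict(2 * bm, hi),
                           2 * panicle_predict(bm, hi))


class TestIntCGMClosedLoop:
    def test_true_intermediates_reproduce_generator_biomass(self,
                                                            zero_noise_sim):
        ds, truth = zero_noise_sim
        for env in ds.environments:
            tab = truth.growth[env].copy()
            tab["heading_day"] = truth.heading_day[env]
            inter = IntermediateTraitSet(tab, "dvr")
            pred, tau = intcgm_predict(inter, ds.weather[env],
                                       ds.sowing_dates[env], tau=1.0)
            assert tau == 1.0
            assert np.abs(pred.to_numpy()
                          - truth.biomass[env].to_numpy()).max() < 1e-9

    def test_identical_intermediates_identical_predictions(self, rng,
                                                           zero_noise_sim):
        ds, _ = zero_noise_sim
        tab = _table(rng, 4)
        tab.iloc[1] = tab.iloc[0]
        inter = IntermediateTraitSet(tab, "gp")
        pred, _ = intcgm_predict(inter, ds.weather["2014"],
                                 ds.sowing_dates["2014"], tau=1.0)
        assert pred.iloc[0] == pred.iloc[1]

    def test_no_heading_line_flagged_not_fatal(self, rng, zero_noise_sim):
        ds, _ = zero_noise_sim
        tab = _table(rng, 3)
        tab.loc[tab.index[1], "heading_day"] = np.nan
        inter = IntermediateTraitSet(tab, "dvr")
        pred, _ = intcgm_predict(inter, ds.weather["2014"],
                                 ds.sowing_dates["2014"], tau=1.0)
        assert np.isnan(pred.iloc[1])
        assert np.isfinite(pred.iloc[0]) and np.isfinite(pred.iloc[2])


class TestStepOne:
    def test_noiseless_traits_predicted_accurately_cv(self, zero_noise_sim,
                                                      default_config):
        # h²=1, sparse additive architecture: out-of-fold LASSO r > 0.95
        ds, _ = zero_noise_sim
        lines = list(ds.genotypes.line_ids)
        folds = kfold_split(lines, 10, np.random.default_rng(2))
        pred = {t: pd.Series(index=lines, dtype=float)
                for t in GROWTH_TRAITS}
        for fold in folds:
            test = list(fold)
            train = [l for l in lines if l not in set(test)]
            inter = predict_intermediate_traits(
                ds, train, test, "2014", default_config,
                heading_source="gp")
            for t in GROWTH_TRAITS:
                pred[t].loc[test] = inter.table[t]
        for t in GROWTH_TRAITS:
            obs = ds.phenotypes["2014"].loc[lines, t]
            r, _, _ = metrics(obs.to_numpy(), pred[t].loc[lines].to_numpy())
            assert r > 0.95, t

    def test_gp_heading_fallback_routes_through_markers(self, small_sim,
                                                        default_config):
        ds, _ = small_sim
        lines = list(ds.genotypes.line_ids)
        inter = predict_intermediate_traits(
            ds, lines[:20], lines[20:], "2015", default_config,
            heading_source="gp")
        assert inter.heading_source == "gp"
        assert np.all(np.isfinite(inter.table["heading_day"]))

    def test_dvr_heading_requires_elm(self, small_sim, default_config):
        ds, _ = small_sim
        lines = list(ds.genotypes.line_ids)
        with pytest.raises(ValueError, match="ELM"):
            predict_intermediate_traits(ds, lines[:20], lines[20:], "2015",
                                        default_config,
                                        heading_source="dvr")


class TestWeatherSensitivity:
    def test_intcgm_responds_to_weather_gp_does_not(self, default_sim,
                                                    default_config,
                                                    default_elm):
        # the mechanistic route must react to the target season; the pure
        # marker regression cannot
        from ricepred.gp import fit_gp, predict_gp
        ds, _ = default_sim
        lines = list(ds.genotypes.line_ids)[:40]
        hd14 = dvr_heading_days(ds.genotypes.subset(lines), default_elm,
                                ds.gene_marker_map, ds.weather["2014"],
                                ds.sowing_dates["2014"], default_config)
        hd15 = dvr_heading_days(ds.genotypes.subset(lines), default_elm,
                                ds.gene_marker_map, ds.weather["2015"],
                                ds.sowing_dates["2015"], default_config)
        assert np.nanmean(np.abs(hd14 - hd15)) > 1.0

        y = ds.phenotypes["2014"].loc[list(ds.genotypes.line_ids),
                                      "biomass"].to_numpy()
        model = fit_gp(ds.genotypes, y, "lasso", seed=1)
        p = predict_gp(model, ds.genotypes.subset(lines))
        # identical call later — markers only, no weather anywhere
        assert np.array_equal(p, predict_gp(model,
                                            ds.genotypes.subset(lines)))
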