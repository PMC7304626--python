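"""DVR phenology: response functions, DVS simulation, PSO fit, ELM map."""

import numpy as np
import pandas as pd
import pytest

from ricepred.config import DVRCardinals, ELMSettings, PSOSettings
from ricepred.phenology import (DVRParams, METRecord, _heading_batch,
                                _heading_batch_loop, day_length, elm_fit,
                                elm_predict, f_temp, fit_dvr_pso, g_photo,
                                simulate_dvs_heading)
from ricepred.synthetic import (SyntheticScenario, sim_met_panel,
                                sim_met_trials)


class TestDayLength:
    def test_equator_near_twelve_hours(self):
        for doy in (10, 100, 200, 300):
            assert abs(day_length(0.0, doy) - 12.0) < 0.2

    def test_equinox_near_twelve_hours(self):
        assert abs(day_length(36.01, 80) - 12.0) < 0.3

    def test_solstice_contrast_midlatitude(self):
        summer = day_length(36.01, 172)
        winter = day_length(36.01, 355)
        assert summer > winter
        assert summer - winter > 4.0

    def test_polar_latitude_rejected(self):
        with pytest.raises(ValueError, match="polar"):
            day_length(70.0, 100)

    def test_vectorized_over_days(self):
        out = day_length(36.01, np.arange(1, 366))
        assert out.shape == (365,)
        assert np.all((out > 0) & (out < 24))


class TestTemperatureResponse:
    @pytest.mark.parametrize("t, expected", [
        (8.0, 0.0), (42.0, 0.0), (30.0, 1.0), (-5.0, 0.0), (50.0, 0.0),
        (20.0, 0.7592),
    ])
    def test_values(self, t, expected):
        assert f_temp(t) == pytest.approx(expected, abs=1e-4)

    def test_bounded_and_peaked(self):
        t = np.linspace(-10, 50, 2001)
        v = f_temp(t)
        assert np.all((v >= 0) & (v <= 1))
        assert t[np.argmax(v)] == pytest.approx(30.0, abs=0.05)

    def test_continuity_at_branch_points(self):
        # the ceiling branch has infinite slope (exponent < 1), so the
        # probe interval must be tiny there
        assert abs(f_temp(8.0 + 1e-8) - f_temp(8.0 - 1e-8)) < 1e-6
        assert abs(f_temp(42.0 + 1e-12) - f_temp(42.0 - 1e-12)) < 1e-6


class TestPhotoperiodResponse:
    @pytest.mark.parametrize("p, expected", [
        (9.0, 1.0), (10.0, 1.0), (14.0, 0.8741), (24.0, 0.0), (5.0, 1.0),
    ])
    def test_values(self, p, expected):
        assert g_photo(p) == pytest.approx(expected, abs=1e-4)

    def test_continuity_at_optimum(self):
        assert abs(g_photo(10.0 + 1e-8) - g_photo(10.0 - 1e-8)) < 1e-6

    def test_decreasing_beyond_optimum(self):
        p = np.linspace(10, 24, 500)
        v = g_photo(p)
        assert np.all(np.diff(v) <= 1e-12)


class TestDVSSimulation:
    def test_constant_optimum_heads_at_g_days(self, const_weather):
        w = const_weather(t=30.0, day_len=9.0)
        res = simulate_dvs_heading(DVRParams(3.7, 2.0, 100.0), w,
                                   "2020-05-01")
        assert res.heading_day == 100

    def test_base_temperature_never_heads(self, const_weather):
        w = const_weather(t=8.0)
        res = simulate_dvs_heading(DVRParams(2.0, 3.0, 100.0), w,
                                   "2020-05-01")
        assert not res.headed
        assert np.allclose(res.dvs, 0.0)

    def test_trajectory_non_decreasing(self, const_weather):
        w = const_weather(t=24.0, day_len=14.0)
        res = simulate_dvs_heading(DVRParams(1.5, 2.0, 60.0), w,
                                   "2020-05-01")
        assert res.headed
        assert np.all(np.diff(res.dvs) >= 0)

    def test_blocked_photoperiod_window_stalls(self, const_weather):
        # g(24h) = 0 applies only inside the DVS window -> stalls there
        w = const_weather(t=30.0, day_len=24.0)
        res = simulate_dvs_heading(DVRParams(2.0, 3.0, 100.0), w,
                                   "2020-05-01")
        assert not res.headed
        assert res.dvs.max() < 0.85

    def test_photoperiod_delay_closed_form(self, const_weather):
        # delay ≈ 0.2·G·(1/g^β − 1) when g^β < 1 throughout the window
        g_val = g_photo(14.0)  # 0.8741
        beta = 3.0
        w = const_weather(t=30.0, day_len=14.0)
        res = simulate_dvs_heading(DVRParams(5.0, beta, 100.0), w,
                                   "2020-05-01")
        expected = 100 + 0.2 * 100.0 * (1.0 / g_val ** beta - 1.0)
        assert res.headed
        assert res.heading_day == pytest.approx(expected, abs=3)

    def test_warmer_series_never_delays_heading(self, const_weather):
        params = DVRParams(2.0, 1.0, 80.0)
        heads = []
        for t in (20.0, 24.0, 28.0):  # all within [T_b, T_o]
            res = simulate_dvs_heading(params, const_weather(t=t),
                                       "2020-05-01")
            assert res.headed
            heads.append(res.heading_day)
        assert heads[0] >= heads[1] >= heads[2]


class TestHeadingBatchEquivalence:
    def test_fast_phase_decomposition_matches_day_loop(self, rng):
        for _ in range(60):
            n_p, n_d = 6, int(rng.integers(60, 240))
            ft = rng.random((n_p, n_d)) * rng.random((n_p, 1))
            gp = rng.random((n_p, n_d)) ** rng.uniform(0, 3)
            g = rng.uniform(40, 200, n_p)
            for frac in (False, True):
                fast = _heading_batch(ft, gp, g, fractional=frac)
                ref = _heading_batch_loop(ft, gp, g, fractional=frac)
                assert np.array_equal(np.isnan(fast), np.isnan(ref))
                assert np.allclose(np.nan_to_num(fast), np.nan_to_num(ref),
                                   atol=1e-8)


def _noiseless_met(n_lines: int, seed: int = 5):
    sc = SyntheticScenario(seed=seed, met_panel_size=n_lines,
                           heading_noise_days=0)
    rng = np.random.default_rng(1)
    eff = rng.standard_normal((6, 3))
    eff /= np.sqrt((eff ** 2).sum(0))
    eff *= np.asarray(sc.dvr_sds)
    _, panel = sim_met_panel(sc, eff, sc.rng("panel"))
    met = sim_met_trials(panel, sc, sc.rng("met"))
    return met, panel


class TestPSOFit:
    def test_single_line_recovery_noiseless(self):
        met, panel = _noiseless_met(1)
        recs = met.for_line(met.line_ids[0])
        fit = fit_dvr_pso(recs, PSOSettings(), np.random.default_rng(2))
        for r in recs:
            res = simulate_dvs_heading(fit.params, r.weather, r.sowing_date)
            assert res.headed
            assert abs(res.heading_day - r.days_to_heading) <= 1

    def test_degenerate_swarm_returns_initial_position(self, const_weather):
        met, _ = _noiseless_met(1)
        recs = met.for_line(met.line_ids[0])
        settings = PSOSettings(swarm_size=1, iterations=5, inertia=0.0,
                               c1=0.0, c2=0.0)
        rng = np.random.default_rng(22)  # initial particle heads everywhere
        # replicate the seeded initial draw
        lb = np.array([0.0, 0.0, 40.0])
        span = np.array([10.0, 15.0, 160.0])
        x0 = lb + np.random.default_rng(22).random((1, 3)) * span
        fit = fit_dvr_pso(recs, settings, rng)
        got = np.array([fit.params.alpha, fit.params.beta_p, fit.params.g])
        assert np.allclose(got, x0[0])

    def test_best_objective_non_increasing(self):
        met, _ = _noiseless_met(1)
        recs = met.for_line(met.line_ids[0])
        fit = fit_dvr_pso(recs, PSOSettings(iterations=50),
                          np.random.default_rng(4))
        assert np.all(np.diff(fit.history) <= 1e-12)

    def test_too_few_trials_rejected(self, const_weather):
        w = const_weather()
        recs = [METRecord("L", "T1", 36.0, pd.Timestamp("2020-05-01"),
                          pd.Timestamp("2020-08-01"), w)]
        with pytest.raises(ValueError, match=">=3 trials"):
            fit_dvr_pso(recs, PSOSettings(), np.random.default_rng(0))


class TestELM:
    def test_constant_targets_recovered_exactly(self, rng):
        x = rng.choice([-1.0, 1.0], size=(40, 6))
        y = np.tile([1.5, 2.5, 80.0], (40, 1))
        model = elm_fit(x, y, ELMSettings(), seed=1)
        pred = model.predict(rng.choice([-1.0, 1.0], size=(7, 6)))
        assert np.allclose(pred, [1.5, 2.5, 80.0], atol=1e-9)

    def test_seeded_refit_reproduces_weights(self, rng):
        x = rng.choice([-1.0, 1.0], size=(30, 6))
        y = rng.normal(size=(30, 3)) + [1.5, 2.0, 65.0]
        m1 = elm_fit(x, y, ELMSettings(), seed=5)
        m2 = elm_fit(x, y, ELMSettings(), seed=5)
        assert np.array_equal(m1.w_in, m2.w_in)
        assert np.array_equal(m1.w_out, m2.w_out)

    def test_linear_targets_fit_well(self):
        rng = np.random.default_rng(3)
        x = rng.choice([-1.0, 1.0], size=(112, 6))
        b = rng.normal(size=(6, 3))
        y = np.array([1.5, 2.0, 65.0]) + x @ b * [0.1, 0.2, 2.0] \
            + rng.normal(0, 0.02, (112, 3))
        model = elm_fit(x, y, ELMSettings(hidden_nodes=50), seed=2)
        pred = model.predict(x)
        for j in range(3):
            ss_res = np.sum((pred[:, j] - y[:, j]) ** 2)
            ss_tot = np.sum((y[:, j] - y[:, j].mean()) ** 2)
            assert 1 - ss_res / ss_tot > 0.9

    def test_prediction_clamped_to_bounds(self, marker_factory, rng):
        x = rng.choice([-1.0, 1.0], size=(40, 6))
        y = np.tile([20.0, 2.0, 65.0], (40, 1))  # alpha target beyond bound
        model = elm_fit(x, y, ELMSettings(), seed=1)
        markers = marker_factory(5, 6)
        gene_map = {f"Hd{i}": f"M{i:03d}" for i in range(6)}
        with pytest.warns(UserWarning, match="clamped"):
            out = elm_predict(model, markers, gene_map)
        assert np.all(out["alpha"].to_numpy() == 10.0)

    def test_unresolved_gene_named_in_error(self, marker_factory, rng):
        x = rng.choice([-1.0, 1.0], size=(40, 6))
        y = np.tile([1.5, 2.0, 65.0], (40, 1))
        model = elm_fit(x, y, ELMSettings(), seed=1)
        markers = marker_factory(5, 6)
        gene_map = {"Hd1": "M000", "Ghd7": "ABSENT"}
        with pytest.raises(KeyError, match="Ghd7"):
            elm_predict(model, markers, gene_map)

    def test_identical_genotype_lines_get_identical_params(
            self, marker_factory, rng):
        x = rng.choice([-1.0, 1.0], size=(40, 6))
        y = np.array([1.5, 2.0, 65.0]) + rng.normal(0, 0.1, (40, 3))
        model = elm_fit(x, y, ELMSettings(), seed=1)
        codes = np.ones((2, 6))
        markers = marker_factory(2, 6, codes=codes)
        gene_map = {f"Hd{i}": f"M{i:03d}" for i in range(6)}
        out = elm_predict(model, markers, gene_map)
        assert np.allclose(out.iloc[0], out.iloc[1])
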