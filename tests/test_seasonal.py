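"""Seasonal concatenation, masked-likelihood SARIMA fits and forecasting."""

import numpy as np
import pytest
from statsmodels.tsa.statespace.sarimax import SARIMAX

from seasonalcgm.partition import RegularizedPartition
from seasonalcgm.seasonal import (
    BLANK,
    PRESAMPLE,
    SCORED,
    FitError,
    SarimaOrder,
    SeasonalSeries,
    batch_forecasts,
    concatenate_cluster,
    fit_sarima,
    forecast_local,
    search_order,
    train_local_models,
)


def _plain_series(values, s, pr=0):
    """All-scored series (length must be a multiple of s)."""
    return SeasonalSeries(np.asarray(values, float),
                          np.zeros(len(values), dtype=np.int8), L=s - pr, Pr=pr)


def simulate_sarima(params, order, seasonal, n, seed, s=20):
    mod = SARIMAX(np.zeros(n), order=order, seasonal_order=seasonal + (s,),
                  trend="c", concentrate_scale=False)
    return mod.simulate(np.asarray(params), n,
                        random_state=np.random.default_rng(seed))


class TestConcatenate:
    def test_block_arithmetic(self):
        pres = np.full((3, 5), 100.0)
        rows = np.full((3, 10), 120.0)
        ser = concatenate_cluster(pres, rows, L=10, Pr=5)
        assert ser.values.size == 45
        assert ser.s == 15

    def test_seasonality_98_plus_5(self):
        pres = np.full((2, 5), 100.0)
        rows = np.full((2, 98), 120.0)
        ser = concatenate_cluster(pres, rows, L=98, Pr=5)
        assert ser.s == 103

    def test_mask_layout_single_row(self):
        pres = np.full((1, 5), 100.0)
        rows = np.full((1, 10), 120.0)
        ser = concatenate_cluster(pres, rows, L=10, Pr=5)
        assert (ser.mask[:5] == PRESAMPLE).all()
        assert (ser.mask[5:] == SCORED).all()

    def test_padding_flagged_blank_and_counts_reconcile(self):
        pres = np.full((2, 3), 100.0)
        rows = np.array([[120.0, 121.0, np.nan, np.nan],
                         [119.0, 118.0, 117.0, 116.0]])
        ser = concatenate_cluster(pres, rows, L=4, Pr=3)
        assert ser.values.size % ser.s == 0
        assert int((ser.mask == BLANK).sum()) == 2
        assert int((ser.mask == PRESAMPLE).sum()) == 6
        assert ser.scored_count() == 6

    def test_empty_cluster_is_error(self):
        with pytest.raises(ValueError):
            concatenate_cluster(np.empty((0, 5)), np.empty((0, 10)), L=10, Pr=5)


class TestFitSarima:
    def test_white_noise_variance(self):
        rng = np.random.default_rng(0)
        y = 100 + rng.normal(0, 3, 400)
        fit = fit_sarima(_plain_series(y, s=20), SarimaOrder(0, 0, 0, 0, 0, 0, 20))
        assert fit.sigma2 == pytest.approx(np.var(y), rel=0.05)
        assert fit.alpha == pytest.approx(y.mean(), abs=0.5)

    @pytest.mark.parametrize("mask_frac", [0.0, 0.1])
    def test_parameter_recovery_sar(self, mask_frac):
        s, n = 20, 2000
        true = np.array([120 * (1 - 0.6) * (1 - 0.3), 0.6, 0.3, 4.0])
        y = simulate_sarima(true, (1, 0, 0), (1, 0, 0), n, seed=42, s=s)
        mask = np.zeros(n, dtype=np.int8)
        if mask_frac:
            rng = np.random.default_rng(1)
            mask[rng.random(n) < mask_frac] = BLANK
        ser = SeasonalSeries(y, mask, L=s, Pr=0)
        fit = fit_sarima(ser, SarimaOrder(1, 0, 0, 1, 0, 0, s), compute_cov=True)
        z = np.abs(fit.params - true[:3]) / fit.bse
        assert np.all(z < 3.0)

    def test_masked_likelihood_equals_unmasked_reference(self):
        rng = np.random.default_rng(5)
        y = 110 + rng.normal(0, 5, 300)
        ser = _plain_series(y, s=20)
        fit = fit_sarima(ser, SarimaOrder(1, 0, 0, 0, 0, 0, 20))
        ref = SARIMAX(y, order=(1, 0, 0), trend="c",
                      concentrate_scale=True).filter(fit.params)
        assert fit.llf == pytest.approx(float(ref.llf), abs=1e-6)

    def test_too_short_series_is_error(self):
        y = 100 + np.zeros(40)
        with pytest.raises(FitError):
            fit_sarima(_plain_series(y, s=20), SarimaOrder(1, 0, 0, 1, 0, 0, 20))


class TestSearchOrder:
    def test_white_noise_selects_minimal_model(self):
        rng = np.random.default_rng(2)
        y = 100 + rng.normal(0, 3, 600)
        s = 20
        grid = [SarimaOrder(p, 0, q, P, 0, Q, s)
                for p in (0, 1) for q in (0, 1) for P in (0, 1) for Q in (0,)]
        best = search_order(_plain_series(y, s=s), grid)
        o = best.order
        assert o.p + o.q + o.P + o.Q <= 1

    def test_selected_order_close_to_truth_in_one_step_error(self):
        s, n = 20, 1500
        true = np.array([5.0, 0.5, 0.2, 0.3, 0.4, 0.3, 4.0])
        y = simulate_sarima(true, (2, 0, 1), (1, 0, 1), n, seed=7, s=s)
        ser = _plain_series(y, s=s)
        grid = [SarimaOrder(*k, s=s) for k in
                [(1, 0, 0, 1, 0, 0), (2, 0, 1, 1, 0, 1), (1, 0, 1, 1, 0, 0)]]
        best = search_order(ser, grid)
        true_fit = fit_sarima(ser, SarimaOrder(2, 0, 1, 1, 0, 1, s))

        def one_step_rmse(model):
            F = batch_forecasts(model, ser.endog_for_fit(), 1)[:-1, 0]
            return float(np.sqrt(np.nanmean((y[1:] - F) ** 2)))

        assert one_step_rmse(best) <= 1.05 * one_step_rmse(true_fit)

    def test_single_order_grid_returns_that_fit(self):
        rng = np.random.default_rng(3)
        y = 100 + rng.normal(0, 3, 300)
        order = SarimaOrder(1, 0, 0, 0, 0, 0, 20)
        best = search_order(_plain_series(y, s=20), [order])
        assert best.order.key() == order.key()


class TestForecast:
    def test_intercept_only_constant_forecast(self):
        rng = np.random.default_rng(4)
        y = 100 + rng.normal(0, 1, 200)
        ser = _plain_series(y, s=20)
        fit = fit_sarima(ser, SarimaOrder(0, 0, 0, 0, 0, 0, 20))
        f = forecast_local(fit, ser, current=np.array([100.0]), horizon=4)
        np.testing.assert_allclose(f, fit.alpha, rtol=1e-8)

    def test_pure_seasonal_ar_repeats_one_season_back(self):
        # Φ1 → 1, no intercept: forecast(t) → y(t − s)
        from seasonalcgm.seasonal import SarimaModel

        s = 6
        model = SarimaModel(order=SarimaOrder(0, 0, 0, 1, 0, 0, s),
                            params=np.array([0.0, 0.9999]),
                            param_names=["intercept", "ar.S.L6"],
                            bse=np.full(2, np.nan), sigma2=1.0, llf=0.0,
                            aicc=0.0, converged=True)
        hist = _plain_series(np.tile([101.0, 102, 103, 104, 105, 106], 3), s=s)
        f = forecast_local(model, hist, current=np.empty(0), horizon=6)
        np.testing.assert_allclose(f, [101, 102, 103, 104, 105, 106], atol=0.05)

    def test_ar1_hand_recursion(self):
        from seasonalcgm.seasonal import SarimaModel

        phi, alpha = 0.7, 30.0
        model = SarimaModel(order=SarimaOrder(1, 0, 0, 0, 0, 0, 5),
                            params=np.array([alpha, phi]),
                            param_names=["intercept", "ar.L1"],
                            bse=np.full(2, np.nan), sigma2=1.0, llf=0.0,
                            aicc=0.0, converged=True)
        y_last = 150.0
        hist = _plain_series(np.full(25, 100.0), s=5)
        f = forecast_local(model, hist, current=np.array([y_last]), horizon=3)
        expect, y = [], y_last
        for _ in range(3):
            y = alpha + phi * y
            expect.append(y)
        np.testing.assert_allclose(f, expect, rtol=1e-6)

    def test_batch_forecasts_match_refiltered_forecasts(self):
        s, n = 10, 300
        y = simulate_sarima(np.array([8.0, 0.5, 0.3, 2.0]),
                            (1, 0, 0), (1, 0, 0), n, seed=9, s=s)
        ser = _plain_series(y, s=s)
        fit = fit_sarima(ser, SarimaOrder(1, 0, 0, 1, 0, 0, s))
        F = batch_forecasts(fit, y, 4)
        for origin in (50, 150, n - 1):
            ref = SARIMAX(y[:origin + 1], order=(1, 0, 0),
                          seasonal_order=(1, 0, 0, s), trend="c",
                          concentrate_scale=True).filter(fit.params).forecast(4)
            np.testing.assert_allclose(F[origin], np.asarray(ref), atol=1e-8)


class TestTrainLocalModels:
    def _partition_with_two_dynamics(self, n_rows=16, L=30, pr=3, seed=0):
        rng = np.random.default_rng(seed)
        rows, labels = [], []
        t = np.arange(L)
        for j in range(n_rows):
            k = j % 2
            base = 150 + 50 * np.sin(2 * np.pi * t / L) if k == 0 else np.full(L, 90.0)
            rows.append(base + rng.normal(0, 2, L))
            labels.append(k)
        part = RegularizedPartition(
            key="M", L=L, Pr=pr, rows=np.array(rows),
            presamples=np.full((n_rows, pr), 100.0),
            event_indices=list(range(n_rows)), lengths=[L] * n_rows)
        return part, np.array(labels)

    def test_80_20_split(self):
        from seasonalcgm.clustering import pdsfcm

        part, _ = self._partition_with_two_dynamics(n_rows=20)
        cs = pdsfcm(part, 2, seed=0, restarts=2)
        grid = [SarimaOrder(1, 0, 0, 0, 0, 0, part.L + part.Pr)]
        lms = train_local_models(part, cs, grid=grid)
        assert lms.c == 2
        for held, hist in zip(lms.heldout_blocks, lms.histories):
            assert len(held) == hist.n_blocks - int(np.floor(0.8 * hist.n_blocks))

    def test_single_cluster_partition_trains_one_model(self):
        from seasonalcgm.clustering import select_c

        part, _ = self._partition_with_two_dynamics(n_rows=6)
        cs = select_c(part, n_min=10)
        assert cs.c == 1
        grid = [SarimaOrder(1, 0, 0, 0, 0, 0, part.L + part.Pr)]
        lms = train_local_models(part, cs, grid=grid)
        assert lms.c == 1
        assert lms.histories[0].n_blocks == 6

    def test_round_trip_persistence(self, tmp_path):
        from seasonalcgm.clustering import pdsfcm
        from seasonalcgm.seasonal import LocalModelSet

        part, _ = self._partition_with_two_dynamics(n_rows=12)
        cs = pdsfcm(part, 2, seed=0, restarts=1)
        grid = [SarimaOrder(1, 0, 0, 0, 0, 0, part.L + part.Pr)]
        lms = train_local_models(part, cs, grid=grid)
        path = tmp_path / "models_M.json"
        lms.to_json(path)
        back = LocalModelSet.from_json(path)
        assert back.c == lms.c and back.s == lms.s
        np.testing.assert_allclose(back.models[0].params, lms.models[0].params)
        np.testing.assert_array_equal(
            np.isnan(back.histories[0].values), np.isnan(lms.histories[0].values))
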