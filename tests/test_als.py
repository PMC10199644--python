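"""Canopy metrics and area-based models: metrics, fitting, selection, prediction."""

import numpy as np
import pandas as pd
import pytest

from standcarbon.als import (
    AreaModelSet,
    bic,
    compute_als_metrics,
    fit_area_models,
    predict_cell_state,
    select_area_model,
    ALSMetricsError,
)
from standcarbon.synthetic import TRUE_AREA_BETA


class TestMetrics:
    def test_uniform_canopy(self):
        m = compute_als_metrics([10.0] * 50)
        for p in range(10, 100, 10):
            assert m[f"H_ALS_{p}"] == 10.0
        assert m["H_ALS_mean"] == 10.0
        for i in range(1, 10):  # levels strictly below 10 m
            assert m[f"D_ALS_{i}"] == 1.0

    def test_single_return(self):
        m = compute_als_metrics([5.0])
        assert all(m[f"H_ALS_{p}"] == 5.0 for p in range(10, 100, 10))
        assert m["H_ALS_mean"] == 5.0

    def test_percentiles_match_independent_quantile_oracle(self):
        """Brute-force linear-interpolation quantile on sorted order statistics."""
        heights = np.arange(1.0, 101.0)  # 1..100 m
        m = compute_als_metrics(heights)
        canopy = np.sort(heights[heights > 1.3])
        n = len(canopy)
        for p in range(10, 100, 10):
            rank = (p / 100) * (n - 1)
            lo, frac = int(np.floor(rank)), rank - int(np.floor(rank))
            expect = canopy[lo] * (1 - frac) + canopy[min(lo + 1, n - 1)] * frac
            assert m[f"H_ALS_{p}"] == pytest.approx(expect, rel=1e-12)

    def test_density_levels_span_threshold_to_p95(self):
        heights = np.linspace(2.0, 30.0, 200)
        m = compute_als_metrics(heights)
        p95 = np.percentile(heights, 95)
        assert m["D_ALS_1"] == pytest.approx(np.mean(heights > 1.3))
        assert m["D_ALS_10"] == pytest.approx(np.mean(heights > p95))
        dens = [m[f"D_ALS_{i}"] for i in range(1, 11)]
        assert all(a >= b for a, b in zip(dens, dens[1:]))

    def test_empty_and_zero_canopy(self):
        with pytest.raises(ALSMetricsError):
            compute_als_metrics([])
        sentinel = compute_als_metrics([0.2, 0.5, 1.0])
        assert (sentinel == 0.0).all()


class TestAreaModelFit:
    def test_zero_noise_recovery_and_row_count(self, zero_bundle, zero_models):
        area, _ = zero_models
        assert area["lnBMS"].n_obs == 2 * zero_bundle.config.n_plots
        for name, beta in TRUE_AREA_BETA.items():
            assert np.allclose(area[name].beta, beta, atol=1e-9), name

    def test_covariance_matches_matrix_oracle(self, noisy_bundle):
        area = fit_area_models(noisy_bundle.plots)
        model = area["lnBMS"]
        plots = noisy_bundle.plots
        x = np.column_stack([np.ones(len(plots)), plots["D_ALS_2"], plots["H_ALS_80"],
                             plots["T"]])
        y = np.log(plots["BMS"].to_numpy())
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        resid = y - x @ beta
        cov = (resid @ resid / (len(y) - 4)) * np.linalg.inv(x.T @ x)
        assert np.allclose(model.beta, beta, rtol=1e-9)
        assert np.allclose(model.cov, cov, rtol=1e-6)

    def test_epoch_swap_time_invariance(self, noisy_bundle):
        """Recoding the epoch dummy reproduces identical fitted responses."""
        plots = noisy_bundle.plots
        swapped = plots.copy()
        swapped["T"] = 1 - swapped["T"]
        a1 = fit_area_models(plots)
        a2 = fit_area_models(swapped)
        pred1 = a1["lnBMS"].predict(plots)
        pred2 = a2["lnBMS"].predict(swapped)
        assert np.allclose(pred1, pred2, rtol=1e-9)

    def test_missing_columns_rejected(self, noisy_bundle):
        with pytest.raises(ValueError, match="missing"):
            fit_area_models(noisy_bundle.plots.drop(columns=["BMS"]))


class TestSelection:
    def _table(self, rng, n=80):
        x = pd.DataFrame({f"D_ALS_{i}": rng.uniform(0, 1, n) for i in range(1, 6)})
        x["T"] = np.repeat([0.0, 1.0], n // 2)
        return x

    def test_perfect_predictor_selected(self, rng):
        table = self._table(rng)
        table["y"] = 3.0 + 2.0 * table["D_ALS_3"] + 0.5 * table["T"]
        chosen = select_area_model(table, "y", [f"D_ALS_{i}" for i in range(1, 6)])
        assert chosen == ["D_ALS_3", "T"]

    def test_bic_matches_hand_formula(self, rng):
        table = self._table(rng)
        y = 1.0 + table["D_ALS_1"] + rng.normal(0, 0.3, len(table))
        x = np.column_stack([np.ones(len(table)), table["D_ALS_1"]])
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
        rss = float(np.sum((y - x @ beta) ** 2))
        n, p = x.shape
        assert bic(y.to_numpy(), x) == pytest.approx(n * np.log(rss / n) + p * np.log(n))

    def test_duplicated_predictor_blocked_by_vif(self, rng):
        table = self._table(rng)
        table["D_ALS_2"] = table["D_ALS_1"]  # infinite VIF when joint
        table["y"] = (1.0 + 2.0 * table["D_ALS_1"] + 1.0 * table["D_ALS_3"]
                      + rng.normal(0, 0.05, len(table)))
        chosen = select_area_model(table, "y",
                                   ["D_ALS_1", "D_ALS_2", "D_ALS_3"])
        assert not {"D_ALS_1", "D_ALS_2"} <= set(chosen)

    def test_max_params_respected(self, rng):
        table = self._table(rng)
        table["y"] = rng.normal(0, 1, len(table))
        chosen = select_area_model(table, "y", [f"D_ALS_{i}" for i in range(1, 6)],
                                   max_params=5)
        assert len(chosen) + 1 <= 5  # + intercept


class TestPrediction:
    def test_null_log_model_predicts_one(self, zero_models, zero_bundle):
        import copy

        area, _ = zero_models
        area0 = copy.deepcopy(area)
        area0.models["lnBMS"].beta = np.zeros(4)
        metrics = _metrics_at(zero_bundle, 2001).head(5)
        state = predict_cell_state(area0, metrics, 0)
        assert np.allclose(state["BMS"], 1.0)

    def test_mean_height_two_step_hand_evaluation(self, zero_models, zero_bundle):
        area, _ = zero_models
        metrics = _metrics_at(zero_bundle, 2016).head(8)
        state = predict_cell_state(area, metrics, 1)
        bh = area["H"].beta
        expect = bh[0] + bh[1] * state["Hdom"].to_numpy() + bh[2] * 1.0
        assert np.allclose(state["H"], expect, rtol=1e-12)

    def test_zero_noise_predictions_equal_truth(self, zero_models, zero_bundle):
        area, _ = zero_models
        y0 = zero_bundle.config.epoch_years[0]
        metrics = _metrics_at(zero_bundle, y0)
        state = predict_cell_state(area, metrics, 0)
        truth = zero_bundle.truth
        for col in ("D", "Hdom", "H", "BMS"):
            assert np.allclose(state[col], truth[f"{col}_{y0}"], rtol=1e-8), col

    def test_prediction_is_pure_function(self, zero_models, zero_bundle):
        area, _ = zero_models
        metrics = _metrics_at(zero_bundle, 2001).head(3)
        a = predict_cell_state(area, metrics, 0)
        b = predict_cell_state(area, metrics, 0)
        pd.testing.assert_frame_equal(a, b)


def _metrics_at(bundle, year):
    from standcarbon.als import METRIC_COLUMNS

    return pd.DataFrame({c: bundle.cells[f"{c}_{year}"] for c in METRIC_COLUMNS})


def test_json_round_trip(zero_models):
    area, _ = zero_models
    restored = AreaModelSet.from_json(area.to_json())
    for name in ("lnD", "Hdom", "lnBMS", "H"):
        assert np.allclose(restored[name].beta, area[name].beta)
        assert restored[name].predictors == area[name].predictors
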