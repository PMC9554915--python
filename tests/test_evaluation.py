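"""Metrics, grid search, repeated evaluation and model comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flavopot.evaluation import (
    ExperimentResult,
    compute_metrics,
    default_estimator_specs,
    inner_grid_search,
    mann_whitney_p,
    pairwise_model_comparison,
    radius_scan,
    repeated_evaluation,
    results_to_tidy,
)
from flavopot.synthetic import generate_record_set

LR_GRID = {"select__alpha": [10.0], "select__rho": [1.0]}


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        m = compute_metrics(y, y)
        assert m == {"MAE": 0.0, "RMSE": 0.0, "R2": 1.0, "SC": 1.0}

    def test_constant_offset(self):
        y = np.array([-250.0, -100.0, 30.0, -310.0])
        m = compute_metrics(y, y + 10.0)
        assert m["MAE"] == pytest.approx(10.0)
        assert m["RMSE"] == pytest.approx(10.0)
        assert m["SC"] == pytest.approx(1.0)

    def test_matches_definition_oracle(self):
        rng = np.random.default_rng(0)
        y_true = rng.normal(-223, 109, 100)
        y_pred = y_true + rng.normal(0, 40, 100)
        m = compute_metrics(y_true, y_pred)
        diff = y_pred - y_true
        assert m["MAE"] == pytest.approx(np.mean(np.abs(diff)), rel=1e-12)
        assert m["RMSE"] == pytest.approx(math.sqrt(np.mean(diff**2)), rel=1e-12)
        ss_res = np.sum(diff**2)
        ss_tot = np.sum((y_true - y_true.mean()) ** 2)
        assert m["R2"] == pytest.approx(1 - ss_res / ss_tot, rel=1e-12)
        # Spearman from rank definition
        rx = stats.rankdata(y_true)
        ry = stats.rankdata(y_pred)
        assert m["SC"] == pytest.approx(np.corrcoef(rx, ry)[0, 1], rel=1e-9)

    def test_rmse_dominates_mae(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            y = rng.normal(size=30)
            p = y + rng.normal(size=30)
            m = compute_metrics(y, p)
            assert m["RMSE"] >= m["MAE"]
            assert m["R2"] <= 1.0
            assert -1.0 <= m["SC"] <= 1.0

    def test_constant_truth_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMannWhitney:
    def test_self_comparison_not_significant(self):
        x = np.arange(10.0)
        assert mann_whitney_p(x, x) > 0.05

    def test_complete_separation_significant(self):
        assert mann_whitney_p(np.arange(1, 11), np.arange(101, 111)) < 0.05

    def test_identical_constant_samples_convention(self):
        assert mann_whitney_p([5.0] * 8, [5.0] * 8) == 1.0

    def test_matches_u_statistic_oracle(self):
        """Direct U computation with the normal approximation (tie-corrected)."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.normal(size=30)
            y = rng.normal(0.3, 1.2, size=35)
            u = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
            n, m = len(x), len(y)
            mu = n * m / 2
            sigma = math.sqrt(n * m * (n + m + 1) / 12)
            z = (u - mu - 0.5 * np.sign(u - mu)) / sigma  # continuity-corrected
            p_oracle = 2 * stats.norm.sf(abs(z))
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                         method="asymptotic").pvalue)
            assert p == pytest.approx(p_oracle, abs=1e-10)
            # the default route agrees with asymptotic for these sizes
            assert mann_whitney_p(x, y) == pytest.approx(p_oracle, rel=1e-6)


class TestGridSearchProtocol:
    @pytest.fixture(scope="class")
    def small_matrix(self, planted):
        matrix, _ = planted
        return matrix

    def test_one_point_grid_returns_that_point(self, small_matrix):
        spec = default_estimator_specs()["LR"]
        X = small_matrix.drop(columns=["Em"]).iloc[:60]
        y = small_matrix["Em"].iloc[:60]
        search = inner_grid_search(X, y, spec, seed=0, grid=LR_GRID)
        assert search.best_params_ == {"select__alpha": 10.0, "select__rho": 1.0}

    def test_argmin_contract(self, small_matrix):
        spec = default_estimator_specs()["LR"]
        X = small_matrix.drop(columns=["Em"]).iloc[:80]
        y = small_matrix["Em"].iloc[:80]
        grid = {"select__alpha": [10.0, 1e6], "select__rho": [1.0]}
        search = inner_grid_search(X, y, spec, seed=0, grid=grid)
        scores = search.cv_results_["mean_test_score"]
        best = scores[search.best_index_]
        assert all(best >= s for s in scores)
        assert search.best_params_["select__alpha"] == 10.0

    def test_selection_deterministic_across_reruns(self, small_matrix):
        spec = default_estimator_specs()["LR"]
        X = small_matrix.drop(columns=["Em"]).iloc[:60]
        y = small_matrix["Em"].iloc[:60]
        a = inner_grid_search(X, y, spec, seed=3, grid=LR_GRID).best_params_
        b = inner_grid_search(X, y, spec, seed=3, grid=LR_GRID).best_params_
        assert a == b


class TestRepeatedEvaluation:
    def test_repetition_count_and_determinism(self, planted):
        matrix, _ = planted
        spec = default_estimator_specs()["LR"]
        a = repeated_evaluation(matrix, spec, n_repeats=3, seed=5, grid=LR_GRID)
        b = repeated_evaluation(matrix, spec, n_repeats=3, seed=5, grid=LR_GRID)
        assert len(a.metrics) == 3
        pd.testing.assert_frame_equal(a.metrics, b.metrics, check_exact=True)
        assert a.seeds == b.seeds
        assert (a.metrics["RMSE"] >= a.metrics["MAE"]).all()

    def test_lr_approaches_gaussian_noise_floor(self, planted):
        """An ideal predictor's expected MAE under N(0, σ²) noise is √(2/π)σ."""
        matrix, truth = planted
        spec = default_estimator_specs()["LR"]
        res = repeated_evaluation(matrix, spec, n_repeats=3, seed=11, grid=LR_GRID)
        floor = math.sqrt(2 / math.pi) * truth.noise_sd
        assert 0.7 * floor <= res.metrics["MAE"].mean() <= 1.3 * floor

    def test_outer_kfold_protocol(self, planted):
        matrix, _ = planted
        spec = default_estimator_specs()["LR"]
        res = repeated_evaluation(matrix, spec, n_repeats=5, seed=1,
                                  grid=LR_GRID, protocol="outer-kfold")
        assert len(res.metrics) == 5


class TestRadiusScan:
    def test_small_grid_shape_and_argmin(self):
        records, _ = generate_record_set(14, seed=8)
        spec = default_estimator_specs()["LR"]
        mae, results = radius_scan(
            records, spec, grid_points=[(8, 3), (8, 5), (12, 3), (12, 5)],
            n_repeats=2, seed=0, param_grid=LR_GRID,
        )
        assert mae.shape == (2, 2)
        assert len(results) == 4
        r1, r2 = mae.attrs["argmin"]
        assert mae.loc[r1, r2] == mae.min().min()


class TestPairwiseComparison:
    def _result(self, name, values):
        return ExperimentResult(
            estimator=name, r1=None, r2=None,
            metrics=pd.DataFrame({"MAE": values}), chosen_params=[], seeds=[],
        )

    def test_matrix_properties(self):
        rng = np.random.default_rng(4)
        results = [self._result("A", rng.normal(40, 5, 10)),
                   self._result("B", rng.normal(41, 5, 10)),
                   self._result("C", rng.normal(80, 5, 10))]
        report = pairwise_model_comparison(results, "MAE")
        p = report.p_values
        assert (p.to_numpy() == p.to_numpy().T).all()
        assert (np.diag(p) == 1.0).all()
        assert report.significant.loc["A", "C"]
        assert not report.significant.loc["A", "A"]

    def test_unequal_repetitions_rejected(self):
        with pytest.raises(ValueError):
            pairwise_model_comparison(
                [self._result("A", [1.0] * 10), self._result("B", [1.0] * 9)]
            )

    def test_tidy_export_shape(self):
        results = [self._result("A", np.arange(10.0))]
        tidy = results_to_tidy(results)
        assert len(tidy) == 10  # one metric column here
        assert set(tidy.columns) == {"estimator", "r1", "r2", "repetition",
                                     "metric", "value"}
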