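"""Leakage-safe nested CV, confound residualization, permutations and FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from expobag import (
    PermutationConfig,
    PredictionCVSpec,
    confound_matrix,
    fdr_correct,
    permutation_test,
    remove_confounds,
    run_prediction,
    summarize_metrics,
)
from expobag.prediction import make_null_runner
from expobag.errors import DegenerateModelError, SchemaError
from tests.conftest import make_regression_frame


def bh_oracle(p):
    """Brute-force Benjamini-Hochberg step-up: q_i = min_{j>=rank(i)} p_(j) m/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    best = np.inf
    for pos in range(m - 1, -1, -1):
        best = min(best, p[order[pos]] * m / (pos + 1))
        q[order[pos]] = min(best, 1.0)
    return q


class TestRemoveConfounds:
    def test_confound_identical_variable_residuals_vanish(self):
        X, C = make_regression_frame(300, 2, seed=0)
        X["x0"] = C["age"]
        resid = remove_confounds(X, C, X.index, X.index)
        assert np.abs(resid["x0"]).max() < 1e-8

    def test_orthogonal_variable_nearly_unchanged(self):
        X, C = make_regression_frame(2000, 1, seed=1)
        resid = remove_confounds(X, C, X.index, X.index)
        assert np.corrcoef(resid["x0"], X["x0"])[0, 1] > 0.99

    def test_apply_rows_cannot_influence_coefficients(self):
        X, C = make_regression_frame(400, 3, seed=2)
        train = X.index[:300]
        apply = X.index[300:]
        r1 = remove_confounds(X, C, train, train)
        X_t = X.copy()
        X_t.loc[apply] = 1e6  # tamper apply rows only
        r2 = remove_confounds(X_t, C, train, train)
        assert np.array_equal(r1.to_numpy(), r2.to_numpy())

    def test_rank_deficient_confounds_raise(self):
        X, C = make_regression_frame(100, 2, seed=3)
        C["dup"] = C["age"]
        from expobag.errors import ConditioningError

        with pytest.raises(ConditioningError):
            remove_confounds(X, C, X.index, X.index)


class TestRunPrediction:
    def test_noiseless_linear_signal_recovered_by_ridge(self):
        X, C = make_regression_frame(800, 4, seed=4)
        y = pd.Series(3.0 * X["x1"].to_numpy(), index=X.index)
        cv = PredictionCVSpec(
            algorithm="ridge", outer_repeats=1, seed=0, param_grid={"alpha": [1e-6]}
        )
        run = run_prediction(X, y, C, cv)
        assert run.metric_means["pearson_r"] > 0.99

    def test_independent_target_gives_null_correlation(self):
        X, C = make_regression_frame(1000, 10, seed=3)
        rng = np.random.default_rng(3)
        y = pd.Series(rng.normal(size=1000), index=X.index)
        cv = PredictionCVSpec(algorithm="ridge", outer_repeats=1, seed=0)
        run = run_prediction(X, y, C, cv)
        assert abs(run.metric_means["pearson_r"]) < 0.1

    def test_rmse_squared_equals_mse_per_fold(self):
        X, C = make_regression_frame(200, 5, seed=5)
        y = pd.Series(X["x0"].to_numpy() + np.random.default_rng(5).normal(size=200), index=X.index)
        run = run_prediction(X, y, C, PredictionCVSpec(algorithm="ridge", outer_repeats=2, seed=1))
        fm = run.fold_metrics
        assert np.allclose(fm["rmse"] ** 2, fm["mse"], rtol=1e-12)
        assert (fm["rmse"] >= 0).all()

    def test_results_invariant_to_row_order(self):
        X, C = make_regression_frame(150, 4, seed=6)
        y = pd.Series(X["x0"].to_numpy() * 2, index=X.index)
        cv = PredictionCVSpec(algorithm="ridge", outer_repeats=1, seed=2)
        run1 = run_prediction(X, y, C, cv)
        perm = np.random.default_rng(0).permutation(len(X))
        run2 = run_prediction(X.iloc[perm], y.iloc[perm], C.iloc[perm], cv)
        pd.testing.assert_frame_equal(run1.fold_metrics, run2.fold_metrics)
        pd.testing.assert_frame_equal(run1.predictions, run2.predictions)

    def test_constant_target_raises(self):
        X, C = make_regression_frame(100, 3, seed=7)
        y = pd.Series(1.0, index=X.index)
        with pytest.raises(DegenerateModelError):
            run_prediction(X, y, C, PredictionCVSpec(algorithm="ridge"))

    def test_incomplete_cases_rejected(self):
        X, C = make_regression_frame(100, 3, seed=8)
        X.iloc[0, 0] = np.nan
        y = pd.Series(np.arange(100, dtype=float), index=X.index)
        with pytest.raises(SchemaError):
            run_prediction(X, y, C, PredictionCVSpec(algorithm="ridge"))


class TestPermutationTest:
    def _runner(self, n=120, seed=0):
        X, C = make_regression_frame(n, 5, seed=seed)
        cv = PredictionCVSpec(algorithm="ridge", param_grid={}, seed=seed)
        cfg = PermutationConfig(n_permutations=20, folds=5, seed=seed)
        return X, C, cv, cfg

    def test_observed_beats_all_nulls_floor(self):
        X, C, cv, cfg = self._runner()
        y = pd.Series(4.0 * X["x0"].to_numpy(), index=X.index)
        runner = make_null_runner(X, C, cv, cfg)
        obs = runner(y.to_numpy())
        p, nulls = permutation_test(runner, y, obs, cfg)
        assert p["pearson_r"] == pytest.approx(1 / 21)
        assert len(nulls) == 20

    def test_observed_worse_than_all_nulls_gives_one(self):
        X, C, cv, cfg = self._runner(seed=1)
        y = pd.Series(np.random.default_rng(1).normal(size=len(X)), index=X.index)
        runner = make_null_runner(X, C, cv, cfg)
        obs = {"pearson_r": -1.0, "mae": 1e9, "mse": 1e9, "rmse": 1e9, "r2": -1e9}
        p, _ = permutation_test(runner, y, obs, cfg)
        assert p["pearson_r"] == 1.0
        assert p["mae"] == 1.0

    def test_error_metrics_use_lower_tail(self):
        X, C, cv, cfg = self._runner(seed=2)
        y = pd.Series(4.0 * X["x1"].to_numpy() + 0.5, index=X.index)
        runner = make_null_runner(X, C, cv, cfg)
        obs = runner(y.to_numpy())
        p, _ = permutation_test(runner, y, obs, cfg)
        # a strong signal is significant under both the fit and error metrics
        assert p["mae"] == pytest.approx(1 / 21)
        assert p["rmse"] == pytest.approx(1 / 21)


class TestFdrCorrect:
    def test_single_p_unchanged(self):
        assert fdr_correct([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        q = fdr_correct([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.random(rng.integers(1, 21))
            assert np.allclose(fdr_correct(p), bh_oracle(p), rtol=0, atol=0)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_oracle_equivalence_property(self, p):
        q = fdr_correct(p)
        assert np.allclose(q, bh_oracle(p), rtol=0, atol=0)
        # monotone non-decreasing in p-rank
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.5])
        with pytest.raises(ValueError):
            fdr_correct([np.nan])


def test_summarize_metrics_includes_p_and_q():
    X, C = make_regression_frame(150, 4, seed=9)
    y = pd.Series(2.0 * X["x0"].to_numpy() + np.random.default_rng(9).normal(size=150), index=X.index)
    run = run_prediction(X, y, C, PredictionCVSpec(algorithm="ridge", outer_repeats=1, seed=0))
    table = summarize_metrics(run, {"pearson_r": 0.01, "mae": 0.02, "mse": 0.03, "rmse": 0.04, "r2": 0.05})
    assert set(table.index) == {"mae", "mse", "rmse", "r2", "pearson_r"}
    assert (table["q"] >= table["p"] - 1e-12).all()


def test_confound_matrix_schema(small_cohort):
    bundle, _, _ = small_cohort
    C = confound_matrix(bundle.participants)
    assert list(C.columns) == ["age", "age_squared", "sex", "height", "volumetric_scaling"]
    assert np.array_equal(C["age_squared"].to_numpy(), C["age"].to_numpy() ** 2)
    with pytest.raises(SchemaError):
        confound_matrix(bundle.participants.drop(columns="height"))


def test_fdr_agrees_with_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(5)
    for _ in range(100):
        p = rng.random(rng.integers(1, 30))
        assert np.allclose(fdr_correct(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)
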