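import math

import joblib
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from deltaboost import synthetic
from deltaboost.brt import (
    ComponentFit,
    FitError,
    deviance,
    fit_component,
    fit_delta,
    grid_search_component,
    null_deviance,
    persist,
    predict_combined,
    restore,
    select_best,
    simplify,
    smearing_factor,
)
from deltaboost.core_data import BrtConfig, SampleTable, ValidationError


def _frame(n, seed, p=3):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {f"x{i + 1}": rng.uniform(-1, 1, n) for i in range(p)}
    )


class TestSmearing:
    def test_zero_residuals_give_unit_factor(self):
        assert smearing_factor([0.0, 0.0, 0.0]) == 1.0

    def test_hand_computed_example(self):
        assert smearing_factor([math.log(2), math.log(0.5)]) == pytest.approx(1.25)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            smearing_factor([])

    @given(st.lists(st.floats(min_value=-5, max_value=5), min_size=1, max_size=100))
    @settings(deadline=None, max_examples=200)
    def test_matches_independent_mean_of_exponentials(self, residuals):
        # oracle: plain-python sum of math.exp, no numpy
        oracle = sum(math.exp(r) for r in residuals) / len(residuals)
        assert smearing_factor(residuals) == pytest.approx(oracle, rel=1e-12)

    def test_lognormal_closed_form(self):
        sigma = 0.8
        rng = np.random.default_rng(0)
        r = rng.normal(0, sigma, 100_000)
        assert smearing_factor(r) == pytest.approx(math.exp(sigma**2 / 2), rel=0.01)


class TestFitComponent:
    def test_separable_binary_reaches_perfect_auc(self):
        X = _frame(120, 0, p=1)
        y = (X["x1"] > 0).astype(int).to_numpy()
        fit = fit_component(X, y, "bernoulli", tc=1, lr=0.1, bf=1.0, cv_folds=4, seed=0)
        assert fit.train_metric == 1.0

    def test_constant_response_flagged_degenerate(self):
        X = _frame(60, 1)
        fit = fit_component(X, np.full(60, 3.0), "gaussian", tc=2, lr=0.1, bf=1.0,
                            cv_folds=3, seed=1)
        assert fit.degenerate

    def test_cv_deviance_beats_intercept_only_null(self):
        X = _frame(500, 2, p=2)
        rng = np.random.default_rng(2)
        y = np.sin(3 * X["x1"].to_numpy()) + 0.2 * rng.standard_normal(500)
        fit = fit_component(X, y, "gaussian", tc=2, lr=0.05, bf=0.8, cv_folds=5, seed=2)
        assert fit.cv_deviance_mean < null_deviance("gaussian", y)

    def test_too_few_cases_per_class_raises(self):
        X = _frame(30, 3)
        y = np.zeros(30)
        y[:2] = 1  # 2 positives < 5 folds
        with pytest.raises(FitError, match="stratification"):
            fit_component(X, y, "bernoulli", tc=1, lr=0.1, bf=1.0, cv_folds=5, seed=3)

    def test_poisson_family_fits_counts(self):
        X = _frame(300, 4, p=2)
        rng = np.random.default_rng(4)
        y = rng.poisson(np.exp(0.5 + X["x1"].to_numpy()))
        fit = fit_component(X, y.astype(float), "poisson", tc=2, lr=0.1, bf=1.0,
                            cv_folds=3, seed=4)
        assert fit.cv_deviance_mean < null_deviance("poisson", y.astype(float))

    def test_unknown_family_rejected(self):
        X = _frame(30, 5)
        with pytest.raises(ValidationError):
            fit_component(X, np.zeros(30), "tweedie", tc=1, lr=0.1, bf=1.0,
                          cv_folds=2, seed=5)


def _stub(cv, trees, tc, lr, bf=0.5):
    return ComponentFit(
        family="gaussian", tc=tc, lr=lr, bf=bf, n_trees=trees,
        cv_deviance_mean=cv, cv_deviance_se=0.1, train_metric=0.5,
        kept_expvars=["x1"], ensemble=None,
    )


class TestSelection:
    def test_minimal_cv_deviance_wins(self):
        fits = [_stub(1.0, 100, 2, 0.01), _stub(0.8, 400, 13, 0.005)]
        assert select_best(fits).cv_deviance_mean == 0.8

    def test_tie_broken_by_fewer_trees_then_tc_then_lr(self):
        a, b = _stub(1.0, 300, 5, 0.01), _stub(1.0, 500, 2, 0.001)
        assert select_best([a, b]).n_trees == 300
        c, d = _stub(1.0, 300, 2, 0.01), _stub(1.0, 300, 5, 0.001)
        assert select_best([c, d]).tc == 2
        e, f = _stub(1.0, 300, 2, 0.005), _stub(1.0, 300, 2, 0.01)
        assert select_best([e, f]).lr == 0.005

    def test_selection_invariant_to_candidate_order(self):
        X = _frame(150, 6, p=2)
        rng = np.random.default_rng(6)
        y = X["x1"].to_numpy() + 0.3 * rng.standard_normal(150)
        cfg_fwd = BrtConfig(tc_candidates=[1, 2], lr_candidates=[0.1, 0.05],
                            bf_candidates=[0.8], cv_folds=3, seed=6)
        cfg_rev = BrtConfig(tc_candidates=[2, 1], lr_candidates=[0.05, 0.1],
                            bf_candidates=[0.8], cv_folds=3, seed=6)
        best_fwd, all_fwd = grid_search_component(X, y, "gaussian", cfg_fwd)
        best_rev, all_rev = grid_search_component(X, y, "gaussian", cfg_rev)
        assert len(all_fwd) == len(all_rev) == 4
        assert (best_fwd.tc, best_fwd.lr, best_fwd.bf) == (best_rev.tc, best_rev.lr, best_rev.bf)

    def test_single_candidate_selected_without_comparison(self):
        X = _frame(100, 7, p=1)
        y = X["x1"].to_numpy()
        cfg = BrtConfig(tc_candidates=[1], lr_candidates=[0.1], bf_candidates=[1.0],
                        cv_folds=3, seed=7)
        best, fits = grid_search_component(X, y, "gaussian", cfg)
        assert len(fits) == 1 and best is fits[0]


class TestSimplify:
    def test_pure_noise_variable_dropped_in_most_seeds(self):
        dropped = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            X = _frame(300, seed, p=3)
            y = (
                np.sin(2 * X["x1"].to_numpy())
                + X["x2"].to_numpy() ** 2
                + 0.3 * rng.standard_normal(300)
            )
            cfg = BrtConfig(tc_candidates=[2], lr_candidates=[0.1],
                            bf_candidates=[0.8], cv_folds=3, seed=seed)
            fit = fit_component(X, y, "gaussian", 2, 0.1, 0.8, cv_folds=3, seed=seed)
            simp = simplify(fit, X, y, cfg)
            if "x3" not in simp.kept_expvars and {"x1", "x2"} <= set(simp.kept_expvars):
                dropped += 1
        assert dropped >= 0.8 * n_seeds

    def test_single_variable_model_unchanged(self):
        X = _frame(100, 8, p=1)
        y = X["x1"].to_numpy()
        cfg = BrtConfig(cv_folds=3, seed=8)
        fit = fit_component(X, y, "gaussian", 1, 0.1, 1.0, cv_folds=3, seed=8)
        assert simplify(fit, X, y, cfg) is fit

    def test_essential_variables_never_removed(self):
        X = _frame(400, 9, p=2)
        y = X["x1"].to_numpy() + X["x2"].to_numpy()  # both essential, no noise
        cfg = BrtConfig(cv_folds=3, seed=9)
        fit = fit_component(X, y, "gaussian", 2, 0.1, 0.8, cv_folds=3, seed=9)
        simp = simplify(fit, X, y, cfg)
        assert set(simp.kept_expvars) == {"x1", "x2"}


class TestPredictCombined:
    def test_combined_is_exact_product(self, fitted_delta, prediction_surface):
        df = prediction_surface.df
        np.testing.assert_allclose(
            df["combined_index"],
            df["p_occurrence"] * df["positive_abundance"],
            rtol=1e-12,
        )
        assert (df["combined_index"] >= 0).all()

    def test_missing_expvar_cell_predicts_missing(self, fitted_delta, small_landscape):
        grid, _ = small_landscape
        g2 = grid.df.copy()
        g2.loc[0, "depth"] = np.nan
        from deltaboost.core_data import GridTable

        surf = predict_combined(fitted_delta.model, GridTable(df=g2, expvars=grid.expvars))
        assert np.isnan(surf.df.loc[0, "combined_index"])
        assert not surf.df["combined_index"].iloc[1:].isna().any()

    def test_missing_expvar_column_rejected(self, fitted_delta, small_landscape):
        grid, _ = small_landscape
        from deltaboost.core_data import GridTable

        bad = GridTable(df=grid.df.drop(columns=["depth"]),
                        expvars=[v for v in grid.expvars if v != "depth"])
        with pytest.raises(ValidationError, match="depth"):
            predict_combined(fitted_delta.model, bad)

    def test_single_family_run_reports_unit_occurrence(self, small_landscape):
        grid, truth = small_landscape
        truth2 = synthetic.TruthModel(
            expvars=truth.expvars, occ_intercept=20.0,
            occ_coef={v: 0.0 for v in truth.expvars},
            abn_intercept=truth.abn_intercept, abn_coef=truth.abn_coef,
            log_sd=0.3, seed=truth.seed,
        )
        samples = synthetic.gen_survey(grid, truth2, 200, seed=5)
        cfg = BrtConfig(tc_candidates=[2], lr_candidates=[0.05], bf_candidates=[0.8],
                        cv_folds=3, seed=5, simplify=False, zi=False)
        result = fit_delta(samples, "cpue", cfg)
        assert result.model.gaussian is None
        assert result.model.smearing_factor is None
        surf = predict_combined(result.model, grid)
        assert (surf.df["p_occurrence"] == 1).all()
        np.testing.assert_allclose(
            surf.df["combined_index"], surf.df["positive_abundance"], rtol=1e-12
        )


class TestPersistence:
    def test_round_trip_predictions_identical(self, fitted_delta, small_landscape, tmp_path):
        grid, _ = small_landscape
        path = tmp_path / "model.joblib"
        persist(fitted_delta.model, path)
        restored = restore(path)
        a = predict_combined(fitted_delta.model, grid).df
        b = predict_combined(restored, grid).df
        assert a.equals(b)

    def test_corrupt_file_raises(self, tmp_path):
        path = tmp_path / "bad.joblib"
        path.write_bytes(b"not a model at all")
        with pytest.raises(FitError):
            restore(path)

    def test_newer_schema_rejected(self, tmp_path):
        path = tmp_path / "future.joblib"
        joblib.dump({"schema_version": 99, "model": None}, path)
        with pytest.raises(FitError, match="version"):
            restore(path)


class TestDeterminism:
    def test_fit_predict_reproducible_from_seed(self, small_survey, small_landscape,
                                                fast_config):
        grid, _ = small_landscape
        a = predict_combined(fit_delta(small_survey, "cpue", fast_config).model, grid)
        b = predict_combined(fit_delta(small_survey, "cpue", fast_config).model, grid)
        assert a.df.equals(b.df)
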