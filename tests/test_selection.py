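"""Tests for the LOOCV engine, PRESS-guided elimination and final models."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import streetshare as ss
from streetshare.regression import design_matrix
from streetshare.selection import prepare_model_frame

from conftest import make_beta_data


def random_linear_data(seed, n=20, p=2):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = 0.5 + X @ beta + rng.normal(0, 0.4, n)
    df = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])
    df["y"] = y
    return df


class TestLoocv:
    def test_perfect_linear_model_has_zero_press(self):
        data = pd.DataFrame({"x": np.arange(10.0)})
        data["y"] = 3.0 + 2.0 * data["x"]
        cv = ss.loocv(ss.ModelSpec("y", [("x", "identity")], "ols"), data)
        assert cv.press == pytest.approx(0.0, abs=1e-16)
        assert cv.mae == pytest.approx(0.0, abs=1e-9)

    def test_press_matches_hat_matrix_identity_for_ols(self):
        # closed-form oracle: PRESS = sum((e_i / (1 - h_ii))^2)
        for seed in range(20):
            data = random_linear_data(seed)
            spec = ss.ModelSpec("y", [("x0", "identity"), ("x1", "identity")], "ols")
            cv = ss.loocv(spec, data)
            fit = ss.fit_ols(spec, data)
            X = design_matrix(spec, data)
            h = np.diag(X @ np.linalg.inv(X.T @ X) @ X.T)
            press_closed = float(np.sum((fit.residuals / (1 - h)) ** 2))
            assert cv.press == pytest.approx(press_closed, rel=1e-9)

    def test_matches_naive_refit_loop_for_beta(self):
        data = make_beta_data(17, n=15)
        spec = ss.ModelSpec("y", [("x", "identity")], "beta")
        cv = ss.loocv(spec, data)
        press = 0.0
        for i in data.index:
            fit = ss.fit_beta(spec, data.drop(index=i))
            pred = float(ss.predict(fit, data.loc[[i]])[0])
            press += (data.loc[i, "y"] - pred) ** 2
        assert cv.press == pytest.approx(press, rel=1e-10)
        assert len(cv.predictions) == len(data)

    def test_summaries_nonnegative_and_counted(self):
        data = make_beta_data(23, n=12)
        cv = ss.loocv(ss.ModelSpec("y", [("x", "identity")], "beta"), data)
        assert cv.mae >= 0 and cv.mdae >= 0
        assert cv.mse_std is not None and cv.mse_std > 0
        assert len(cv.observed) == len(data)

    def test_too_few_cities_rejected(self):
        data = make_beta_data(1, n=2)
        with pytest.raises(ValueError, match="at least 3"):
            ss.loocv(ss.ModelSpec("y", [("x", "identity")], "beta"), data)


class TestCorrelationMatrix:
    def test_unit_diagonal_and_symmetry(self):
        data = random_linear_data(3, n=30, p=3)
        corr = ss.correlation_matrix(data)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)

    def test_exact_negatives(self):
        data = pd.DataFrame({"a": [1.0, 2, 3], "b": [-1.0, -2, -3]})
        corr = ss.correlation_matrix(data)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_zero_variance_column_is_missing(self):
        data = pd.DataFrame({"a": [1.0, 2, 3], "c": [5.0, 5, 5]})
        corr = ss.correlation_matrix(data)
        assert np.isnan(corr.loc["c", "a"])
        assert np.isnan(corr.loc["c", "c"])

    def test_pairwise_complete_with_missing_block(self):
        data = pd.DataFrame(
            {"a": [1.0, 2, 3, 4, 5], "b": [2.0, 4, 6, 8, np.nan]}
        )
        corr = ss.correlation_matrix(data)
        assert corr.loc["a", "b"] == pytest.approx(1.0)


class TestMaximalSpec:
    def test_single_informative_feature(self):
        rng = np.random.default_rng(0)
        n = 40
        f = rng.normal(size=n)
        data = pd.DataFrame({
            "f": f, "noise": rng.normal(size=n),
            "y": expit(-1 + 1.5 * f + rng.normal(0, 0.05, n)),
        })
        # force the uninformative feature to be essentially uncorrelated
        data["noise"] -= np.polyval(np.polyfit(data["y"], data["noise"], 1), data["y"])
        spec = ss.build_maximal_spec("y", data, ["f", "noise"], family="beta")
        assert [c for c, _ in spec.predictors] == ["f"]

    def test_all_zero_correlations_gives_intercept_only(self):
        data = pd.DataFrame({"y": [0.1, 0.2, 0.3, 0.4], "f": [1.0, 1, 1, 1]})
        with pytest.warns(UserWarning, match="intercept-only"):
            spec = ss.build_maximal_spec("y", data, ["f"], family="beta")
        assert spec.predictors == ()

    def test_months_enter_via_gsv_correlation(self):
        rng = np.random.default_rng(5)
        n = 40
        f = rng.normal(size=n)
        month = f * 2 + rng.normal(0, 0.1, n)  # correlated with the feature
        data = pd.DataFrame({
            "f": f, "GSV_Jun": month,
            "y": expit(-1 + f + rng.normal(0, 0.1, n)),
        })
        spec = ss.build_maximal_spec("y", data, ["f"], month_columns=["GSV_Jun"])
        assert ("GSV_Jun", "identity") in spec.predictors

    def test_planted_structure_always_found(self):
        # cycle-share outcome driven by the cyclist feature alone
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 30
            cyc = rng.gamma(2, 10, n)
            other = rng.normal(size=n)
            data = pd.DataFrame({
                "GSV_Cycle": cyc, "GSV_MC": other,
                "y": expit(-3 + 0.05 * cyc + rng.normal(0, 0.2, n)),
            })
            spec = ss.build_maximal_spec("y", data, ["GSV_Cycle", "GSV_MC"])
            assert ("GSV_Cycle", "identity") in spec.predictors


class TestSequentialElimination:
    def test_pure_noise_predictor_removed(self):
        removed = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 60
            f = rng.gamma(2, 10, n)
            noise = rng.normal(size=n)
            mu = expit(-3 + 0.05 * f)
            phi = 80.0
            y = np.clip(rng.beta(mu * phi, (1 - mu) * phi), 1e-5, 1 - 1e-5)
            data = pd.DataFrame({"y": y, "f": f, "noise": noise})
            maximal = ss.ModelSpec(
                "y", [("f", "identity"), ("noise", "identity")], "beta"
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                trace = ss.sequential_elimination(maximal, data)
            if [c for c, _ in trace.final.predictors] == ["f"]:
                removed += 1
        assert removed >= 18

    def test_press_optimal_maximal_model_is_kept(self):
        data = pd.DataFrame({"x": np.arange(12.0)})
        data["y"] = 0.1 + 0.9 * data["x"]  # x indispensable
        maximal = ss.ModelSpec("y", [("x", "identity")], "ols")
        trace = ss.sequential_elimination(maximal, data)
        assert trace.final == maximal
        assert trace.accepted_steps() == []

    def test_accepted_steps_strictly_reduce_press(self):
        data = make_beta_data(31, n=25)
        rng = np.random.default_rng(1031)
        data["junk1"] = rng.normal(size=len(data))
        data["junk2"] = rng.normal(size=len(data))
        maximal = ss.ModelSpec(
            "y", [("x", "identity"), ("junk1", "identity"), ("junk2", "identity")],
            "beta",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            trace = ss.sequential_elimination(maximal, data)
        for step in trace.accepted_steps():
            assert step["press_after"] < step["press_before"]
        if trace.accepted_steps():
            assert trace.final_press <= min(
                s["press_before"] for s in trace.accepted_steps()
            )


class TestFinalModels:
    def test_all_models_converge_on_synthetic_world(self, small_world, small_features):
        table = small_features.join(small_world.outcomes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = ss.fit_final_models(table)
        assert len(report) == 10
        assert report["converged"].all()
        assert (report["PRESS"] >= 0).all()
        beta_rows = report[report["family"] == "beta"]
        assert beta_rows["MSR"].notna().all()

    def test_census_only_table_restricts_to_first_four(self, small_world, small_features):
        table = small_features.join(small_world.outcomes)
        table = table.drop(columns=[c for c in table.columns if c.startswith("APS_")])
        with pytest.warns(UserWarning, match="missing columns"):
            report = ss.fit_final_models(table)
        assert list(report.index) == [1, 2, 3, 4]

    def test_percent_outcomes_are_rescaled(self, small_world, small_features):
        table = small_features.join(small_world.outcomes)
        frame = prepare_model_frame(ss.FINAL_MODEL_SPECS[2], table)
        assert frame["Census_Cycle"].max() < 1.0
        # month predictors stay on the percent scale
        frame1 = prepare_model_frame(ss.FINAL_MODEL_SPECS[1], table)
        assert frame1["GSV_Mar"].max() > 1.0

    def test_reproduce_study_bundle(self, small_world, small_features):
        table = small_features.join(small_world.outcomes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            arts = ss.reproduce_study(table)
        assert {"correlations", "table2", "model2_cv"} <= set(arts)
        corr = arts["correlations"]
        assert corr.loc["GSV_Cycle", "Census_Cycle"] > 0.3
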