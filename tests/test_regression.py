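import json

import numpy as np
import pandas as pd
import pytest

from thc_correct.core_io import ValidationError
from thc_correct.datasets import LabelSet
from thc_correct.features import SCS_COLUMNS
from thc_correct.regression import (RegressionModel, cross_validate,
                                    fit_krr_dual, fit_linear, metrics,
                                    pct_improvement, rbf_kernel, round_pct,
                                    train_model, tune_hyperparameters)
from thc_correct.synthetic import generate_planted_regression


def frame(X, prefix="x"):
    return pd.DataFrame(X, columns=[f"{prefix}{k}" for k in range(X.shape[1])])


class TestFitLinear:
    def test_noiseless_recovery(self):
        X, y, truth = generate_planted_regression(50, 5, seed=0)
        coef, icpt = fit_linear(X, y, intercept=True)
        assert np.allclose(coef, truth.c_true, atol=1e-10)
        assert icpt == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        coef, _ = fit_linear(X, y, intercept=False)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(coef, oracle, atol=1e-10)

    def test_underdetermined_is_an_error(self):
        with pytest.raises(ValidationError):
            fit_linear(np.ones((3, 5)), np.ones(3))

    def test_rank_deficient_warns(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        X = np.hstack([X, X[:, :1]])  # duplicated column
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit_linear(X, rng.normal(size=20), intercept=False)


class TestKRR:
    def test_zero_ridge_interpolates_training_data(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(15, 3))
        y = rng.normal(size=15)
        w = fit_krr_dual(X, y, alpha=0.0, gamma=0.7)
        yhat = rbf_kernel(X, X, 0.7) @ w
        assert np.allclose(yhat, y, atol=1e-8)

    def test_dual_weights_match_closed_form_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        alpha, gamma = 1e-3, 0.5
        w = fit_krr_dual(X, y, alpha, gamma)
        K = np.exp(-gamma * ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        oracle = np.linalg.solve(K + alpha * np.eye(20), y)
        assert np.allclose(w, oracle, atol=1e-10)

    def test_matches_sklearn_kernel_ridge(self):
        kr = pytest.importorskip("sklearn.kernel_ridge")
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        Xnew = rng.normal(size=(8, 3))
        model = train_model("krr", frame(X), y, alpha=1e-2, gamma=0.3)
        ours = model.predict(frame(Xnew))
        # oracle operates in the same scaled space our model trains in
        Xs = model.feature_scaler.transform(frame(X)).to_numpy()
        Xns = model.feature_scaler.transform(frame(Xnew)).to_numpy()
        ys = model.label_scaler.transform_vector(y)
        ref = kr.KernelRidge(alpha=1e-2, gamma=0.3, kernel="rbf").fit(Xs, ys)
        theirs = model.label_scaler.inverse_transform_vector(ref.predict(Xns))
        assert np.allclose(ours, theirs, atol=1e-8)

    def test_infinite_ridge_predicts_training_mean(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 3))
        y = rng.normal(5.0, 2.0, size=30)
        model = train_model("krr", frame(X), y, alpha=1e9, gamma=0.1)
        pred = model.predict(frame(rng.normal(size=(5, 3))))
        assert np.allclose(pred, y.mean(), rtol=1e-6)


class TestMetrics:
    def test_perfect_prediction_is_zero(self):
        y = np.array([1.0, -2.0, 3.0])
        assert metrics(y, y) == (0.0, 0.0, 0.0)

    def test_arithmetic_on_definition(self):
        rmse, mae, mape = metrics(np.array([1.0, 2.0]), np.array([2.0, 4.0]))
        assert rmse == pytest.approx(np.sqrt(2.5))
        assert mae == pytest.approx(1.5)
        assert mape == pytest.approx(100.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        y, yhat = rng.normal(size=30) + 3, rng.normal(size=30)
        rmse, mae, mape = metrics(y, yhat)
        se = [(a - b) ** 2 for a, b in zip(y, yhat)]
        ae = [abs(a - b) for a, b in zip(y, yhat)]
        pe = [100 * abs((a - b) / a) for a, b in zip(y, yhat)]
        assert rmse == pytest.approx(np.sqrt(np.mean(se)), abs=1e-13)
        assert mae == pytest.approx(np.mean(ae), abs=1e-13)
        assert mape == pytest.approx(np.mean(pe), abs=1e-11)

    def test_zero_labels_excluded_from_mape(self):
        y = np.array([0.0, 2.0])
        yhat = np.array([1.0, 1.0])
        _, _, mape = metrics(y, yhat)
        assert mape == pytest.approx(50.0)


class TestPctImprovement:
    def test_printed_table_values(self):
        # improvement percentages recomputed from published error pairs
        assert round_pct(pct_improvement(0.1337, 0.0517)) == 61
        assert pct_improvement(0.1337, 0.0517) == pytest.approx(61.33, abs=0.01)
        assert round_pct(pct_improvement(0.1337, 0.0292)) == 78
        assert pct_improvement(0.1337, 0.0292) == pytest.approx(78.16, abs=0.01)

    def test_equal_inputs_give_zero(self):
        assert pct_improvement(1.0, 1.0) == 0.0

    def test_nonpositive_baseline_is_an_error(self):
        with pytest.raises(ValidationError):
            pct_improvement(0.0, 1.0)

    def test_rounding_half_away_from_zero(self):
        assert round_pct(61.5) == 62
        assert round_pct(-61.5) == -62
        assert round_pct(61.33) == 61


class TestScsMode:
    def test_component_sum_label_recovers_unit_coefficients(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 10))
        feats = pd.DataFrame(X, columns=list(SCS_COLUMNS))
        y = X.sum(axis=1)
        model = train_model("scs", feats, y, baseline=np.zeros(60))
        assert np.allclose(model.coef, np.ones(10), atol=1e-10)

    def test_prediction_adds_baseline(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 10))
        feats = pd.DataFrame(X, columns=list(SCS_COLUMNS))
        base = rng.normal(size=40)
        y = base + X @ np.full(10, 0.25)
        model = train_model("scs", feats, y, baseline=base)
        pred = model.predict(feats, baseline=base)
        assert np.allclose(pred, y, atol=1e-8)


class TestTuning:
    def test_single_point_grid_returns_that_point(self):
        X, y, _ = generate_planted_regression(40, 3, seed=0, sigma=0.1)
        a, g, trace = tune_hyperparameters(frame(X), y, grid_alpha=[1e-2],
                                           grid_gamma=[1e-1], k=5, seed=0)
        assert (a, g) == (1e-2, 1e-1)
        assert len(trace) == 1

    def test_refinement_never_degrades_grid_optimum(self):
        X, y, _ = generate_planted_regression(50, 4, seed=1, amplitude=2.0,
                                              bandwidth=1.0, sigma=0.05)
        a, g, trace = tune_hyperparameters(frame(X), y,
                                           grid_alpha=[1e-4, 1e-2, 1.0],
                                           grid_gamma=[1e-2, 1e-1, 1.0],
                                           k=5, seed=0)
        grid_best = trace[trace.stage == "grid"]["cv_rmse"].min()
        final = trace["cv_rmse"].min()
        assert final <= grid_best + 1e-12

    def test_bandwidth_recovered_within_one_decade(self):
        # planted RBF bump with known inverse length scale
        hits = 0
        for seed in range(10):
            bw = 0.8
            gamma_true = 1.0 / (2 * bw**2)
            X, y, _ = generate_planted_regression(
                80, 2, seed=seed, c_scale=0.0, amplitude=3.0,
                bandwidth=bw, sigma=0.05)
            _, g, _ = tune_hyperparameters(
                frame(X), y, grid_alpha=10.0 ** np.arange(-8, 1.0),
                grid_gamma=10.0 ** np.arange(-4, 2.0), k=5, seed=seed)
            if 0.1 * gamma_true <= g <= 10 * gamma_true:
                hits += 1
        assert hits >= 8


def make_label_set(y, kind="delta_molecule"):
    ids = [f"s{i}" for i in range(len(y))]
    return LabelSet(kind, pd.DataFrame({"id": ids, "y": y}))


class TestCrossValidate:
    def test_bookkeeping_matches_manual_recomputation(self):
        X, y, _ = generate_planted_regression(50, 4, seed=2, sigma=0.3)
        feats = frame(X)
        feats.index = [f"s{i}" for i in range(50)]
        labels = make_label_set(y)
        report = cross_validate(feats, labels, np.zeros(50), "mlr", k=5, seed=0)
        for j, sub in report.predictions.groupby("fold"):
            rmse = np.sqrt(np.mean((sub["y"] - sub["yhat"]) ** 2))
            assert report.per_fold.loc[j, "rmse"] == pytest.approx(rmse, abs=1e-12)
        mean = report.per_fold["rmse"].mean()
        assert report.model_metrics["rmse"]["mean"] == pytest.approx(mean, abs=1e-12)

    def test_same_seed_gives_identical_report(self):
        X, y, _ = generate_planted_regression(40, 3, seed=3, sigma=0.2)
        feats = frame(X)
        feats.index = [f"s{i}" for i in range(40)]
        labels = make_label_set(y)
        r1 = cross_validate(feats, labels, np.zeros(40), "krr", k=5, seed=4,
                            alpha=1e-3, gamma=0.1)
        r2 = cross_validate(feats, labels, np.zeros(40), "krr", k=5, seed=4,
                            alpha=1e-3, gamma=0.1)
        assert r1.to_dict() == r2.to_dict()

    def test_zero_labels_zero_model_reports_zero_baseline(self):
        feats = frame(np.random.default_rng(0).normal(size=(20, 3)))
        feats.index = [f"s{i}" for i in range(20)]
        labels = make_label_set(np.zeros(20))
        report = cross_validate(feats, labels, np.zeros(20), "mlr", k=5, seed=0)
        assert report.baseline_metrics["rmse"]["mean"] == 0.0
        assert report.to_dict()["pct_imp"]["rmse"] is None  # degenerate case flagged

    def test_scaler_never_sees_test_rows(self):
        # shuffling the held-out rows must not change test predictions
        X, y, _ = generate_planted_regression(40, 3, seed=5, sigma=0.1)
        feats = frame(X)
        feats.index = [f"s{i}" for i in range(40)]
        labels = make_label_set(y)
        r1 = cross_validate(feats, labels, np.zeros(40), "mlr", k=4, seed=1)
        # perturbing a test row's features changes only that row's prediction
        fold0_test = r1.predictions[r1.predictions["fold"] == 0]["id"].iloc[0]
        feats2 = feats.copy()
        feats2.loc[fold0_test] += 100.0
        r2 = cross_validate(feats2, labels, np.zeros(40), "mlr", k=4, seed=1)
        p1 = r1.predictions.set_index("id")["yhat"]
        p2 = r2.predictions.set_index("id")["yhat"]
        others_fold0 = [i for i in p1.index
                        if i != fold0_test
                        and r1.predictions.set_index("id")["fold"][i] == 0]
        assert np.allclose(p1[others_fold0], p2[others_fold0])
        assert p1[fold0_test] != p2[fold0_test]


class TestModelSerialization:
    @pytest.mark.parametrize("kind", ["scs", "mlr", "krr"])
    def test_predictions_bit_reproducible_from_file(self, tmp_path, kind):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 10))
        cols = list(SCS_COLUMNS) if kind == "scs" else [f"x{k}" for k in range(10)]
        feats = pd.DataFrame(X, columns=cols)
        y = rng.normal(size=30)
        base = np.zeros(30) if kind == "scs" else None
        model = train_model(kind, feats, y, baseline=base, alpha=1e-2, gamma=0.1)
        path = tmp_path / "m.json"
        model.save(path)
        loaded = RegressionModel.load(path)
        Xnew = pd.DataFrame(rng.normal(size=(7, 10)), columns=cols)
        bnew = np.zeros(7) if kind == "scs" else None
        assert np.array_equal(model.predict(Xnew, baseline=bnew),
                              loaded.predict(Xnew, baseline=bnew))

    def test_model_json_is_versioned(self, tmp_path):
        rng = np.random.default_rng(1)
        feats = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        model = train_model("mlr", feats, rng.normal(size=20))
        model.save(tmp_path / "m.json")
        with open(tmp_path / "m.json") as fh:
            d = json.load(fh)
        assert d["format_version"].startswith("thc-correct-model/")


class TestModelFamilyBehaviour:
    def test_quasi_linear_krr_approaches_mlr_on_planted_linear_data(self):
        X, y, _ = generate_planted_regression(80, 4, seed=6, sigma=0.05)
        feats = frame(X)
        feats.index = [f"s{i}" for i in range(80)]
        labels = make_label_set(y)
        mlr = cross_validate(feats, labels, np.zeros(80), "mlr", k=5, seed=0)
        krr = cross_validate(feats, labels, np.zeros(80), "krr", k=5, seed=0,
                             alpha=1e-6, gamma=1e-4)
        r_mlr = mlr.model_metrics["rmse"]["mean"]
        r_krr = krr.model_metrics["rmse"]["mean"]
        assert r_krr <= 1.1 * r_mlr

    def test_planted_nonlinearity_orders_model_families(self):
        # intercept defeats scs, Gaussian bump defeats mlr: scs >= mlr >= krr
        wins = 0
        for seed in range(10):
            X, y, _ = generate_planted_regression(
                90, 4, seed=seed, intercept=3.0, amplitude=4.0,
                bandwidth=1.2, sigma=0.05)
            feats = pd.DataFrame(X, columns=list(SCS_COLUMNS)[:4])
            feats.index = [f"s{i}" for i in range(90)]
            labels = make_label_set(y)
            rmse = {}
            for kind in ("mlr", "krr"):
                rep = cross_validate(feats, labels, np.zeros(90), kind,
                                     k=5, seed=seed, alpha=1e-3, gamma=0.1)
                rmse[kind] = rep.model_metrics["rmse"]["mean"]
            # scs: zero-intercept linear on the same columns
            from thc_correct.datasets import make_folds

            folds = make_folds(90, 5, seed)
            errs = []
            for j in range(5):
                tr, te = folds.train_indices(j), folds.test_indices(j)
                coef, _ = fit_linear(X[tr], y[tr], intercept=False)
                errs.append(np.sqrt(np.mean((y[te] - X[te] @ coef) ** 2)))
            rmse["scs"] = np.mean(errs)
            if rmse["scs"] >= rmse["mlr"] >= rmse["krr"]:
                wins += 1
        assert wins >= 8
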