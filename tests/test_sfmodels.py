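import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.preprocessing import StandardScaler

from poseforge import sfmodels
from poseforge._mars import MarsRegressor
from poseforge.sfmodels import (
    fit,
    load_model,
    predict,
    rank_poses,
    save_model,
    table1_params,
    tune,
)

from conftest import split_by_complex


def _table(X, y_rmsd, y_ba=None, family="R"):
    n, p = X.shape
    df = pd.DataFrame(X, columns=[f"{family}.f{j}" for j in range(p)])
    df["complex_id"] = [f"c{i}" for i in range(n)]
    df["pose_id"] = "native"
    df["RMSD"] = y_rmsd
    df["BA"] = y_ba if y_ba is not None else np.nan
    return df.set_index(["complex_id", "pose_id"])


class TestFitBasics:
    def test_mlr_recovers_noiseless_linear_model(self, rng):
        X = rng.normal(size=(50, 2))
        y = 2 * X[:, 0] - 3 * X[:, 1] + 1
        model = fit(_table(X, y), "mlr", response="RMSD")
        est = model.estimator
        assert est.coef_ == pytest.approx([2.0, -3.0], abs=1e-10)
        assert est.intercept_ == pytest.approx(1.0, abs=1e-10)
        assert predict(model, _table(X, y)) == pytest.approx(y, abs=1e-10)

    def test_knn_k1_reproduces_training_rows(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.uniform(0, 10, 30)
        table = _table(X, y)
        model = fit(table, "knn", params={"k": 1, "q": 1})
        assert predict(model, table) == pytest.approx(y, abs=1e-12)

    def test_ba_mode_uses_native_rows_only(self, small_benchmark):
        _, _, table = small_benchmark
        model = fit(table, "mlr", response="BA")
        assert model.n_training_rows == table["BA"].notna().sum()
        model_rmsd = fit(table, "mlr", response="RMSD")
        assert model_rmsd.n_training_rows == len(table)

    def test_nonfinite_features_rejected(self, rng):
        X = rng.normal(size=(25, 2))
        X[3, 1] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            fit(_table(X, np.ones(25)), "mlr")


class TestRankPoses:
    def _model(self, response, preds):
        # tiny kNN fitted so that its predictions are exactly `preds`
        X = np.arange(len(preds), dtype=float)[:, None]
        table = _table(X, preds, y_ba=preds)
        return fit(table, "knn", response=response, params={"k": 1, "q": 1}), table

    def test_rmsd_response_ranks_ascending(self):
        model, table = self._model("RMSD", np.array([2.1, 0.3, 5.0]))
        assert rank_poses(model, table).tolist() == [1, 0, 2]

    def test_ba_response_ranks_descending(self):
        model, table = self._model("BA", np.array([6.2, 7.9]))
        assert rank_poses(model, table).tolist() == [1, 0]

    def test_ties_keep_input_order(self):
        model, table = self._model("RMSD", np.array([1.0, 1.0]))
        assert rank_poses(model, table).tolist() == [0, 1]


class TestTable1Params:
    def test_rf_xarg_mtry(self):
        assert table1_params("rf", "XARG") == {"mtry": 35}

    def test_mars_x_has_interaction_degree(self):
        assert table1_params("mars", "X") == {"degree": 2, "penalty": 2}

    def test_knn_q_is_one_everywhere(self):
        for label in ("X", "A", "R", "G", "XARG", "RG"):
            assert table1_params("knn", label)["q"] == 1

    def test_brt_fixed_shrinkage_constant(self):
        assert sfmodels.BRT_SHRINKAGE == 0.005
        assert sfmodels.RF_N_TREES == 2000


class TestTune:
    def test_single_point_grid_returned_verbatim(self, rng):
        X = rng.normal(size=(30, 2))
        table = _table(X, rng.uniform(0, 5, 30))
        assert tune(table, "knn", grid={"k": [7], "q": [1]}, response="RMSD") == {"k": 7, "q": 1}

    def test_empty_grid_is_configuration_error(self, rng):
        X = rng.normal(size=(30, 2))
        table = _table(X, rng.uniform(0, 5, 30))
        with pytest.raises(sfmodels.ConfigurationError):
            tune(table, "knn", grid={"k": []}, response="RMSD")

    def test_knn_matches_exhaustive_cv_oracle(self, rng):
        # fine-structure signal: the best neighbourhood is small
        X = rng.uniform(0, 1, size=(100, 1))
        y = np.sin(12 * X[:, 0])
        table = _table(X, y)
        grid = {"k": [1, 3, 7, 15], "q": [1]}
        chosen = tune(table, "knn", grid=grid, response="RMSD", seed=9)

        # independent oracle: explicit 10-fold CV over the same grid
        Xs = StandardScaler().fit(X).transform(X)
        best = None
        for k in grid["k"]:
            mse = 0.0
            folds = KFold(n_splits=10, shuffle=True, random_state=9)
            for tr, va in folds.split(Xs):
                est = KNeighborsRegressor(n_neighbors=k, p=1).fit(Xs[tr], y[tr])
                mse += np.mean((est.predict(Xs[va]) - y[va]) ** 2)
            if best is None or mse / 10 < best[0]:
                best = (mse / 10, k)
        assert chosen["k"] == best[1]
        assert chosen["k"] <= 3


class TestMars:
    def test_degree_one_has_no_interactions(self, rng):
        X = rng.normal(size=(120, 4))
        y = np.maximum(0, X[:, 0] - 0.3) + 2 * np.maximum(0, -X[:, 1]) + rng.normal(scale=0.05, size=120)
        est = MarsRegressor(degree=1, penalty=3).fit(X, y)
        assert est.max_degree_ <= 1
        assert all(len(t) <= 1 for t in est.terms_)

    def test_recovers_hinge_function(self, rng):
        X = rng.uniform(-2, 2, size=(200, 3))
        y = 3 * np.maximum(0, X[:, 0] - 0.5)
        est = MarsRegressor(degree=1).fit(X, y)
        pred = est.predict(X)
        assert np.corrcoef(pred, y)[0, 1] > 0.99

    def test_degree_two_can_model_products(self, rng):
        X = rng.uniform(-1, 1, size=(300, 2))
        y = X[:, 0] * X[:, 1]
        lin = MarsRegressor(degree=1).fit(X, y)
        quad = MarsRegressor(degree=2).fit(X, y)
        assert np.mean((quad.predict(X) - y) ** 2) < np.mean((lin.predict(X) - y) ** 2)
        assert quad.max_degree_ == 2

    def test_deterministic(self, rng):
        X = rng.normal(size=(80, 5))
        y = X[:, 0] ** 2 + rng.normal(scale=0.1, size=80)
        p1 = MarsRegressor(degree=1).fit(X, y).predict(X)
        p2 = MarsRegressor(degree=1).fit(X, y).predict(X)
        assert np.array_equal(p1, p2)


class TestBrt:
    def test_staged_training_error_non_increasing(self, rng):
        X = rng.normal(size=(80, 3))
        y = X[:, 0] + 0.5 * X[:, 1] ** 2
        table = _table(X, y)
        model = fit(table, "brt", params={"interaction_depth": 3, "n_trees": 200}, seed=1)
        errs = [
            np.mean((pred - y) ** 2)
            for pred in model.estimator.staged_predict(model._matrix(table))
        ]
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))

    def test_internal_cv_selects_tree_count(self, rng):
        X = rng.normal(size=(60, 2))
        y = X[:, 0] + rng.normal(scale=0.1, size=60)
        model = fit(_table(X, y), "brt", params={"interaction_depth": 2}, seed=1)
        assert 1 <= model.params["n_trees"] <= 3000


class TestModelContract:
    def test_predictions_invariant_to_row_permutation(self, small_benchmark, rng):
        _, _, table = small_benchmark
        model = fit(table, "knn", response="RMSD", seed=2)
        perm = rng.permutation(len(table))
        shuffled = table.iloc[perm]
        assert predict(model, shuffled) == pytest.approx(predict(model, table)[perm], abs=1e-12)

    def test_save_load_round_trip_bitwise(self, small_benchmark, tmp_path):
        _, _, table = small_benchmark
        model = fit(table, "mars", response="RMSD", seed=2)
        path = tmp_path / "m.bundle"
        save_model(model, path)
        back = load_model(path)
        assert back.method == "mars" and back.response == "RMSD"
        assert np.array_equal(predict(back, table), predict(model, table))

    def test_same_seed_identical_predictions(self, small_benchmark):
        _, _, table = small_benchmark
        p1 = predict(fit(table, "rf", params={"mtry": 8}, seed=7), table)
        p2 = predict(fit(table, "rf", params={"mtry": 8}, seed=7), table)
        assert np.array_equal(p1, p2)

    def test_signature_mismatch_raises(self, small_benchmark):
        _, _, table = small_benchmark
        model = fit(table, "mlr", response="RMSD")
        with pytest.raises(Exception, match="signature|columns"):
            predict(model, table[[c for c in table.columns if c.startswith("X.")] + ["RMSD", "BA"]])

    def test_rmsd_model_ranking_tracks_true_rmsd(self, small_benchmark):
        from scipy.stats import kendalltau

        _, _, table = small_benchmark
        train, test = split_by_complex(table, 30)
        model = fit(train, "rf", params={"mtry": 20}, response="RMSD", seed=4)
        taus = []
        for _, group in test.groupby(level="complex_id"):
            tau = kendalltau(predict(model, group), group["RMSD"]).statistic
            taus.append(tau)
        assert np.mean(taus) > 0.5
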