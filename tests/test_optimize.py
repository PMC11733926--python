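"""Grid/Bayesian optimization, embedding concatenation and the final model."""

import numpy as np
import pandas as pd
import pytest

from gbfs.optimize import (
    FittedModel,
    HyperparameterSpace,
    Param,
    attach_embeddings,
    coarse_grid_search,
    minimize_function,
    train_final_model,
)


def quad_space():
    return HyperparameterSpace([Param("x", "real", (0.0, 5.0))])


class TestSpace:
    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            Param("lr", "real", (1.0, 0.5))
        with pytest.raises(ValueError):
            Param("lr", "log-real", (0.0, 1.0))
        with pytest.raises(ValueError):
            Param("c", "categorical", None, choices=[])
        with pytest.raises(ValueError):
            HyperparameterSpace([Param("a", "real", (0, 1)), Param("a", "real", (0, 1))])

    def test_sampling_respects_types(self):
        space = HyperparameterSpace(
            [
                Param("n", "integer", (1, 10)),
                Param("lr", "log-real", (1e-3, 1.0)),
                Param("kind", "categorical", None, choices=["a", "b"]),
            ]
        )
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = space.sample(rng)
            assert isinstance(p["n"], int) and 1 <= p["n"] <= 10
            assert 1e-3 <= p["lr"] <= 1.0
            assert p["kind"] in ("a", "b")


class TestBayesianMinimizer:
    def test_finds_analytic_optimum(self):
        trace = minimize_function(
            lambda p: (p["x"] - 2.0) ** 2, quad_space(), n_calls=30, seed=1
        )
        assert abs(trace.best_point["x"] - 2.0) < 0.1

    def test_best_so_far_non_increasing(self):
        trace = minimize_function(
            lambda p: (p["x"] - 2.0) ** 2, quad_space(), n_calls=12, seed=0
        )
        assert (np.diff(trace.best_so_far) <= 1e-15).all()

    def test_seeded_traces_identical(self):
        f = lambda p: np.sin(3 * p["x"]) + 0.1 * p["x"]
        t1 = minimize_function(f, quad_space(), n_calls=15, seed=7)
        t2 = minimize_function(f, quad_space(), n_calls=15, seed=7)
        assert t1.points == t2.points and t1.values == t2.values

    def test_call_budget_enforced(self):
        trace = minimize_function(lambda p: p["x"], quad_space(), n_calls=9, seed=0)
        assert len(trace.values) == 9
        with pytest.raises(ValueError):
            minimize_function(lambda p: p["x"], quad_space(), n_calls=2, seed=0)


class TestGridSearch:
    def _data(self, rng):
        X = pd.DataFrame(rng.normal(size=(120, 3)), columns=list("abc"))
        y = X["a"].to_numpy() + 0.2 * rng.normal(size=120)
        return X, y

    def test_single_point_grid_degenerate(self, rng):
        X, y = self._data(rng)
        best, region, trace = coarse_grid_search(
            X, y, {"learning_rate": [0.1]}, cv_folds=3, seed=0
        )
        assert best == {"learning_rate": 0.1}
        assert region == {"learning_rate": [0.1]}
        assert len(trace.values) == 1

    def test_evaluation_count_is_grid_size(self, rng):
        X, y = self._data(rng)
        grid = {"learning_rate": [0.05, 0.1], "num_leaves": [7, 15, 31]}
        _, _, trace = coarse_grid_search(X, y, grid, cv_folds=3, seed=0)
        assert len(trace.values) == 6

    def test_region_brackets_best(self, rng):
        X, y = self._data(rng)
        grid = {"learning_rate": [0.01, 0.05, 0.1]}
        best, region, _ = coarse_grid_search(X, y, grid, cv_folds=3, seed=0)
        assert best["learning_rate"] in region["learning_rate"]
        assert len(region["learning_rate"]) <= 3

    def test_empty_grid_rejected(self, rng):
        X, y = self._data(rng)
        with pytest.raises(ValueError):
            coarse_grid_search(X, y, {}, cv_folds=3, seed=0)


class TestAttachEmbeddings:
    def test_width_additivity_and_order(self, rng):
        X = pd.DataFrame(rng.normal(size=(8, 4)), columns=list("abcd"))
        E = pd.DataFrame(rng.normal(size=(8, 3)), columns=[f"Mol2Vec-{i}" for i in range(3)])
        out = attach_embeddings(X, E)
        assert out.shape[1] == 7
        assert list(out.columns)[:4] == list("abcd")

    def test_empty_embeddings_identity(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 2)), columns=list("ab"))
        assert attach_embeddings(X, pd.DataFrame(index=range(5))).equals(X)

    def test_row_mismatch_and_collision_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 2)), columns=list("ab"))
        with pytest.raises(ValueError):
            attach_embeddings(X, pd.DataFrame({"Mol2Vec-0": [1.0]}))
        with pytest.raises(ValueError):
            attach_embeddings(X, pd.DataFrame({"a": np.zeros(5)}))


class TestFinalModel:
    def test_capacity_on_noiseless_linear_target(self, rng):
        X = pd.DataFrame(rng.normal(size=(400, 3)), columns=list("abc"))
        y = X["a"].to_numpy() + 2 * X["b"].to_numpy()
        model = train_final_model(X, y, best_point={"n_estimators": 400}, seed=0)
        from gbfs import metrics as M

        assert M.r_squared(y, model.predict(X)) >= 0.99

    def test_deterministic_refit(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        y = X["a"].to_numpy() + 0.1 * rng.normal(size=200)
        p1 = train_final_model(X, y, seed=3).predict(X)
        p2 = train_final_model(X, y, seed=3).predict(X)
        assert np.array_equal(p1, p2)

    def test_constant_target_warns_and_predicts_constant(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=list("ab"))
        with pytest.warns(UserWarning):
            model = train_final_model(X, np.ones(50), seed=0)
        assert np.allclose(model.predict(X), 1.0)

    def test_feature_name_contract(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        y = X["a"].to_numpy()
        model = train_final_model(X, y, seed=0)
        # permuted column order is realigned by name
        assert np.array_equal(model.predict(X[["c", "a", "b"]]), model.predict(X))
        with pytest.raises(ValueError, match="schema"):
            model.predict(X[["a", "b"]])
        with pytest.raises(ValueError, match="schema"):
            model.predict(X.assign(extra=1.0))

    def test_classification_probabilities_valid(self, rng):
        X = pd.DataFrame(rng.normal(size=(300, 3)), columns=list("abc"))
        y = (X["a"] > 0).astype(int).to_numpy()
        model = train_final_model(X, y, task_type="classification", seed=0)
        proba = model.predict_proba(X)
        assert proba.shape == (300, 2)
        assert np.all(proba >= 0) and np.all(proba <= 1)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_save_load_roundtrip(self, tmp_path, rng):
        X = pd.DataFrame(rng.normal(size=(150, 3)), columns=list("abc"))
        y = X["a"].to_numpy() + 0.1 * rng.normal(size=150)
        model = train_final_model(X, y, seed=0)
        model.save(tmp_path / "m")
        loaded = FittedModel.load(tmp_path / "m")
        assert loaded.feature_names == model.feature_names
        assert np.allclose(loaded.predict(X), model.predict(X))
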