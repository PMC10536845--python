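"""Fold discipline, KNN semantics, benchmarking, grid search and persistence."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.tree import DecisionTreeRegressor

from qsarscreen.exceptions import ParameterError, ProvenanceError, StateError
from qsarscreen.models import (
    CVMetrics,
    KNNSpec,
    KNeighborsActivityRegressor,
    aggregate_metrics,
    benchmark,
    check_featurizer_match,
    cross_validate,
    cv_predictions,
    default_registry,
    grid_search,
    kfold_split,
    knn_predict,
    load_model,
    save_model,
)


class TestKFold:
    def test_singleton_folds(self):
        labels = kfold_split(10, 10, seed=0)
        assert sorted(np.bincount(labels)) == [1] * 10

    def test_study_size_partition(self):
        sizes = sorted(np.bincount(kfold_split(1647, 10, seed=0)))
        assert sizes == [164] * 3 + [165] * 7

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(min_value=10, max_value=400), st.integers(min_value=0, max_value=99))
    def test_partition_property(self, n, seed):
        labels = kfold_split(n, 10, seed=seed)
        assert len(labels) == n
        counts = np.bincount(labels, minlength=10)
        assert counts.max() - counts.min() <= 1

    def test_too_few_samples(self):
        with pytest.raises(ParameterError):
            kfold_split(5, 10)


def _brute_knn(X, y, query, spec: KNNSpec):
    d = (np.abs(X - query) ** spec.p).sum(axis=1) ** (1.0 / spec.p)
    order = sorted(range(len(X)), key=lambda i: (d[i], i))[: spec.n_neighbors]
    if spec.weights == "uniform":
        return y[order].mean()
    dd = d[order]
    if (dd == 0).any():
        return y[[i for i in order if d[i] == 0][0]]
    return float(np.average(y[order], weights=1.0 / dd))


class TestKnnPredict:
    def test_training_point_identity(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        assert knn_predict(X, y, X[3], KNNSpec(n_neighbors=1)) == pytest.approx(y[3])

    def test_equidistant_mean(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        y = np.array([4.0, 8.0])
        assert knn_predict(X, y, np.array([0.0, 0.0]), KNNSpec(n_neighbors=2)) == pytest.approx(6.0)

    @pytest.mark.parametrize("p", [1, 2, 3])
    @pytest.mark.parametrize("weights", ["uniform", "distance"])
    def test_matches_exhaustive_sort_oracle(self, rng, p, weights):
        X = rng.normal(size=(200, 6))
        y = rng.normal(size=200)
        Q = rng.normal(size=(20, 6))
        spec = KNNSpec(n_neighbors=5, p=p, weights=weights)
        pred = knn_predict(X, y, Q, spec)
        oracle = np.array([_brute_knn(X, y, q, spec) for q in Q])
        np.testing.assert_allclose(pred, oracle, atol=1e-10)

    def test_matches_sklearn_cross_check(self, rng):
        from sklearn.neighbors import KNeighborsRegressor

        X = rng.normal(size=(80, 5))
        y = rng.normal(size=80)
        Q = rng.normal(size=(15, 5))
        mine = KNeighborsActivityRegressor(n_neighbors=5, p=2).fit(X, y).predict(Q)
        ref = KNeighborsRegressor(n_neighbors=5, p=2).fit(X, y).predict(Q)
        np.testing.assert_allclose(mine, ref, atol=1e-10)

    def test_leaf_size_is_prediction_neutral(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        Q = rng.normal(size=(8, 3))
        a = KNeighborsActivityRegressor(leaf_size=5).fit(X, y).predict(Q)
        b = KNeighborsActivityRegressor(leaf_size=50).fit(X, y).predict(Q)
        np.testing.assert_array_equal(a, b)

    def test_empty_training_set(self):
        with pytest.raises(StateError):
            KNeighborsActivityRegressor().fit(np.empty((0, 3)), np.empty(0))


class TestCrossValidate:
    def test_perfect_learner_scores_one(self, rng):
        class FeatureEcho:
            """Reads the target straight from the last feature column."""

            def get_params(self, deep=True):
                return {}

            def set_params(self, **kw):
                return self

            def fit(self, X, y):
                return self

            def predict(self, X):
                return np.asarray(X)[:, -1]

        X = rng.normal(size=(50, 2))
        y = X[:, 0] * 2.0
        metrics = cross_validate(FeatureEcho(), np.hstack([X, y[:, None]]), y, k=5, seed=0)
        assert metrics.mean["r2"] == pytest.approx(1.0, abs=1e-9)
        assert metrics.mean["rmse"] == pytest.approx(0.0, abs=1e-9)

    def test_mean_predictor_baseline_r2_near_zero(self, rng):
        from sklearn.dummy import DummyRegressor

        X = rng.normal(size=(200, 3))
        y = rng.normal(size=200)
        metrics = cross_validate(DummyRegressor(), X, y, k=10, seed=0)
        assert metrics.mean["r2"] <= 0.0
        assert metrics.mean["r2"] > -0.3

    def test_metric_identities_per_fold(self, featurized_library):
        X, y = featurized_library
        metrics = cross_validate(KNeighborsActivityRegressor(), X, y, k=5, seed=1)
        per = metrics.per_fold
        np.testing.assert_allclose(per["rmse"] ** 2, per["mse"], atol=1e-12)
        assert (per["mae"] <= per["rmse"] + 1e-12).all()

    def test_held_out_discipline(self, rng):
        """Every sample's CV prediction comes from a model that never saw it:
        a 1-NN memorizer must NOT be perfect out of fold on noise."""
        X = rng.normal(size=(60, 2))
        y = rng.normal(size=60)
        yhat = cv_predictions(KNeighborsActivityRegressor(n_neighbors=1), X, y, k=6, seed=0)
        assert not np.allclose(yhat, y)

    def test_synthetic_benchmark_r2_band(self, featurized_library):
        X, y = featurized_library
        metrics = cross_validate(KNeighborsActivityRegressor(), X, y, k=10, seed=2)
        assert 0.5 <= metrics.mean["r2"] <= 1.0


class TestAggregate:
    def test_constant_list_zero_sd(self):
        per = pd.DataFrame({"r2": [0.5] * 4})
        mean, sd = aggregate_metrics(per)
        assert mean["r2"] == pytest.approx(0.5)
        assert sd["r2"] == 0.0

    def test_sample_sd_uses_n_minus_one(self):
        per = pd.DataFrame({"x": [1.0, 3.0]})
        _, sd = aggregate_metrics(per)
        assert sd["x"] == pytest.approx(np.sqrt(2.0))


class TestBenchmark:
    def test_perfect_learner_ranked_first(self, rng):
        X = rng.normal(size=(60, 3))
        y = X.sum(axis=1)
        from sklearn.dummy import DummyRegressor
        from sklearn.linear_model import LinearRegression

        table = benchmark({"linear": LinearRegression(), "mean": DummyRegressor()}, X, y, k=5, seed=0)
        assert table.iloc[0]["algorithm"] == "linear"

    def test_same_learner_twice_identical_rows(self, featurized_library):
        X, y = featurized_library
        table = benchmark(
            {"a": KNeighborsActivityRegressor(), "b": KNeighborsActivityRegressor()},
            X[:100], y[:100], k=5, seed=3,
        )
        assert table.iloc[0][["r2", "rmse", "mae"]].tolist() == table.iloc[1][["r2", "rmse", "mae"]].tolist()

    def test_knn_beats_stump_on_linear_map(self, featurized_library):
        X, y = featurized_library
        table = benchmark(
            {"k_neighbors": KNeighborsActivityRegressor(),
             "stump": DecisionTreeRegressor(max_depth=1, random_state=0)},
            X, y, k=5, seed=0,
        )
        assert table.iloc[0]["algorithm"] == "k_neighbors"

    def test_failed_learner_recorded_run_continues(self, rng):
        class Broken:
            def get_params(self, deep=True):
                return {}

            def set_params(self, **kw):
                return self

            def fit(self, X, y):
                raise RuntimeError("boom")

        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        table = benchmark({"ok": KNeighborsActivityRegressor(), "bad": Broken()}, X, y, k=3, seed=0)
        bad = table[table["algorithm"] == "bad"].iloc[0]
        assert bad["status"].startswith("failed")
        assert table[table["algorithm"] == "ok"].iloc[0]["status"] == "ok"

    def test_registry_has_ten_learners(self):
        assert len(default_registry()) == 10


class TestGridSearch:
    def test_single_point_grid(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        best, table = grid_search(
            X, y, n_neighbors_range=[4], p_range=[2], weights_options=["uniform"],
            leaf_sizes=[30], k=4, seed=0,
        )
        assert best == KNNSpec(n_neighbors=4, p=2, weights="uniform", leaf_size=30)
        assert len(table) == 1

    def test_smooth_target_prefers_small_k(self, rng):
        X = rng.uniform(-1, 1, size=(120, 2))
        y = X[:, 0] ** 2 + 0.5 * X[:, 1]
        best, _ = grid_search(
            X, y, n_neighbors_range=range(1, 11), p_range=[2],
            weights_options=["uniform"], leaf_sizes=[30], k=5, seed=0,
        )
        assert best.n_neighbors <= 5

    def test_result_inside_grid_bounds(self, featurized_library):
        X, y = featurized_library
        best, _ = grid_search(
            X[:80], y[:80], n_neighbors_range=range(2, 6), p_range=[1, 2],
            weights_options=["uniform", "distance"], leaf_sizes=[5, 10], k=4, seed=0,
        )
        assert 2 <= best.n_neighbors <= 5 and best.p in (1, 2)


class TestPersistence:
    def test_round_trip_bitwise(self, rng, tmp_path):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        probes = rng.normal(size=(20, 4))
        model = KNeighborsActivityRegressor(n_neighbors=3).fit(X, y)
        prov = {"kind": "hashed", "dimension": 4, "seed": 1, "radii": [0, 1]}
        path = tmp_path / "model.json"
        save_model(model, path, prov)
        loaded, loaded_prov = load_model(path)
        np.testing.assert_array_equal(loaded.predict(probes), model.predict(probes))
        assert loaded_prov == prov

    def test_tampered_file_refused(self, rng, tmp_path):
        X = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        path = tmp_path / "model.json"
        save_model(KNeighborsActivityRegressor(n_neighbors=2).fit(X, y), path, {})
        import json

        doc = json.loads(path.read_text())
        doc["y"][0] += 1.0
        path.write_text(json.dumps(doc))
        with pytest.raises(ProvenanceError, match="hash"):
            load_model(path)

    def test_featurizer_mismatch_refused(self):
        with pytest.raises(ProvenanceError, match="seed"):
            check_featurizer_match(
                {"kind": "hashed", "dimension": 32, "seed": 1},
                {"kind": "hashed", "dimension": 32, "seed": 2},
            )
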