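"""Quality-aware learners: forests, SVRs, specs and persistence."""

import numpy as np
import pytest

import ec50ml.forest as forest_mod
from ec50ml.data import QualityTargetTable
from ec50ml.forest import (
    OutputSmearingForest,
    ParametricBootstrapForest,
    RandomForest,
    VariableOutputSmearingForest,
    WeightedForest,
    min_samples_split_count,
)
from ec50ml.models import ModelSpec, TrainedModel, train_model
from ec50ml.svm import SupportVectorRegressor, WeightedSupportVectorRegressor
from ec50ml.weights import quality_weights


@pytest.fixture
def small_data():
    rng = np.random.default_rng(0)
    X = (rng.random((80, 12)) < 0.3).astype(float)
    y = X[:, 0] * 3.0 + X[:, 1] - 0.5 * X[:, 2] + 0.05 * rng.standard_normal(80)
    z = rng.random(80) * 4
    return X, y, z


FOREST_KW = dict(n_trees=25, min_samples_split=0.05, seed=11)


class TestAlphaZeroEquivalence:
    def test_pb_and_weighted_reduce_to_plain_forest(self, small_data):
        X, y, z = small_data
        rf = RandomForest(max_features=0.5, **FOREST_KW).fit(X, y, z)
        pb = ParametricBootstrapForest(alpha=0, max_features=0.5, **FOREST_KW).fit(X, y, z)
        wf = WeightedForest(alpha=0, max_features=0.5, **FOREST_KW).fit(X, y, z)
        np.testing.assert_array_equal(rf.predict(X), pb.predict(X))
        np.testing.assert_array_equal(rf.predict(X), wf.predict(X))

    def test_vos_reduces_to_os(self, small_data):
        X, y, z = small_data
        os_ = OutputSmearingForest(beta=1.5, **FOREST_KW).fit(X, y, z)
        vos = VariableOutputSmearingForest(alpha=0, beta=1.5, **FOREST_KW).fit(X, y, z)
        np.testing.assert_array_equal(os_.predict(X), vos.predict(X))

    def test_os_with_zero_beta_is_plain_forest_all_features(self, small_data):
        X, y, z = small_data
        rf = RandomForest(max_features=1.0, **FOREST_KW).fit(X, y, z)
        os_ = OutputSmearingForest(beta=0.0, **FOREST_KW).fit(X, y, z)
        np.testing.assert_array_equal(rf.predict(X), os_.predict(X))

    def test_weighted_svr_reduces_to_svr(self, small_data):
        X, y, z = small_data
        svr = SupportVectorRegressor(epsilon=0.1).fit(X, y)
        wsvr = WeightedSupportVectorRegressor(alpha=0, epsilon=0.1).fit(X, y, z)
        np.testing.assert_array_equal(svr.predict(X), wsvr.predict(X))


class _RecordingTree:
    """Stand-in for a decision tree that records what it is fitted on."""

    log: list = []

    def __init__(self, **kwargs):
        pass

    def fit(self, X, y, sample_weight=None):
        type(self).log.append((np.asarray(X).copy(), np.asarray(y).copy()))
        return self

    def predict(self, X):
        return np.zeros(len(X))


@pytest.fixture
def recording_trees(monkeypatch):
    _RecordingTree.log = []
    monkeypatch.setattr(forest_mod, "DecisionTreeRegressor", _RecordingTree)
    return _RecordingTree.log


class TestParametricBootstrap:
    def test_selection_frequencies_follow_quality_weights(self, recording_trees):
        X = np.arange(6, dtype=float).reshape(-1, 1)
        y = np.arange(6, dtype=float)
        z = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 8.0])
        alpha = 1.0
        ParametricBootstrapForest(alpha=alpha, n_trees=3000, seed=5).fit(X, y, z)
        counts = np.zeros(6)
        for Xb, _ in recording_trees:
            idx, c = np.unique(Xb[:, 0].astype(int), return_counts=True)
            counts[idx] += c
        freq = counts / counts.sum()
        np.testing.assert_allclose(freq, quality_weights(z, alpha).p, atol=0.01)

    def test_extreme_alpha_collapses_to_best_point(self, small_data):
        X, y, z = small_data
        z = z.copy()
        z[:] = 50.0
        z[3] = 0.0
        pb = ParametricBootstrapForest(alpha=500.0, max_features=1.0, **FOREST_KW)
        pb.fit(X, y, z)
        np.testing.assert_allclose(pb.predict(X), y[3], atol=1e-12)


class TestOutputSmearing:
    def test_per_tree_smearing_variance_matches_beta(self, recording_trees):
        beta = 4.0
        X = np.arange(5, dtype=float).reshape(-1, 1)
        y = np.zeros(5)
        OutputSmearingForest(beta=beta, n_trees=8000, seed=3).fit(X, y)
        values = [[] for _ in range(5)]
        for Xb, yb in recording_trees:
            # one smear draw per original point per tree: dedupe bootstrap copies
            for xv in np.unique(Xb[:, 0].astype(int)):
                values[xv].append(yb[Xb[:, 0] == xv][0])
        pooled = np.concatenate(values)
        assert np.var(pooled) == pytest.approx(beta, rel=0.05)
        for v in values:
            assert np.var(v) == pytest.approx(beta, rel=0.10)

    def test_vos_variances_honor_quality_ordering_and_mean(self):
        vos = VariableOutputSmearingForest(alpha=1.0, beta=2.0)
        var = vos._smear_variances(np.array([0.0, 10.0]), 2)
        assert var[0] < 2.0 < var[1]
        assert var.mean() == pytest.approx(2.0, abs=1e-12)

    def test_vos_literal_mode_uses_beta_p(self):
        z = np.array([0.0, 1.0, 3.0])
        vos = VariableOutputSmearingForest(alpha=0.7, beta=2.0, smear_mode="literal")
        np.testing.assert_allclose(
            vos._smear_variances(z, 3), 2.0 * quality_weights(z, 0.7).p, rtol=1e-12
        )

    def test_negative_beta_rejected(self, small_data):
        X, y, z = small_data
        with pytest.raises(ValueError, match="beta"):
            OutputSmearingForest(beta=-1.0).fit(X, y, z)


class TestWeightedModels:
    def test_weighted_forest_moves_toward_low_z_targets(self):
        # one indistinguishable cluster: low-z points say 0, high-z points say 10
        X = np.zeros((20, 1))
        y = np.array([0.0] * 10 + [10.0] * 10)
        z = np.array([0.0] * 10 + [30.0] * 10)
        preds = []
        for alpha in (0.0, 0.5, 1.0, 2.0, 4.0):
            wf = WeightedForest(alpha=alpha, n_trees=50, seed=2).fit(X, y, z)
            preds.append(wf.predict(np.zeros((1, 1)))[0])
        assert preds[0] == pytest.approx(5.0, abs=1.0)
        assert np.all(np.diff(preds) < 0)
        assert preds[-1] < 0.5

    def test_weighted_svr_tracks_low_z_point_per_region(self):
        X = np.array([[0.0]] * 6 + [[3.0]] * 6)
        y = np.array([1.0] + [0.0] * 5 + [0.0] + [1.0] * 5)
        z = np.array([0.0] + [20.0] * 5 + [0.0] + [20.0] * 5)
        wsvr = WeightedSupportVectorRegressor(alpha=50.0, epsilon=0.05).fit(X, y, z)
        assert wsvr.predict([[0.0]])[0] == pytest.approx(1.0, abs=0.15)
        assert wsvr.predict([[3.0]])[0] == pytest.approx(0.0, abs=0.15)

    def test_svr_epsilon_validation(self, small_data):
        X, y, z = small_data
        with pytest.raises(ValueError, match="epsilon"):
            SupportVectorRegressor(epsilon=0.0).fit(X, y)
        with pytest.raises(ValueError, match="alpha"):
            WeightedSupportVectorRegressor(alpha=-1.0).fit(X, y, z)


class TestPredictionContracts:
    def test_deterministic_across_refits(self, small_data):
        X, y, z = small_data
        p1 = VariableOutputSmearingForest(alpha=1, beta=1, **FOREST_KW).fit(X, y, z).predict(X)
        p2 = VariableOutputSmearingForest(alpha=1, beta=1, **FOREST_KW).fit(X, y, z).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_forest_prediction_is_mean_of_trees(self, small_data):
        X, y, z = small_data
        rf = RandomForest(max_features=0.5, **FOREST_KW).fit(X, y, z)
        np.testing.assert_allclose(
            rf.predict(X), rf.tree_predictions(X).mean(axis=0), atol=1e-12
        )

    def test_constant_target_predicts_constant(self, small_data):
        X, _, z = small_data
        y = np.full(len(X), 3.25)
        rf = RandomForest(**FOREST_KW).fit(X, y, z)
        np.testing.assert_allclose(rf.predict(X), 3.25, atol=1e-12)

    def test_feature_dimension_mismatch_raises(self, small_data):
        X, y, z = small_data
        rf = RandomForest(**FOREST_KW).fit(X, y, z)
        with pytest.raises(ValueError):
            rf.predict(X[:, :-1])

    def test_min_samples_split_fraction_rounds_half_up(self):
        assert min_samples_split_count(0.025, 500) == 13
        assert min_samples_split_count(0.01, 500) == 5
        assert min_samples_split_count(0.10, 500) == 50
        assert min_samples_split_count(0.01, 10) == 2  # floor at 2
        assert min_samples_split_count(7, 500) == 7


class TestModelSpec:
    def test_irrelevant_hyperparameters_rejected(self):
        with pytest.raises(ValueError, match="not used"):
            ModelSpec("RF", {"alpha": 1.0})
        with pytest.raises(ValueError, match="not used"):
            ModelSpec("SVR", {"max_features": 0.5})
        with pytest.raises(ValueError, match="unknown family"):
            ModelSpec("GBM", {})

    def test_build_dispatches_to_each_family(self):
        families = {
            "RF": RandomForest,
            "PB_RF": ParametricBootstrapForest,
            "W_RF": WeightedForest,
            "OS_RF": OutputSmearingForest,
            "VOS_RF": VariableOutputSmearingForest,
            "SVR": SupportVectorRegressor,
            "WSVR": WeightedSupportVectorRegressor,
        }
        for family, cls in families.items():
            assert isinstance(ModelSpec(family, {}).build(), cls)

    def test_train_save_load_round_trip(self, toy_table, tmp_path):
        spec = ModelSpec("PB_RF", {"alpha": 1.0, "max_features": 0.5}, n_trees=20, seed=1)
        model = train_model(toy_table, spec)
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = TrainedModel.load(path)
        np.testing.assert_array_equal(
            model.predict(toy_table.features), loaded.predict(toy_table.features)
        )
        assert loaded.spec == spec

    def test_empty_table_rejected(self):
        empty = QualityTargetTable([], np.empty((0, 0)), [], [])
        with pytest.raises(ValueError, match="empty"):
            train_model(empty, ModelSpec("RF", {}))
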