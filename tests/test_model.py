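"""Tests for importance ranking, selection, regression and error metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermotex.model import (
    ForestConfig,
    feature_temperature_correlation,
    fit,
    mae,
    predict,
    rank_importance,
    rmse,
    select_top_k,
    train_temperature_model,
)

CFG = ForestConfig(n_trees=100, seed=0)


def _planted(rng, n=300, p=20):
    """Feature 3 is a noisy copy of the target; the rest are noise."""
    X = rng.normal(size=(n, p))
    y = X[:, 3] * 10 + rng.normal(scale=0.1, size=n)
    return X, y


class TestRanking:
    def test_planted_signal_ranks_first_across_seeds(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, y = _planted(rng)
            names = tuple(f"f{i}" for i in range(20))
            ranking = rank_importance(X, y, ForestConfig(n_trees=50, seed=seed), names)
            hits += ranking.names[0] == "f3"
        assert hits >= 9

    def test_uninformative_features_look_like_permuted_target(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, 10))
        y = rng.normal(size=300)
        names = tuple(f"f{i}" for i in range(10))
        top_real = rank_importance(X, y, CFG, names).entries[0][1]
        perm_tops = [
            rank_importance(
                X, np.random.default_rng(s).permutation(y), CFG, names
            ).entries[0][1]
            for s in range(5)
        ]
        # the best importance under independence is indistinguishable from
        # the permuted-target distribution
        assert top_real <= 2 * max(perm_tops)

    def test_same_seed_identical_ranking(self):
        rng = np.random.default_rng(1)
        X, y = _planted(rng)
        names = tuple(f"f{i}" for i in range(20))
        assert (
            rank_importance(X, y, CFG, names).entries
            == rank_importance(X, y, CFG, names).entries
        )

    def test_constant_target_flags_zero_importances(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 5))
        names = tuple(f"f{i}" for i in range(5))
        with pytest.warns(UserWarning, match="constant target"):
            ranking = rank_importance(X, np.full(60, 5.0), CFG, names)
        assert all(v == 0 for _, v in ranking.entries)
        assert ranking.names == names  # canonical-order tie-break


class TestSelection:
    def test_top_k_returns_k_names(self):
        rng = np.random.default_rng(2)
        X, y = _planted(rng)
        ranking = rank_importance(X, y, CFG, tuple(f"f{i}" for i in range(20)))
        assert len(select_top_k(ranking, k=10)) == 10

    def test_full_k_is_identity(self):
        rng = np.random.default_rng(3)
        X, y = _planted(rng)
        ranking = rank_importance(X, y, CFG, tuple(f"f{i}" for i in range(20)))
        assert select_top_k(ranking, k=20) == ranking.names

    def test_k_too_large_raises(self):
        rng = np.random.default_rng(3)
        X, y = _planted(rng)
        ranking = rank_importance(X, y, CFG, tuple(f"f{i}" for i in range(20)))
        with pytest.raises(ValueError):
            select_top_k(ranking, k=21)


class TestMetrics:
    @pytest.mark.parametrize(
        "y,y_hat,expected",
        [
            ((0, 0, 0), (1, 2, 3), 2.0),
            ((37.0,), (38.5,), 1.5),
            ((5, 5), (5, 5), 0.0),
        ],
    )
    def test_mae_hand_values(self, y, y_hat, expected):
        assert mae(np.array(y), np.array(y_hat)) == pytest.approx(expected)

    def test_rmse_hand_value(self):
        assert rmse(np.zeros(3), np.array([1.0, 2.0, 3.0])) == pytest.approx(
            np.sqrt(14 / 3)
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mae(np.zeros(3), np.zeros(4))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=30),
        st.integers(0, 2**31 - 1),
    )
    def test_rmse_dominates_mae(self, ys, seed):
        y = np.array(ys)
        y_hat = y + np.random.default_rng(seed).normal(size=len(y))
        assert rmse(y, y_hat) >= mae(y, y_hat) - 1e-12


class TestPredictionMetrics:
    def test_summary_wraps_both_errors(self):
        from thermotex.model import evaluate_predictions

        m = evaluate_predictions(np.zeros(3), np.array([1.0, 2.0, 3.0]))
        assert m.mae_C == pytest.approx(2.0)
        assert m.rmse_C == pytest.approx(np.sqrt(14 / 3))
        assert m.n == 3
        assert m.rmse_C >= m.mae_C

    def test_inconsistent_pair_rejected(self):
        from thermotex.model import PredictionMetrics

        with pytest.raises(ValueError):
            PredictionMetrics(mae_C=2.0, rmse_C=1.0, n=5)


class TestCorrelation:
    def test_identical_series(self):
        x = np.arange(10.0)
        assert feature_temperature_correlation(x, x) == pytest.approx(1.0)

    def test_negated_series(self):
        x = np.arange(10.0)
        assert feature_temperature_correlation(x, -x) == pytest.approx(-1.0)

    def test_independent_noise_is_uncorrelated(self):
        rng = np.random.default_rng(0)
        r = feature_temperature_correlation(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(r) < 0.1

    def test_constant_series_undefined(self):
        assert np.isnan(feature_temperature_correlation(np.ones(10), np.arange(10.0)))


class TestFitPredict:
    def test_pipeline_recovers_planted_relationship(self):
        rng = np.random.default_rng(4)
        X, y = _planted(rng, n=600)
        labels = np.array(["train"] * 400 + ["val"] * 100 + ["test"] * 100)
        names = tuple(f"f{i}" for i in range(20))
        model = train_temperature_model(
            X, y, labels, ForestConfig(n_trees=50, seed=0), feature_names=names
        )
        assert "f3" in model.selected_features
        test = labels == "test"
        assert mae(y[test], predict(model, X[test])) < 0.2 * y.std()

    def test_prediction_rejects_wrong_width(self):
        rng = np.random.default_rng(4)
        X, y = _planted(rng)
        labels = np.array(["train"] * 200 + ["val"] * 50 + ["test"] * 50)
        model = train_temperature_model(
            X, y, labels, ForestConfig(n_trees=20, seed=0),
            feature_names=tuple(f"f{i}" for i in range(20)),
        )
        with pytest.raises(ValueError, match="length"):
            predict(model, np.zeros((3, 7)))

    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        X, y = _planted(rng)
        labels = np.array(["train"] * 200 + ["val"] * 50 + ["test"] * 50)
        model = train_temperature_model(
            X, y, labels, ForestConfig(n_trees=20, seed=0),
            feature_names=tuple(f"f{i}" for i in range(20)),
        )
        path = tmp_path / "model.joblib"
        model.save(path)
        from thermotex.model import TrainedTemperatureModel

        loaded = TrainedTemperatureModel.load(path)
        assert np.array_equal(predict(loaded, X), predict(model, X))
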