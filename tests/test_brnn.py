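"""Feature encoding, splitting, Bayesian-regularized training and the
ensemble algebra."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riacarb import brnn
from riacarb.brnn import (
    EncodingError,
    FEATURE_NAMES,
    Metrics,
    NetworkMember,
    encode_features,
    evaluate,
    predict_members,
    split_train_test,
    train_ensemble,
    train_member,
)


def _one_row(week):
    return pd.DataFrame({
        "latitude": [42.2], "longitude": [-8.8], "depth_m": [2.5],
        "temperature_c": [15.0], "salinity": [35.0],
        "phosphate_umol_kg": [0.5], "nitrate_umol_kg": [6.0],
        "silicate_umol_kg": [5.0], "year_decimal": [2001.5], "week": [week],
    })


class TestEncodeFeatures:
    def test_week_full_period(self):
        X = encode_features(_one_row(52))
        i, j = FEATURE_NAMES.index("week_sin"), FEATURE_NAMES.index("week_cos")
        assert abs(X[0, i] - 0.0) < 1e-12
        assert abs(X[0, j] - 1.0) < 1e-12

    def test_week_quarter_period(self):
        X = encode_features(_one_row(13))
        i, j = FEATURE_NAMES.index("week_sin"), FEATURE_NAMES.index("week_cos")
        assert abs(X[0, i] - 1.0) < 1e-12
        assert abs(X[0, j] - 0.0) < 1e-12

    def test_week_20_against_arbitrary_precision(self):
        # frozen from sympy at 30 digits: sin(2*pi*20/52), cos(2*pi*20/52)
        expected_sin = 0.663122658240795202376785492667
        expected_cos = -0.748510748171101098634630599701

        X = encode_features(_one_row(20))
        i, j = FEATURE_NAMES.index("week_sin"), FEATURE_NAMES.index("week_cos")
        assert X[0, i] == pytest.approx(expected_sin, abs=1e-15)
        assert X[0, j] == pytest.approx(expected_cos, abs=1e-15)

    def test_unit_circle_invariant(self):
        for week in range(1, 53):
            X = encode_features(_one_row(week))
            i, j = FEATURE_NAMES.index("week_sin"), FEATURE_NAMES.index("week_cos")
            assert X[0, i] ** 2 + X[0, j] ** 2 == pytest.approx(1.0, abs=1e-12)

    def test_missing_predictor_named(self):
        row = _one_row(10).drop(columns=["salinity"])
        with pytest.raises(EncodingError, match="salinity"):
            encode_features(row)

    def test_non_finite_predictor_rejected(self):
        row = _one_row(10)
        row.loc[0, "nitrate_umol_kg"] = np.nan
        with pytest.raises(EncodingError, match="nitrate"):
            encode_features(row)


class TestSplit:
    def test_exhaustive_disjoint_partition(self):
        df = pd.DataFrame({"x": np.arange(100)})
        train, test = split_train_test(df, 0.10, seed=4)
        assert len(test) == 10 and len(train) == 90
        assert sorted(train["x"].tolist() + test["x"].tolist()) == list(range(100))

    def test_same_seed_same_split(self):
        df = pd.DataFrame({"x": np.arange(57)})
        a = split_train_test(df, 0.10, seed=9)
        b = split_train_test(df, 0.10, seed=9)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_rounding_half_away_from_zero(self):
        # 0.10 * 5755 = 575.5 -> 576 test rows under the documented rule
        df = pd.DataFrame({"x": np.zeros(5755)})
        train, test = split_train_test(df, 0.10, seed=0)
        assert len(test) == 576
        assert len(train) == 5755 - 576

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            split_train_test(pd.DataFrame({"x": [1, 2, 3]}), 0.10, seed=0)


class TestEvaluate:
    def test_perfect_predictions(self):
        m = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.mae == 0 and m.mse == 0 and m.rmse == 0 and m.r2 == 1.0

    def test_constant_mean_prediction_r2_zero(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        m = evaluate(np.full(4, obs.mean()), obs)
        assert m.r2 == pytest.approx(0.0, abs=1e-15)

    def test_hand_arithmetic_example(self):
        m = evaluate([1.0, 2.0, 4.0], [1.0, 2.0, 3.0])
        assert m.mae == pytest.approx(1 / 3)
        assert m.mse == pytest.approx(1 / 3)
        assert m.rmse == pytest.approx(0.5774, abs=1e-4)
        assert m.r2 == pytest.approx(0.5)

    def test_zero_variance_flags_r2(self):
        m = evaluate([1.0, 2.0], [3.0, 3.0])
        assert math.isnan(m.r2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate([1.0, 2.0], [1.0])

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_metric_inequalities(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.normal(size=20)
        pred = rng.normal(size=20)
        m = evaluate(pred, obs)
        assert m.mae <= m.rmse + 1e-12
        assert m.rmse == pytest.approx(math.sqrt(m.mse))
        assert m.r2 <= 1.0


class TestTrainMember:
    def test_linear_labels_tiny_net(self, linear_regression_data):
        """Noiseless linear target: a 1-hidden-unit net reaches the
        target essentially exactly."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(150, 2))
        y = 3.0 * X[:, 0] - 1.0
        m = train_member(X, y, [1], seed=1, max_iter=300, tol=1e-14)
        rmse = float(np.sqrt(np.mean((m.predict(X) - y) ** 2)))
        assert rmse < 1e-3

    def test_linear_model_path_exact(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 4.0
        m = train_member(X, y, [], seed=0, max_iter=100)
        rmse = float(np.sqrt(np.mean((m.predict(X) - y) ** 2)))
        assert rmse < 1e-4

    def test_gamma_bounds_and_stabilization(self, linear_regression_data):
        X, y = linear_regression_data
        m = train_member(X, y, [], seed=0, max_iter=200, tol=1e-10)
        assert 0 <= m.gamma <= m.n_weights
        assert m.converged
        # gamma stabilizes: last update is tiny
        assert abs(m.gamma_history[-1] - m.gamma_history[-2]) < 1e-3

    def test_scaling_invariance(self, linear_regression_data):
        """Affinely rescaling a feature column is absorbed by the input
        standardization: identical fit to numerical precision."""
        X, y = linear_regression_data
        m1 = train_member(X, y, [2], seed=5, max_iter=30)
        X2 = X.copy()
        X2[:, 1] = 100.0 * X2[:, 1] + 7.0
        m2 = train_member(X2, y, [2], seed=5, max_iter=30)
        p1, p2 = m1.predict(X), m2.predict(X2)
        np.testing.assert_allclose(p1, p2, rtol=1e-8, atol=1e-8)

    def test_non_finite_inputs_rejected(self):
        X = np.array([[1.0], [np.inf]])
        with pytest.raises(ValueError):
            train_member(X, np.array([1.0, 2.0]), [1])


def _stub_member(n_features, constant):
    """A member that predicts a constant, for ensemble-averaging checks."""
    return NetworkMember(
        hidden=[], weights=np.zeros(n_features + 1),
        x_center=np.zeros(n_features), x_scale=np.ones(n_features),
        y_center=constant, y_scale=1.0, alpha_reg=0.0, beta_reg=1.0,
        gamma=0.0, seed=0, n_iter=0, converged=True)


class TestEnsemble:
    def test_stub_members_average(self):
        X = np.zeros((5, 11))
        members = [_stub_member(11, 7.9), _stub_member(11, 8.1)]
        np.testing.assert_allclose(predict_members(members, X), 8.0)

    def test_identical_members_equal_member_output(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        y = X[:, 0] + 0.1 * rng.normal(size=20)
        m = train_member(X, y, [2], seed=3, max_iter=20)
        np.testing.assert_allclose(predict_members([m, m, m], X), m.predict(X))

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_ensemble_mse_never_exceeds_mean_member_mse(self, seed):
        """Convexity of squared error under averaging, on arbitrary data."""
        rng = np.random.default_rng(seed)
        preds = rng.normal(size=(10, 30))  # 10 members x 30 points
        obs = rng.normal(size=30)
        ens_mse = np.mean((preds.mean(axis=0) - obs) ** 2)
        member_mse = np.mean((preds - obs) ** 2, axis=1)
        assert ens_mse <= member_mse.mean() + 1e-12

    def test_trained_ensemble_contract(self, small_world):
        training, _, _, _ = small_world
        model = train_ensemble(training, "ph", hidden=[3], seed=10,
                               n_members=3, max_iter=15)
        assert len(model.members) == 3
        assert len(model.member_metrics) == 3
        # all members share one split: identical test observations
        assert model.ensemble_metrics.mse <= np.mean(
            [m.mse for m in model.member_metrics]) + 1e-12
        assert model.ensemble_metrics.rmse == pytest.approx(
            math.sqrt(model.ensemble_metrics.mse))

    def test_train_ensemble_deterministic(self, small_world):
        training, _, _, _ = small_world
        a = train_ensemble(training, "ta", hidden=[2], seed=21,
                           n_members=2, max_iter=10)
        b = train_ensemble(training, "ta", hidden=[2], seed=21,
                           n_members=2, max_iter=10)
        assert a.ensemble_metrics == b.ensemble_metrics
        np.testing.assert_array_equal(a.test_predictions, b.test_predictions)

    def test_zero_noise_linear_world_near_exact(self):
        """An ensemble on noiseless data linear in the predictors
        recovers the target to solver precision."""
        rng = np.random.default_rng(8)
        n = 200
        table = pd.DataFrame({
            "latitude": rng.uniform(42, 42.3, n),
            "longitude": rng.uniform(-9.1, -8.6, n),
            "depth_m": rng.uniform(0, 50, n),
            "temperature_c": rng.uniform(12, 18, n),
            "salinity": rng.uniform(34, 36, n),
            "phosphate_umol_kg": rng.uniform(0, 1, n),
            "nitrate_umol_kg": rng.uniform(0, 10, n),
            "silicate_umol_kg": rng.uniform(0, 10, n),
            "year_decimal": rng.uniform(1990, 2020, n),
            "week": rng.integers(1, 53, n),
            "ta_umol_kg": np.nan,
        })
        table["ph"] = 8.0 + 0.01 * (table["salinity"] - 35.0)
        model = train_ensemble(table, "ph", hidden=[], seed=2, n_members=2,
                               max_iter=100)
        assert model.ensemble_metrics.rmse < 1e-3

    def test_serialization_roundtrip(self, small_world, tmp_path):
        training, prediction, _, _ = small_world
        model = train_ensemble(training, "ph", hidden=[2], seed=1,
                               n_members=2, max_iter=8)
        path = tmp_path / "model.json"
        model.save(path)
        back = brnn.EnsembleModel.load(path)
        head = prediction.head(50)
        np.testing.assert_allclose(back.predict(head), model.predict(head),
                                   rtol=1e-12)

    def test_unknown_target_rejected(self, small_world):
        training, _, _, _ = small_world
        with pytest.raises(ValueError, match="target"):
            train_ensemble(training, "oxygen")
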