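import numpy as np
import pandas as pd
import pytest

from ppgage import (
    FFNNModel,
    LinearAgeModel,
    ParameterError,
    SplitSpec,
    fit_ffnn,
    fit_linear_stepwise,
    hidden_layer_sweep,
    published_model,
    split_indices,
    synthesize_features,
)


class TestPublishedModel:
    def test_intercept_at_zero_features(self):
        pred = published_model().predict({"AI": 0.0, "sum_tdppg_e4": 0.0})
        assert pred[0] == 109.65

    def test_table_mean_point(self):
        pred = published_model().predict({"AI": -1.49, "sum_tdppg_e4": 100.18})
        assert pred[0] == pytest.approx(71.62, abs=0.005)

    def test_unit_ai(self):
        pred = published_model().predict({"AI": 1.0, "sum_tdppg_e4": 0.0})
        assert pred[0] == pytest.approx(131.81)

    def test_missing_feature_rejected(self):
        with pytest.raises(ParameterError):
            published_model().predict({"AI": [0.0]})

    def test_json_round_trip(self, tmp_path):
        m = published_model()
        m.to_json(tmp_path / "m.json")
        back = LinearAgeModel.from_json(tmp_path / "m.json")
        assert back.intercept == m.intercept
        assert back.coefficients == m.coefficients


class TestStepwise:
    def test_constant_ages_select_nothing(self):
        df = synthesize_features(60, seed=1)
        m = fit_linear_stepwise(df, np.full(60, 70.0))
        assert m.coefficients == {}
        assert m.intercept == pytest.approx(70.0)

    def test_single_candidate_exact_fit(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=80)
        df = pd.DataFrame({"x": x})
        m = fit_linear_stepwise(df, 50.0 + 2.0 * x, candidates=["x"])
        assert m.fit_stats["adjusted_r2"] == pytest.approx(1.0)
        assert m.coefficients["x"] == pytest.approx(2.0)

    def test_mean_point_property(self):
        df = synthesize_features(120, seed=4)
        y = df["age"].to_numpy()
        m = fit_linear_stepwise(df, y)
        at_mean = m.predict(df[m.selected_features].mean().to_frame().T)
        assert at_mean[0] == pytest.approx(y.mean(), abs=1e-8)

    def test_thresholds_validated(self):
        df = synthesize_features(60, seed=1)
        with pytest.raises(ParameterError):
            fit_linear_stepwise(df, df["age"], p_enter=0.10, p_remove=0.05)

    def test_too_few_subjects(self):
        df = synthesize_features(8, seed=1)
        with pytest.raises(ParameterError):
            fit_linear_stepwise(df, df["age"])

    def test_recovers_generating_model(self):
        df = synthesize_features(500, seed=0)
        m = fit_linear_stepwise(df, df["age"], candidates=["AI", "sum_tdppg_e4", "T_ab_ms"])
        assert set(m.selected_features) == {"AI", "sum_tdppg_e4"}
        se = m.fit_stats["se"]
        assert abs(m.coefficients["AI"] - 22.16) < 3 * se["AI"]
        assert abs(m.coefficients["sum_tdppg_e4"] + 0.05) < 3 * se["sum_tdppg_e4"]


class TestSplit:
    def test_default_fractions(self):
        s = SplitSpec()
        assert (s.train, s.validation, s.test) == (0.60, 0.20, 0.20)

    def test_partition_is_disjoint_and_complete(self):
        tr, va, te = split_indices(100, SplitSpec(seed=5))
        allidx = np.concatenate([tr, va, te])
        assert sorted(allidx) == list(range(100))
        assert (len(tr), len(va), len(te)) == (60, 20, 20)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ParameterError):
            SplitSpec(train=0.5, validation=0.2, test=0.2)


@pytest.fixture(scope="module")
def linear_data():
    df = synthesize_features(200, seed=7, noise_sd=0.0)
    return df, df["age"].to_numpy()


class TestFFNN:
    def test_noiseless_linear_target_is_learned(self, linear_data):
        df, y = linear_data
        model = fit_ffnn(df, y, seed=1)
        _, _, te = split_indices(len(df), SplitSpec(seed=1))
        mse = float(np.mean((model.predict(df)[te] - y[te]) ** 2))
        assert mse < 1e-3

    def test_determinism(self, linear_data):
        df, y = linear_data
        m1 = fit_ffnn(df, y, seed=2, max_epochs=40)
        m2 = fit_ffnn(df, y, seed=2, max_epochs=40)
        assert np.array_equal(m1.W1, m2.W1)
        assert m1.trace == m2.trace

    def test_training_mse_non_increasing(self, linear_data):
        df, y = linear_data
        m = fit_ffnn(df, y, seed=3, max_epochs=60)
        tr = np.asarray(m.trace["train"])
        assert np.all(np.diff(tr) <= 1e-9 * np.maximum(tr[:-1], 1.0))

    def test_best_epoch_is_validation_argmin(self, linear_data):
        df, y = linear_data
        m = fit_ffnn(df, y, seed=4, max_epochs=60)
        assert m.best_epoch == int(np.argmin(m.trace["validation"]))

    def test_patience_zero_stops_at_first_validation_increase(self, linear_data):
        df, y = linear_data
        m = fit_ffnn(df, y, seed=5, patience=0, max_epochs=200)
        va = m.trace["validation"]
        assert m.best_epoch == int(np.argmin(va))
        increases = [i for i in range(1, len(va)) if va[i] > va[i - 1]]
        if increases:  # training stopped right after the first increase
            assert increases[0] == len(va) - 1

    def test_constant_feature_rejected(self, linear_data):
        df, y = linear_data
        bad = df.copy()
        bad["AI"] = 1.0
        with pytest.raises(ParameterError):
            fit_ffnn(bad, y, seed=0)

    def test_json_round_trip(self, tmp_path, linear_data):
        df, y = linear_data
        m = fit_ffnn(df, y, seed=6, max_epochs=30)
        m.to_json(tmp_path / "ffnn.json")
        back = FFNNModel.from_json(tmp_path / "ffnn.json")
        assert np.allclose(back.predict(df), m.predict(df))

    def test_feature_order_irrelevant(self, linear_data):
        df, y = linear_data
        m = fit_ffnn(df, y, seed=7, max_epochs=30)
        shuffled = df[df.columns[::-1]]
        assert np.allclose(m.predict(shuffled), m.predict(df))


class TestSweep:
    def test_shape_and_reproducibility(self):
        df = synthesize_features(80, seed=9, noise_sd=0.0)
        sizes = list(range(1, 21))
        t1 = hidden_layer_sweep(df, df["age"], sizes, seeds=1, max_epochs=25)
        t2 = hidden_layer_sweep(df, df["age"], sizes, seeds=1, max_epochs=25)
        assert len(t1) == 20
        for col in ("mse_test", "r_train", "r_validation", "r_test", "r_all"):
            assert col in t1.columns
        pd.testing.assert_frame_equal(t1, t2)
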