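"""Model family contracts: determinism, recovery, consensus, architectures."""

from __future__ import annotations

import numpy as np
import pytest

from conjointfp import (
    ModelSpec,
    build_dnn,
    build_lstm,
    consensus_predict,
    load_model,
    predict,
    save_model,
    train,
    train_consensus,
)

FAMILIES = ["rf", "svr", "xgb", "dnn", "lstm"]
FAST_HP = {
    "rf": {"n_estimators": 30},
    "svr": {},
    "xgb": {"n_estimators": 50},
    "dnn": {"width": 40, "epochs": 120, "dropout": 0.0},
    "lstm": {"hidden2": 16, "dense_units": 16, "epochs": 120},
}


@pytest.mark.parametrize("family", FAMILIES)
def test_constant_target_is_recovered(family, random_bit_data):
    X, _, _ = random_bit_data
    y = np.full(X.shape[0], 2.5)
    model = train(ModelSpec(family, hyperparams=FAST_HP[family], seed=0), X, y)
    pred = predict(model, X[:20])
    # SVR's epsilon tube and brief SGD training of the neural nets leave a
    # small residual; tree ensembles recover a constant essentially exactly
    tol = 0.05 if family in ("rf", "xgb") else 0.15
    np.testing.assert_allclose(pred, 2.5, atol=tol)


@pytest.mark.parametrize("family", ["rf", "xgb", "dnn"])
def test_planted_linear_signal_training_error_below_noise_floor(family, random_bit_data):
    """Noiseless linear target in a few bits: flexible models overfit to ~0."""
    X, y, _ = random_bit_data
    model = train(ModelSpec(family, hyperparams=FAST_HP[family], seed=1), X, y)
    rmse_train = float(np.sqrt(np.mean((predict(model, X) - y) ** 2)))
    assert rmse_train < 0.25  # noise_sd would be 0.5; training fit is well below


@pytest.mark.parametrize("family", FAMILIES)
def test_seeded_determinism(family, random_bit_data):
    X, y, _ = random_bit_data
    spec = ModelSpec(family, hyperparams=FAST_HP[family], seed=7)
    p1 = predict(train(spec, X, y), X[:30])
    p2 = predict(train(spec, X, y), X[:30])
    np.testing.assert_allclose(p1, p2, atol=1e-5)  # tree/kernel exact, neural tol


class TestPredictContract:
    def test_empty_matrix_gives_empty_vector(self, random_bit_data):
        X, y, _ = random_bit_data
        model = train(ModelSpec("rf", hyperparams=FAST_HP["rf"]), X, y)
        assert predict(model, np.empty((0, X.shape[1]))).shape == (0,)

    def test_duplicate_rows_get_identical_predictions(self, random_bit_data):
        X, y, _ = random_bit_data
        model = train(ModelSpec("xgb", hyperparams=FAST_HP["xgb"]), X, y)
        dup = np.vstack([X[5], X[5]])
        p = predict(model, dup)
        assert p[0] == p[1]

    def test_width_mismatch_raises(self, random_bit_data):
        X, y, _ = random_bit_data
        model = train(ModelSpec("svr"), X, y)
        with pytest.raises(ValueError, match="columns"):
            predict(model, X[:, :10])

    def test_nonfinite_targets_rejected(self, random_bit_data):
        X, _, _ = random_bit_data
        bad = np.zeros(X.shape[0])
        bad[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            train(ModelSpec("rf"), X, bad)

    def test_dimension_mismatch_rejected(self, random_bit_data):
        X, y, _ = random_bit_data
        with pytest.raises(ValueError):
            train(ModelSpec("rf"), X, y[:-5])


class TestConsensus:
    def test_mean_of_members_elementwise(self, random_bit_data):
        X, y, _ = random_bit_data
        X_m, X_e = X[:, :30], X[:, 30:]
        cm = train_consensus("xgb", X_m, X_e, y, FAST_HP["xgb"], seed=0)
        cons = consensus_predict(cm, X_m, X_e)
        a = predict(cm.member_a, X_m)
        b = predict(cm.member_b, X_e)
        np.testing.assert_array_equal(cons, (a + b) / 2.0)

    def test_identical_members_equal_single_model(self, random_bit_data):
        X, y, _ = random_bit_data
        half = X[:, :30]
        cm = train_consensus("rf", half, half, y, FAST_HP["rf"], seed=3)
        np.testing.assert_allclose(
            consensus_predict(cm, half, half), predict(cm.member_a, half)
        )

    def test_two_point_mean(self, random_bit_data):
        X, y, _ = random_bit_data
        cm = train_consensus("rf", X[:, :30], X[:, 30:], y, FAST_HP["rf"])
        a = predict(cm.member_a, X[:1, :30])
        b = predict(cm.member_b, X[:1, 30:])
        assert consensus_predict(cm, X[:1, :30], X[:1, 30:])[0] == (a[0] + b[0]) / 2

    def test_mismatched_families_rejected(self, random_bit_data):
        from conjointfp.models import ConsensusModel

        X, y, _ = random_bit_data
        a = train(ModelSpec("rf", representation="maccs", hyperparams=FAST_HP["rf"]), X, y)
        b = train(ModelSpec("svr", representation="ecfp"), X, y)
        with pytest.raises(ValueError, match="family"):
            ConsensusModel(member_a=a, member_b=b)

    def test_row_count_mismatch_rejected(self, random_bit_data):
        X, y, _ = random_bit_data
        cm = train_consensus("rf", X[:, :30], X[:, 30:], y, FAST_HP["rf"])
        with pytest.raises(ValueError, match="row count"):
            consensus_predict(cm, X[:5, :30], X[:6, 30:])


class TestLstmArchitecture:
    def test_first_layer_width_equals_input_dimension(self):
        net = build_lstm(2214)
        assert net.layer_widths[0] == 2214

    def test_four_layers_two_lstm_one_dense_one_output(self):
        net = build_lstm(100)
        kinds = [spec.kind for spec in net.layer_specs]
        assert kinds == ["lstm", "lstm", "dense", "dense"]
        assert net.n_layers == 4
        assert net.layer_widths[-1] == 1

    def test_forward_pass_shape(self):
        net = build_lstm(20, {"hidden2": 8, "dense_units": 8})
        out = net.predict(np.zeros((3, 20)))
        assert out.shape == (3,)


class TestDnnArchitecture:
    def test_hidden_width_from_hyperparams(self):
        net = build_dnn(166, {"width": 100, "activation": "relu"})
        assert net.layer_widths[0] == 100

    def test_invalid_activation_rejected(self):
        with pytest.raises(ValueError, match="activation"):
            build_dnn(166, {"activation": "swish"})

    def test_dropout_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="dropout"):
            build_dnn(166, {"dropout": 0.7})

    def test_dropout_zero_inference_deterministic(self, random_bit_data):
        X, y, _ = random_bit_data
        net = build_dnn(X.shape[1], {"width": 20, "dropout": 0.0, "epochs": 5}, seed=0)
        net.fit(X, y, epochs=5)
        np.testing.assert_array_equal(net.predict(X[:10]), net.predict(X[:10]))

    def test_scalar_output_per_row(self):
        net = build_dnn(50, {"width": 10})
        assert net.predict(np.zeros((7, 50))).shape == (7,)


class TestLossHistory:
    @pytest.mark.parametrize("family", ["dnn", "lstm"])
    def test_one_entry_per_epoch_with_validation(self, family, random_bit_data):
        X, y, _ = random_bit_data
        hp = dict(FAST_HP[family], epochs=15)
        model = train(
            ModelSpec(family, hyperparams=hp, seed=0),
            X[:200], y[:200], X_val=X[200:], y_val=y[200:],
        )
        assert len(model.loss_history) == 15
        assert all(v is not None for _, v in model.loss_history)

    def test_running_minimum_is_monotone_nonincreasing(self, random_bit_data):
        X, y, _ = random_bit_data
        model = train(
            ModelSpec("dnn", hyperparams=dict(FAST_HP["dnn"], epochs=40), seed=0), X, y
        )
        train_losses = [t for t, _ in model.loss_history]
        running_min = np.minimum.accumulate(train_losses)
        assert all(np.diff(running_min) <= 0)

    def test_tree_families_have_no_loss_history(self, random_bit_data):
        X, y, _ = random_bit_data
        assert train(ModelSpec("rf", hyperparams=FAST_HP["rf"]), X, y).loss_history is None


class TestSpecAndPersistence:
    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(ValueError, match="not valid"):
            ModelSpec("svr", hyperparams={"n_estimators": 10})

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ModelSpec("gbm")

    @pytest.mark.parametrize("family", ["rf", "dnn"])
    def test_save_load_roundtrip_preserves_predictions(self, family, random_bit_data, tmp_path):
        X, y, _ = random_bit_data
        model = train(ModelSpec(family, hyperparams=FAST_HP[family], seed=1), X, y)
        save_model(model, tmp_path / "bundle")
        back = load_model(tmp_path / "bundle")
        np.testing.assert_array_equal(predict(back, X[:20]), predict(model, X[:20]))
        assert back.spec == model.spec
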