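"""The 1D CNN: single-layer forward oracle, architecture, training behaviour."""

import numpy as np
import pytest

from kinoreg import (
    ConvLayerSpec,
    ModelConfig,
    PairDataset,
    PercentInhibitionCNN,
    build_model,
    conv1d_forward,
)
from kinoreg.cnn import CNNRegressionResults
from kinoreg.dataset import split_dataset
from kinoreg.errors import ConfigurationError, SchemaError, ValidationError


def brute_force_conv(x, w, b, activation):
    """Independent oracle: explicit double loop over positions and kernels."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    K, C, M = w.shape
    L_out = x.shape[1] - M + 1
    out = np.zeros((K, L_out))
    for k in range(K):
        for i in range(L_out):
            acc = b[k]
            for c in range(C):
                for m in range(M):
                    acc += w[k, c, m] * x[c, i + m]
            out[k, i] = max(acc, 0.0) if activation == "relu" else acc
    return out


class TestConv1dForward:
    def test_hand_example(self):
        spec = ConvLayerSpec(weights=[1.0, 0.0], bias=0.0, activation="linear")
        np.testing.assert_allclose(conv1d_forward([1.0, 2.0, 3.0], spec), [[1.0, 2.0]])

    def test_zero_kernel_relu_gives_zeros(self):
        spec = ConvLayerSpec(weights=np.zeros(3), bias=0.0, activation="relu")
        out = conv1d_forward(np.arange(10.0), spec)
        assert np.all(out == 0)

    def test_shift_kernel_reproduces_input(self):
        M = 4
        w = np.zeros(M)
        w[-1] = 1.0
        x = np.arange(12.0)
        out = conv1d_forward(x, ConvLayerSpec(weights=w))
        np.testing.assert_allclose(out[0], x[M - 1 :])

    def test_too_short_input_rejected(self):
        with pytest.raises(ValidationError, match="kernel size"):
            conv1d_forward([1.0, 2.0], ConvLayerSpec(weights=np.ones(3)))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            C = int(rng.integers(1, 4))
            M = int(rng.integers(1, 6))
            L = int(rng.integers(M, 30))
            K = int(rng.integers(1, 5))
            x = rng.normal(size=(C, L))
            w = rng.normal(size=(K, C, M))
            b = rng.normal(size=K)
            act = rng.choice(["relu", "linear"])
            fast = conv1d_forward(x, ConvLayerSpec(weights=w, bias=b, activation=act))
            np.testing.assert_allclose(fast, brute_force_conv(x, w, b, act), atol=1e-6)


class TestBuildModel:
    def test_canonical_architecture_counts_at_full_width(self):
        net = build_model(ModelConfig(), input_width=11308)
        counts = net.architecture_report()["counts"]
        assert (counts["conv_layers"], counts["pooling_layers"], counts["fc_layers"]) == (20, 2, 3)
        assert ModelConfig().is_paper_fidelity

    def test_free_mode_configuration_echo(self):
        cfg = ModelConfig(n_conv_layers=1, pooling_after=(1,), fc_sizes=(8, 1),
                          n_filters=2, learning_rate=0.01)
        counts = build_model(cfg, 32).architecture_report()["counts"]
        assert counts == {"conv_layers": 1, "pooling_layers": 1, "fc_layers": 2}
        assert not cfg.is_paper_fidelity

    def test_same_seed_gives_identical_initial_weights(self):
        cfg = ModelConfig(n_filters=4, fc_sizes=(16, 8, 1), seed=9)
        p1 = build_model(cfg, 64).initial_parameters()
        p2 = build_model(cfg, 64).initial_parameters()
        assert all(np.array_equal(a, b) for a, b in zip(p1, p2))

    def test_different_seed_changes_weights(self):
        cfg1 = ModelConfig(n_filters=4, fc_sizes=(16, 8, 1), seed=9)
        cfg2 = ModelConfig(n_filters=4, fc_sizes=(16, 8, 1), seed=10)
        p1 = build_model(cfg1, 64).initial_parameters()
        p2 = build_model(cfg2, 64).initial_parameters()
        assert any(not np.array_equal(a, b) for a, b in zip(p1, p2))

    def test_too_narrow_input_names_offending_layer(self):
        with pytest.raises(ConfigurationError, match="pooling"):
            # width 1 collapses to zero at the first pooling layer
            build_model(ModelConfig(), input_width=1)

    def test_zero_weight_network_predicts_output_bias(self):
        cfg = ModelConfig(n_filters=2, fc_sizes=(4, 1), n_conv_layers=2,
                          pooling_after=(2,), learning_rate=0.01)
        net = build_model(cfg, 16)
        zeros = [np.zeros_like(p) for p in net.parameters()]
        zeros[-1] = np.array([3.5])  # output bias
        net.set_parameters(zeros)
        pred = net.forward(np.random.default_rng(0).normal(size=(5, 16)))
        np.testing.assert_allclose(pred, 3.5, atol=1e-6)


def _toy_dataset(n=60, width=24, seed=0, with_val=True):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, width))
    y = np.clip(50 + 30 * X[:, 0] - 20 * X[:, 1] + 5 * rng.normal(size=n), 0, 100)
    ds = PairDataset(
        X=X, y=y,
        kinase_id=np.array([f"K{i % 6}" for i in range(n)], dtype=object),
        compound_id=np.array([f"C{i}" for i in range(n)], dtype=object),
        feature_names=[f"f{j}" for j in range(width)],
    )
    ratios = (0.7, 0.15, 0.15) if with_val else (0.85, 0.0, 0.15)
    return split_dataset(ds, ratios=ratios, seed=seed)


_FAST_CFG = dict(n_filters=4, fc_sizes=(32, 16, 1), batch_size=64,
                 target_transform="scale01")


class TestTraining:
    def test_epochs_zero_returns_initialized_model(self):
        ds = _toy_dataset()
        cfg = ModelConfig(epochs=0, learning_rate=1e-3, seed=2, **_FAST_CFG)
        model = PercentInhibitionCNN(ds, cfg)
        init = model.network.initial_parameters()
        res = model.fit()
        assert len(res.history) == 0
        assert all(np.array_equal(a, b) for a, b in zip(res.parameters, init))

    def test_small_set_memorization(self):
        """With enough epochs at an adequate lr the net overfits 50 rows."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 32))
        y = rng.uniform(0, 100, size=50)
        cfg = ModelConfig(learning_rate=1e-3, epochs=500, seed=1, batch_size=50,
                          n_filters=4, fc_sizes=(32, 16, 1), target_transform="scale01")
        res = PercentInhibitionCNN.from_arrays(X, y, config=cfg).fit()
        pred = res.predict(X, use_checkpoint=False)
        train_rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
        assert train_rmse < 0.25 * y.std()

    def test_history_reproducible_for_fixed_seed(self):
        ds = _toy_dataset()
        cfg = ModelConfig(epochs=8, learning_rate=1e-3, seed=3, **_FAST_CFG)
        h1 = PercentInhibitionCNN(ds, cfg).fit().history
        h2 = PercentInhibitionCNN(ds, cfg).fit().history
        np.testing.assert_allclose(h1.train_rmse, h2.train_rmse, atol=1e-6)
        np.testing.assert_allclose(h1.val_rmse, h2.val_rmse, atol=1e-6)

    def test_history_length_matches_epochs(self):
        ds = _toy_dataset()
        cfg = ModelConfig(epochs=5, learning_rate=1e-3, seed=3, **_FAST_CFG)
        res = PercentInhibitionCNN(ds, cfg).fit()
        assert list(res.history.epoch) == [1, 2, 3, 4, 5]

    def test_standardization_statistics_come_from_train_rows_only(self):
        ds = _toy_dataset(n=80, seed=4)
        # shift val/test rows far away; the scaler must not see them
        for part in ("val", "test"):
            ds.X[ds.split == part] += 1000.0
        model = PercentInhibitionCNN(ds, ModelConfig(epochs=0, learning_rate=1e-3, **_FAST_CFG))
        train_rows = ds.X[ds.split == "train"]
        np.testing.assert_allclose(model.scaler.mean, train_rows.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(
            model.scaler.std, np.where(train_rows.std(axis=0) < 1e-8, 1.0,
                                       train_rows.std(axis=0)), atol=1e-12
        )

    def test_divergent_learning_rate_raises_with_diagnostic(self):
        ds = _toy_dataset()
        cfg = ModelConfig(epochs=50, learning_rate=1e12, seed=0, **_FAST_CFG)
        with pytest.raises(RuntimeError, match="learning rate"):
            PercentInhibitionCNN(ds, cfg).fit()

    def test_predict_schema_mismatch_names_widths(self):
        ds = _toy_dataset()
        res = PercentInhibitionCNN(ds, ModelConfig(epochs=1, learning_rate=1e-3, **_FAST_CFG)).fit()
        with pytest.raises(SchemaError, match="expected 24"):
            res.predict(np.zeros((3, 10)))

    def test_distinct_inputs_get_distinct_predictions_after_training(self):
        ds = _toy_dataset(seed=6)
        cfg = ModelConfig(epochs=40, learning_rate=1e-3, seed=6, **_FAST_CFG)
        res = PercentInhibitionCNN(ds, cfg).fit()
        p = res.predict(np.vstack([np.zeros(24), np.ones(24)]))
        assert abs(p[0] - p[1]) > 1e-8

    def test_checkpoint_round_trip(self, tmp_path):
        ds = _toy_dataset(seed=8)
        cfg = ModelConfig(epochs=6, learning_rate=1e-3, seed=8, **_FAST_CFG)
        res = PercentInhibitionCNN(ds, cfg).fit()
        res.save(tmp_path / "ckpt")
        back = CNNRegressionResults.load(tmp_path / "ckpt")
        Xq = np.random.default_rng(1).normal(size=(7, 24))
        np.testing.assert_allclose(back.predict(Xq), res.predict(Xq), atol=1e-6)
        assert back.schema_hash == res.schema_hash

    def test_summary_mentions_architecture(self):
        ds = _toy_dataset()
        res = PercentInhibitionCNN(ds, ModelConfig(epochs=1, learning_rate=1e-3, **_FAST_CFG)).fit()
        text = res.summary()
        assert "conv layers" in text and "RMSprop" in text
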