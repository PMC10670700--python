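"""1D-CNN architecture arithmetic, training loop and gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gastronir.cnn import (
    CNNClassifier,
    CNNRegressor,
    CNNSpec,
    CNNNetwork,
    TrainConfig,
    TrainingDivergedError,
    build_cnn,
    build_cnn_regressor,
    train_cnn,
)


def small_spec(**kw):
    base = dict(input_len=80, n_outputs=3, noise_sigma=0.0, dropout_rate=0.0,
                dense_units=16)
    base.update(kw)
    return CNNSpec(**base)


class TestShapeArithmetic:
    def test_published_shapes_for_1030_input(self):
        spec = CNNSpec(input_len=1030, n_outputs=11)
        assert spec.conv1_len == 999
        assert spec.conv2_len == 968
        assert spec.flatten_size == 15_488
        shapes = dict(spec.layer_shapes())
        assert shapes["gaussian_noise"] == (1030,)
        assert shapes["conv1"] == (999, 8)
        assert shapes["conv2"] == (968, 16)
        assert shapes["flatten"] == (15_488,)
        assert shapes["dense"] == (128,)
        assert shapes["output"] == (11,)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(input_len=st.integers(63, 2000))
    def test_each_valid_convolution_shortens_by_31(self, input_len):
        spec = CNNSpec(input_len=input_len)
        assert spec.conv1_len == input_len - 31
        assert spec.conv2_len == input_len - 62
        assert spec.flatten_size == (input_len - 62) * 16

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            CNNSpec(input_len=62)
        CNNSpec(input_len=63)  # boundary case is valid

    def test_noise_layer_is_shape_preserving(self, rng):
        net = build_cnn(CNNSpec(input_len=1030, noise_sigma=0.05))
        net.initialize(rng)
        X = rng.random((4, 1030), dtype=np.float32)
        z4, _ = net._forward(X, training=True, rng=rng)
        assert z4.shape == (4, 11)
        out = net.predict_output(X)
        assert out.shape == (4, 11)

    def test_regressor_shares_trunk_and_has_one_output(self, rng):
        cls_net = build_cnn(CNNSpec(input_len=200))
        reg_net = build_cnn_regressor(CNNSpec(input_len=200))
        assert reg_net.spec.conv1_len == cls_net.spec.conv1_len
        assert reg_net.spec.conv2_len == cls_net.spec.conv2_len
        assert reg_net.spec.flatten_size == cls_net.spec.flatten_size
        assert reg_net.spec.n_outputs == 1
        reg_net.initialize(rng)
        assert reg_net.predict_output(
            rng.random((3, 200), dtype=np.float32)
        ).shape == (3, 1)


class TestTrainingLoop:
    def test_history_has_one_entry_per_epoch(self, rng):
        X = rng.random((20, 80)).astype(np.float32)
        y = rng.integers(1, 4, size=20)
        net = build_cnn(small_spec())
        _, hist = train_cnn(net, X, y, cfg=TrainConfig(epochs=5, seed=0))
        assert len(hist) == 5
        assert len(hist.train_acc) == 5

    def test_single_epoch_returns_usable_model(self, rng):
        X = rng.random((10, 80)).astype(np.float32)
        y = rng.integers(1, 4, size=10)
        net, hist = train_cnn(build_cnn(small_spec()), X, y,
                              cfg=TrainConfig(epochs=1, seed=0))
        assert len(hist) == 1
        assert net.predict_output(X).shape == (10, 3)

    def test_inference_deterministic(self, rng):
        X = rng.random((12, 80)).astype(np.float32)
        y = rng.integers(1, 4, size=12)
        net, _ = train_cnn(
            build_cnn(small_spec(noise_sigma=0.05, dropout_rate=0.5)),
            X, y, cfg=TrainConfig(epochs=2, seed=0),
        )
        np.testing.assert_array_equal(net.predict_output(X), net.predict_output(X))

    def test_same_seed_reproduces_training(self, rng):
        X = rng.random((16, 80)).astype(np.float32)
        y = rng.integers(1, 4, size=16)
        nets = []
        for _ in range(2):
            net, hist = train_cnn(
                build_cnn(small_spec(noise_sigma=0.05, dropout_rate=0.5)),
                X, y, cfg=TrainConfig(epochs=3, seed=9),
            )
            nets.append((net, hist.train_loss))
        assert nets[0][1] == nets[1][1]
        np.testing.assert_array_equal(
            nets[0][0].predict_output(X), nets[1][0].predict_output(X)
        )

    def test_width_mismatch_rejected(self, rng):
        X = rng.random((10, 90)).astype(np.float32)
        with pytest.raises(ValueError, match="input_len"):
            train_cnn(build_cnn(small_spec()), X, np.ones(10, dtype=int))

    def test_loss_decreases_on_learnable_fixture(self, rng):
        # separable two-class stripes; median over 5 seeds decreases
        X = np.vstack([
            np.tile(np.sin(np.linspace(0, 6, 80)), (10, 1)),
            np.tile(np.cos(np.linspace(0, 6, 80)), (10, 1)),
        ]).astype(np.float32) + 0.01 * rng.random((20, 80), dtype=np.float32)
        y = np.array([1] * 10 + [2] * 10)
        drops = []
        for seed in range(5):
            _, hist = train_cnn(
                build_cnn(small_spec(n_outputs=2)), X, y,
                cfg=TrainConfig(epochs=8, seed=seed),
            )
            drops.append(hist.train_loss[-1] - hist.train_loss[0])
        assert np.median(drops) < 0

    def test_divergence_reported_with_epoch(self, rng):
        X = (1e3 * rng.random((16, 80))).astype(np.float32)
        y = 1e3 * rng.random(16)
        net = build_cnn_regressor(small_spec())
        with pytest.raises(TrainingDivergedError, match="epoch"):
            train_cnn(net, X, y, cfg=TrainConfig(
                learning_rate=1e18, epochs=30, seed=0))


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        # noise/dropout off so the training forward pass is deterministic
        spec = small_spec(input_len=70, n_outputs=3, dense_units=8,
                          conv1_kernels=3, conv2_kernels=4, l1=1e-3, l2=1e-3)
        net = build_cnn(spec)
        net.initialize(rng)
        X = rng.random((4, 70)).astype(np.float32)
        y = np.array([0, 1, 2, 1])
        _, _, grads = net._loss_and_grads(X, y, rng)
        grads = {k: g.copy() for k, g in grads.items()}

        def loss_at():
            l, _, _ = net._loss_and_grads(X, y, rng)
            return l

        # central differences can cross ReLU kinks for early-layer weights,
        # so require a large majority of sampled coordinates to agree
        check = {"W1": 8, "W2": 8, "W3": 8, "W4": 8, "b1": 3, "b3": 3}
        fd_rng = np.random.default_rng(0)
        for name, n_coords in check.items():
            flat = net.params[name].reshape(-1)
            agree = 0
            for _ in range(n_coords):
                i = int(fd_rng.integers(flat.size))
                eps = 3e-3
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss_at()
                flat[i] = orig - eps
                lm = loss_at()
                flat[i] = orig
                fd = (lp - lm) / (2 * eps)
                an = grads[name].reshape(-1)[i]
                agree += abs(an - fd) <= max(2e-3, 0.05 * abs(fd))
            assert agree >= n_coords - 1, name


class TestPersistence:
    def test_save_load_round_trip(self, rng, tmp_path):
        X = rng.random((10, 80)).astype(np.float32)
        y = rng.integers(1, 4, size=10)
        net, _ = train_cnn(build_cnn(small_spec()), X, y,
                           cfg=TrainConfig(epochs=2, seed=0))
        net.save(tmp_path / "model")
        from gastronir.cnn import CNNNetwork

        back = CNNNetwork.load(tmp_path / "model")
        assert back.spec == net.spec
        np.testing.assert_array_equal(back.predict_output(X),
                                      net.predict_output(X))


class TestSklearnWrappers:
    def test_classifier_learns_separable_patterns(self, rng):
        t = np.linspace(0, 4 * np.pi, 80)
        templates = [np.sin(t), np.cos(t), np.sin(2 * t)]
        X = np.vstack([
            tpl + 0.05 * rng.normal(size=80)
            for tpl in templates for _ in range(15)
        ])
        y = np.repeat(["a", "b", "c"], 15)
        clf = CNNClassifier(noise_sigma=0.02, dropout_rate=0.2, dense_units=16,
                            epochs=25, random_state=0)
        clf.fit(X, y)
        assert list(clf.classes_) == ["a", "b", "c"]
        assert np.mean(clf.predict(X) == y) >= 0.95
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-5)

    def test_regressor_standardizes_and_backtransforms(self, rng):
        # noiseless linear map from spectra to target
        basis = rng.normal(size=(3, 80))
        coef = rng.uniform(1, 3, size=(60, 3))
        X = coef @ basis
        X = (X - X.min()) / (X.max() - X.min())  # global scaling keeps levels
        y = 5.0 + 10.0 * coef[:, 0]
        reg = CNNRegressor(noise_sigma=0.0, dropout_rate=0.0, dense_units=16,
                           epochs=60, batch_size=16, random_state=1)
        reg.fit(X, y)
        pred = reg.predict(X)
        r2 = 1 - np.sum((pred - y) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 >= 0.95

    def test_constant_target_rejected(self, rng):
        X = rng.random((10, 80))
        with pytest.raises(ValueError, match="constant"):
            CNNRegressor().fit(X, np.ones(10))

    def test_history_records_validation_curves(self, rng):
        X = rng.random((20, 80))
        y = rng.integers(1, 3, size=20)
        clf = CNNClassifier(dense_units=8, epochs=3, random_state=0)
        clf.fit(X[:15], y[:15], X[15:], y[15:])
        frame = clf.history_.to_frame()
        assert list(frame["epoch"]) == [1, 2, 3]
        assert {"train_loss", "test_loss", "train_acc", "test_acc"} <= set(
            frame.columns
        )
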