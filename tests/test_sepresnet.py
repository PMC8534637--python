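"""Network micro-oracles: activations, SE gating, residual algebra,
build/train/predict contracts, and a finite-difference gradient check."""

import numpy as np
import pytest

from specfresh import (
    ArchitectureConfig,
    SynthConfig,
    TrainConfig,
    activation_eval,
    build_model,
    build_shallow_cnn,
    generate,
    predict,
    train_model,
)
from specfresh.errors import BuildError, ConfigError
from specfresh.sepresnet import (
    ResidualBlock,
    SEBlock,
    StageSpec,
    StemSpec,
    _argmax_fresh,
    _cross_entropy,
    load_model,
    save_model,
    se_recalibrate,
    softmax,
)


def _tiny_arch(activation="elu", se_enabled=True):
    return ArchitectureConfig(
        stem=StemSpec(kernel_size=3, out_channels=3, pool_size=2),
        stages=[StageSpec(4, 3, 2), StageSpec(4, 3, 1)],
        se_reduction_ratio=2,
        se_enabled=se_enabled,
        activation=activation,
    )


class TestActivations:
    def test_sigmoid_symmetry_point(self):
        assert activation_eval("sigmoid", 0.0) == pytest.approx(0.5)

    def test_relu_closed_form(self):
        assert activation_eval("relu", -3.0) == 0.0
        assert activation_eval("relu", 3.0) == 3.0

    def test_elu_negative_branch(self):
        assert activation_eval("elu", -1.0, alpha=1.0) == pytest.approx(
            np.exp(-1.0) - 1.0
        )
        assert activation_eval("elu", 2.5) == 2.5

    def test_elu_alpha_scales_negative_branch(self):
        assert activation_eval("elu", -1.0, alpha=2.0) == pytest.approx(
            2.0 * (np.exp(-1.0) - 1.0)
        )

    def test_unknown_name_is_config_error(self):
        with pytest.raises(ConfigError):
            activation_eval("swish", 1.0)


class TestSEBlock:
    def test_hand_computed_forward(self):
        # 2 channels, length 3, hidden width 1; worked by hand:
        # squeeze z = (2, 4); h = z.W1 + b1 = 2*0.5 - 4*0.25 + 0.1 = 0.1
        # a = relu(h) = 0.1; pre = a*W2 + b2 = (0.1*1+0, 0.1*(-1)+0.2)
        # gates = sigmoid(0.1), sigmoid(0.1)
        x = np.array([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]])
        params = {
            "W1": np.array([[0.5], [-0.25]]),
            "b1": np.array([0.1]),
            "W2": np.array([[1.0, -1.0]]),
            "b2": np.array([0.0, 0.2]),
        }
        out = se_recalibrate(x, params, act_name="relu")
        g1 = 1 / (1 + np.exp(-0.1))
        g2 = 1 / (1 + np.exp(-0.1))
        expected = np.vstack([x[0] * g1, x[1] * g2])
        assert np.allclose(out, expected, atol=1e-6)

    def test_gates_strictly_inside_unit_interval(self, rng):
        se = SEBlock(8, 2, "elu", 1.0, rng)
        se.forward(rng.normal(size=(5, 8, 13)), training=False)
        assert np.all(se.last_gates > 0.0) and np.all(se.last_gates < 1.0)

    def test_forced_gate_identity_limit(self, rng):
        se = SEBlock(4, 2, "elu", 1.0, rng)
        se.params["W2"][:] = 0.0
        se.params["b2"][:] = 50.0  # pre-sigmoid hugely positive -> gates ~ 1
        x = rng.normal(size=(3, 4, 7))
        out = se.forward(x, training=False)
        assert np.allclose(out, x, atol=1e-8)

    def test_reduction_floor_is_one(self, rng):
        se = SEBlock(4, 100, "elu", 1.0, rng)
        assert se.hidden == 1


class TestResidualBlock:
    def test_zeroed_stacked_path_reduces_to_activated_shortcut(self, rng):
        block = ResidualBlock(4, StageSpec(4, 3, 1), 2, True, "elu", 1.0, rng)
        block.bn2.params["gamma"][:] = 0.0  # kill the stacked path at its end
        block.bn2.params["beta"][:] = 0.0
        x = rng.normal(size=(2, 4, 9))
        out = block.forward(x, training=False)
        assert np.allclose(out, activation_eval("elu", x), atol=1e-5)

    def test_stride_one_preserves_length(self, rng):
        block = ResidualBlock(4, StageSpec(4, 3, 1), 2, True, "elu", 1.0, rng)
        out = block.forward(rng.normal(size=(2, 4, 11)), training=False)
        assert out.shape == (2, 4, 11)

    def test_projection_shortcut_halves_length(self, rng):
        block = ResidualBlock(4, StageSpec(8, 3, 2), 2, True, "elu", 1.0, rng)
        out = block.forward(rng.normal(size=(2, 4, 10)), training=False)
        assert out.shape == (2, 8, 5)

    def test_matches_independent_step_by_step_composition(self, rng):
        """Re-derive the block output with naive loops: direct convolution,
        inference BN formula, SE pass, add, activation."""
        block = ResidualBlock(2, StageSpec(2, 3, 1), 1, True, "relu", 1.0, rng)
        x = rng.normal(size=(1, 2, 6))
        # seed running stats so inference BN is non-trivial
        for bn in (block.bn1, block.bn2):
            bn.running_mean = rng.normal(size=2) * 0.1
            bn.running_var = 1.0 + rng.uniform(size=2) * 0.2

        def naive_conv(x1, W, b):
            ci, L = x1.shape
            co, _, k = W.shape
            pad = k // 2
            xp = np.pad(x1, ((0, 0), (pad, pad)))
            out = np.zeros((co, L))
            for o in range(co):
                for pos in range(L):
                    acc = b[o]
                    for c in range(ci):
                        for j in range(k):
                            acc += W[o, c, j] * xp[c, pos + j]
                    out[o, pos] = acc
            return out

        def naive_bn(h, bn):
            out = np.zeros_like(h)
            for c in range(h.shape[0]):
                xhat = (h[c] - bn.running_mean[c]) / np.sqrt(bn.running_var[c] + bn.eps)
                out[c] = bn.params["gamma"][c] * xhat + bn.params["beta"][c]
            return out

        h = naive_conv(x[0], block.conv1.params["W"], block.conv1.params["b"])
        h = naive_bn(h, block.bn1)
        h = np.maximum(h, 0.0)
        h = naive_conv(h, block.conv2.params["W"], block.conv2.params["b"])
        h = naive_bn(h, block.bn2)
        h = se_recalibrate(h, block.se.params, act_name="relu")
        expected = np.maximum(h + x[0], 0.0)
        got = block.forward(x, training=False)[0]
        assert np.allclose(got, expected, atol=1e-5)


class TestBuild:
    def test_softmax_rows_sum_to_one(self, rng):
        model = build_model(ArchitectureConfig.default(), 125, seed=0)
        probs = model.predict_proba(rng.normal(size=(4, 125)))
        assert probs.shape == (4, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_identical_parameters(self):
        m1 = build_model(_tiny_arch(), 40, seed=9)
        m2 = build_model(_tiny_arch(), 40, seed=9)
        for k, v in m1.state_arrays().items():
            assert np.array_equal(v, m2.state_arrays()[k]), k

    def test_doubling_stem_channels_increases_parameter_count(self):
        small = build_model(_tiny_arch(), 40, seed=0).n_parameters
        arch2 = _tiny_arch()
        arch2.stem.out_channels *= 2
        big = build_model(arch2, 40, seed=0).n_parameters
        assert big > small

    def test_parameter_count_is_analytic(self):
        # stem conv 1->3 k3 (3*3+3=12) + stem BN (6)
        # stage1 (in 3 -> 4, stride 2, SE hidden 2, projection):
        #   conv1 3*4*3+4=40, bn1 8, conv2 4*4*3+4=52, bn2 8,
        #   SE (4*2+2)+(2*4+4)=22, proj conv 3*4*1+4=16, proj bn 8 -> 154
        # stage2 (4->4, identity): 52+8+52+8+22 = 142
        # head dense 4*2+2 = 10
        model = build_model(_tiny_arch(), 40, seed=0)
        assert model.n_parameters == (12 + 6) + 154 + 142 + 10

    def test_length_underflow_raises_build_error(self):
        # with 'same' padding only pooling can drive the length to zero
        with pytest.raises(BuildError, match="pool"):
            arch = _tiny_arch()
            arch.stem.pool_size = 64
            build_model(arch, 16, seed=0)

    def test_default_has_eight_stages(self):
        assert len(ArchitectureConfig.default().stages) == 8

    def test_bad_activation_rejected(self):
        with pytest.raises(ConfigError):
            ArchitectureConfig(activation="tanh")

    def test_config_dict_round_trip(self):
        arch = _tiny_arch()
        assert ArchitectureConfig.from_dict(arch.to_dict()).to_dict() == arch.to_dict()


@pytest.fixture(scope="module")
def separable():
    # strong class signal, low noise -> linearly separable in practice
    ds = generate(SynthConfig(n_days=4, samples_per_day_per_class=25,
                              n_wavelengths=40, class_shift=0.5,
                              white_noise_sd=0.002, smooth_noise_sd=0.005,
                              seed=2))
    return ds.X, ds.y()


class TestTraining:
    def test_separable_data_reaches_high_train_accuracy(self, separable):
        X, y = separable
        model = build_model(_tiny_arch(), 40, seed=3)
        cfg = TrainConfig(max_epochs=50, seed=3, batch_size=16,
                          early_stop_patience=None)
        model, hist = train_model(model, X, y, cfg=cfg)
        assert max(hist.train_acc) >= 0.98
        labels, _ = predict(model, X)
        assert np.mean(labels == y) >= 0.95

    def test_zero_epochs_leaves_model_untouched(self, separable):
        X, y = separable
        model = build_model(_tiny_arch(), 40, seed=4)
        before = model.copy_state()
        model, hist = train_model(
            model, X, y, cfg=TrainConfig(max_epochs=0, seed=0)
        )
        assert hist.n_epochs == 0
        for k, v in model.state_arrays().items():
            assert np.array_equal(v, before[k])

    def test_same_seed_bitwise_identical_trajectories(self, separable):
        X, y = separable
        runs = []
        for _ in range(2):
            model = build_model(_tiny_arch(), 40, seed=5)
            _, hist = train_model(
                model, X, y, cfg=TrainConfig(max_epochs=4, seed=7,
                                             early_stop_patience=None)
            )
            runs.append(hist.train_loss)
        assert runs[0] == runs[1]

    def test_single_class_training_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 40))
        model = build_model(_tiny_arch(), 40, seed=0)
        with pytest.raises(ValueError, match="single class"):
            train_model(model, X, np.zeros(10, dtype=int),
                        cfg=TrainConfig(max_epochs=1, seed=0))

    def test_uniform_predictor_cross_entropy_is_ln2(self):
        probs = np.full((8, 2), 0.5)
        y = np.array([0, 1] * 4)
        assert _cross_entropy(probs, y) == pytest.approx(np.log(2.0))


class TestPredict:
    def test_duplicated_rows_identical_outputs(self, rng):
        model = build_model(_tiny_arch(), 40, seed=1)
        x = rng.normal(size=(1, 40))
        X = np.vstack([x, x, x])
        labels, probs = predict(model, X)
        assert np.array_equal(probs[0], probs[1]) and np.array_equal(probs[1], probs[2])
        assert labels[0] == labels[1] == labels[2]

    def test_wavelength_mismatch_raises(self, rng):
        model = build_model(_tiny_arch(), 40, seed=1)
        with pytest.raises(ValueError, match="wavelength"):
            predict(model, rng.normal(size=(2, 39)))

    def test_probability_ties_resolve_to_fresh(self):
        probs = np.array([[0.5, 0.5], [0.6, 0.4], [0.4, 0.6]])
        assert list(_argmax_fresh(probs)) == [1, 0, 1]

    def test_softmax_invariant_to_logit_shift(self, rng):
        z = rng.normal(size=(3, 2))
        assert np.allclose(softmax(z), softmax(z + 100.0), atol=1e-12)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """End-to-end analytic gradients vs central differences on a tiny
        network (absolute tolerance; gradients of conv biases feeding BN
        are exactly zero)."""
        arch = _tiny_arch()
        model = build_model(arch, 12, seed=7)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 12))
        y = np.array([0, 1, 0, 1, 1])

        def loss():
            return _cross_entropy(softmax(model.forward_logits(X, training=True)), y)

        probs = softmax(model.forward_logits(X, training=True))
        g = probs.copy()
        g[np.arange(5), y] -= 1.0
        model.backward(g / 5)
        checked = 0
        for layer in model.layers():
            for key, w in layer.params.items():
                flat, gflat = w.reshape(-1), layer.grads[key].reshape(-1)
                for j in range(0, flat.size, max(1, flat.size // 3)):
                    old = flat[j]
                    flat[j] = old + 1e-6
                    lp = loss()
                    flat[j] = old - 1e-6
                    lm = loss()
                    flat[j] = old
                    assert abs((lp - lm) / 2e-6 - gflat[j]) < 1e-6
                    checked += 1
        assert checked > 30


class TestVariants:
    def test_se_disabled_model_has_fewer_parameters(self):
        with_se = build_model(_tiny_arch(se_enabled=True), 40, seed=0)
        without = build_model(_tiny_arch(se_enabled=False), 40, seed=0)
        assert without.n_parameters < with_se.n_parameters

    def test_all_activations_build_and_train(self):
        ds = generate(SynthConfig(n_days=3, samples_per_day_per_class=4,
                                  n_wavelengths=24, seed=6))
        for act in ("sigmoid", "relu", "elu"):
            model = build_model(_tiny_arch(activation=act), 24, seed=0)
            _, hist = train_model(
                model, ds.X, ds.y(),
                cfg=TrainConfig(max_epochs=2, seed=1, early_stop_patience=None),
            )
            assert hist.n_epochs == 2

    def test_shallow_cnn_builds_and_predicts(self, rng):
        model = build_shallow_cnn(40, seed=0)
        probs = model.predict_proba(rng.normal(size=(3, 40)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestPersistence:
    def test_checkpoint_round_trip(self, tmp_path, rng):
        ds = generate(SynthConfig(n_days=3, samples_per_day_per_class=4,
                                  n_wavelengths=24, seed=6))
        model = build_model(_tiny_arch(), 24, seed=2)
        model, _ = train_model(model, ds.X, ds.y(),
                               cfg=TrainConfig(max_epochs=2, seed=3,
                                               early_stop_patience=None))
        path = save_model(model, tmp_path / "model.npz")
        restored = load_model(path)
        X = rng.normal(size=(5, 24))
        assert np.array_equal(model.predict_proba(X), restored.predict_proba(X))
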