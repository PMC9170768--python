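import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ocrdenovo as o
from ocrdenovo.data import LabeledDataset
from ocrdenovo.nn import (
    CNNModel,
    ModelSpec,
    apply_dropout,
    bce_loss,
    build_model,
    load_model,
    predict_proba,
    relu,
    save_model,
    sigmoid,
    train_model,
)

TINY = ModelSpec(
    conv1_filters=4, conv1_width=5, conv2_filters=3, conv2_width=3,
    fc_units=8, dropout_p=0.0, input_length=20, epochs=20, seed=7,
    batch_size=8,
)


class TestActivations:
    @pytest.mark.parametrize("x,expected", [(-3.0, 0.0), (2.5, 2.5), (0.0, 0.0)])
    def test_relu(self, x, expected):
        assert relu(x) == expected

    def test_sigmoid_midpoint_and_saturation(self):
        assert sigmoid(0.0) == 0.5
        assert sigmoid(1000.0) == pytest.approx(1.0)
        assert sigmoid(-1000.0) == pytest.approx(0.0)

    @given(st.floats(-50, 50))
    def test_sigmoid_symmetry(self, z):
        assert sigmoid(z) + sigmoid(-z) == pytest.approx(1.0)


class TestBCE:
    def test_uniform_predictor_is_ln2(self):
        y = np.array([0, 1, 0, 1])
        assert bce_loss(np.full(4, 0.5), y) == pytest.approx(math.log(2))

    def test_hand_computed_value(self):
        loss = bce_loss(np.array([0.9, 0.2]), np.array([1, 0]))
        assert loss == pytest.approx(-(math.log(0.9) + math.log(0.8)) / 2)
        assert loss == pytest.approx(0.1643, abs=5e-5)

    def test_perfect_fit_near_zero(self):
        assert bce_loss(np.array([1.0, 0.0]), np.array([1, 0])) < 1e-6

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bce_loss(np.array([0.5]), np.array([1, 0]))


class TestDropout:
    def test_p_zero_is_identity_both_modes(self):
        x = np.arange(10.0)
        assert np.array_equal(apply_dropout(x, 0.0, "train"), x)
        assert np.array_equal(apply_dropout(x, 0.0, "infer"), x)

    def test_infer_mode_identity(self):
        x = np.arange(10.0)
        assert np.array_equal(apply_dropout(x, 0.9, "infer"), x)

    def test_expected_value_preserved(self):
        """Inverted rescaling keeps the mean activation within 2% of identity."""
        rng = np.random.default_rng(0)
        x = np.ones(10_000)
        means = [apply_dropout(x, 0.6, "train", rng).mean() for _ in range(100)]
        assert abs(np.mean(means) - 1.0) < 0.02

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            apply_dropout(np.ones(3), 1.0, "train")


class TestBuildModel:
    def test_forward_returns_probability(self):
        spec = ModelSpec(input_length=36, epochs=1)
        model = build_model(spec)
        rng = np.random.default_rng(0)
        x = np.eye(4)[rng.integers(0, 4, 36)].T[None]
        p = predict_proba(model, x)
        assert p.shape == (1,) and 0.0 < p[0] < 1.0

    def test_parameter_count_hand_computed(self):
        # conv1: 2 filters x (4x3)+2b = 26; map 8-3+1=6
        # conv2: 2 x (2x2)+2b = 10; map 6-2+1=5; flatten 2x5=10
        # fc: 4x10+4b = 44; out: 1x4+1b = 5; total 85
        spec = ModelSpec(conv1_filters=2, conv1_width=3, conv2_filters=2,
                         conv2_width=2, fc_units=4, input_length=8)
        assert spec.n_parameters == 85
        model = build_model(spec)
        assert sum(p.size for p in model.params.values()) == 85

    def test_no_dropout_training_forward_is_deterministic(self):
        model = build_model(TINY)
        rng = np.random.default_rng(0)
        x = np.eye(4)[rng.integers(0, 4, 20)].T[None]
        p1, _ = model.forward(x, train=True, rng=np.random.default_rng(1))
        p2, _ = model.forward(x, train=True, rng=np.random.default_rng(2))
        assert np.array_equal(p1, p2)

    def test_conv_wider_than_feature_map_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(conv1_width=30, conv2_width=11, input_length=36)


class TestGradients:
    def test_backward_matches_numerical_gradient(self):
        """Analytic gradients agree with central differences for every
        parameter tensor (dense random input keeps ReLU away from kinks)."""
        spec = ModelSpec(conv1_filters=3, conv1_width=3, conv2_filters=2,
                         conv2_width=2, fc_units=5, dropout_p=0.0,
                         input_length=10, seed=1)
        m = build_model(spec)
        rng = np.random.default_rng(0)
        for k in m.params:  # nonzero biases keep pre-activations off zero
            m.params[k] = m.params[k] + 0.05 * rng.standard_normal(m.params[k].shape)
        X = rng.uniform(0.1, 1.0, size=(4, 4, 10))
        y = np.array([1.0, 0.0, 1.0, 0.0])
        probs, cache = m.forward(X, train=False)
        grads = m.backward(probs, y, cache)
        eps = 1e-6
        for k, P in m.params.items():
            flat = P.ravel()
            num = np.zeros_like(flat)
            for i in range(flat.size):
                old = flat[i]
                flat[i] = old + eps
                lp = bce_loss(m.forward(X)[0], y)
                flat[i] = old - eps
                lm = bce_loss(m.forward(X)[0], y)
                flat[i] = old
                num[i] = (lp - lm) / (2 * eps)
            assert np.allclose(num, grads[k].ravel(), atol=1e-7), k


def _toy_dataset():
    """Identical positives vs a few fixed distinct negatives (separable)."""
    pos = "ACGTTTACGGACGTTTACGG"
    negs = ["TTTTACACACGTGTGTAAAA", "GGGGCACACATTTTACGTAC",
            "CCCCGTGTGTAAAACGTACG", "AAAACACACAGGGGTACGTC",
            "GTGTGTCACATTTTGCATGC", "TGCATGCAAACCCCGGGGTT"]
    ids, seqs, labels, pids, parts = [], [], [], [], []
    k = 0
    for i in range(12):
        for lab, s in ((1, pos), (0, negs[i % len(negs)])):
            ids.append(f"{'p' if lab else 'n'}{k}")
            seqs.append(s)
            labels.append(lab)
            pids.append(i)
            parts.append("train" if i < 9 else "validation")
            k += 1
    return LabeledDataset(ids, seqs, np.array(labels), parts, np.array(pids), 20)


class TestTraining:
    def test_separable_toy_reaches_full_training_accuracy(self):
        model = train_model(TINY, _toy_dataset())
        assert max(model.history["train_acc"]) == 1.0

    def test_training_loss_mostly_non_increasing(self):
        model = train_model(TINY, _toy_dataset())
        losses = model.history["train_loss"]
        drops = sum(b <= a for a, b in zip(losses, losses[1:]))
        assert drops / (len(losses) - 1) >= 0.8

    def test_same_seed_reproduces_validation_loss(self):
        m1 = train_model(TINY, _toy_dataset())
        m2 = train_model(TINY, _toy_dataset())
        assert m1.history["val_loss"] == m2.history["val_loss"]

    def test_history_length_matches_epochs(self):
        model = train_model(TINY, _toy_dataset())
        assert len(model.history["val_loss"]) == TINY.epochs

    def test_fragment_length_mismatch_rejected(self):
        spec = ModelSpec(conv1_filters=2, conv1_width=3, conv2_filters=2,
                         conv2_width=2, input_length=30)
        with pytest.raises(ValueError, match="input_length"):
            train_model(spec, _toy_dataset())


class TestPredict:
    def test_outputs_in_unit_interval_and_repeatable(self):
        model = train_model(TINY, _toy_dataset())
        X, _ = _toy_dataset().encoded()
        p1 = predict_proba(model, X)
        p2 = predict_proba(model, X)
        assert np.all((p1 > 0) & (p1 < 1))
        assert np.array_equal(p1, p2)

    def test_shape_mismatch(self):
        model = build_model(TINY)
        with pytest.raises(ValueError):
            predict_proba(model, np.zeros((2, 4, 33)))


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        model = train_model(TINY, _toy_dataset())
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        assert back.spec == model.spec
        assert back.trained
        assert back.history == model.history
        X, _ = _toy_dataset().encoded()
        assert np.array_equal(predict_proba(back, X), predict_proba(model, X))
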