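"""The autodiff core, the two network architectures, and training behavior."""

import copy

import numpy as np
import pytest

from ictalkit.models import (
    MultigroupConfig,
    TrainingConfig,
    build_binary_cnn,
    build_multigroup_model,
    load_model,
    pipeline_predict,
    predict_proba,
    save_model,
    train_model,
)
from ictalkit.nn import autodiff as ad
from ictalkit.nn.autodiff import Tensor


def _numgrad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


class TestAutodiff:
    """Backward passes agree with central finite differences."""

    rng = np.random.default_rng(0)

    def test_conv2d_gradients(self):
        x = Tensor(self.rng.normal(size=(2, 3, 5, 4)), requires_grad=True)
        w = Tensor(self.rng.normal(size=(4, 3, 3, 3)), requires_grad=True)
        b = Tensor(self.rng.normal(size=4), requires_grad=True)
        loss = ad.sum_all(ad.mul(ad.conv2d(x, w, b), ad.conv2d(x, w, b)))
        loss.backward()

        def f():
            return float(
                (ad.conv2d(Tensor(x.data), Tensor(w.data), Tensor(b.data)).data ** 2)
                .sum()
            )

        for tensor in (x, w, b):
            np.testing.assert_allclose(tensor.grad, _numgrad(f, tensor.data),
                                       atol=1e-5)

    def test_maxpool_gradients(self):
        x = Tensor(self.rng.normal(size=(2, 2, 5, 6)), requires_grad=True)
        ad.sum_all(ad.mul(ad.maxpool2x2(x), ad.maxpool2x2(x))).backward()

        def f():
            return float((ad.maxpool2x2(Tensor(x.data)).data ** 2).sum())

        np.testing.assert_allclose(x.grad, _numgrad(f, x.data), atol=1e-6)

    def test_batchnorm_gradients_train_mode(self):
        x = Tensor(self.rng.normal(size=(4, 3, 2, 2)), requires_grad=True)
        g = Tensor(self.rng.normal(size=3) + 1, requires_grad=True)
        b = Tensor(self.rng.normal(size=3), requires_grad=True)
        run = {"mean": np.zeros(3), "var": np.ones(3)}
        out = ad.batchnorm(x, g, b, copy.deepcopy(run), train=True)
        ad.sum_all(ad.mul(out, out)).backward()

        def f():
            o = ad.batchnorm(Tensor(x.data), Tensor(g.data), Tensor(b.data),
                             copy.deepcopy(run), train=True)
            return float((o.data**2).sum())

        for tensor in (x, g, b):
            np.testing.assert_allclose(tensor.grad, _numgrad(f, tensor.data),
                                       atol=1e-5)

    def test_weighted_cross_entropy_gradients_and_zero_weight(self):
        logits = Tensor(self.rng.normal(size=(5, 3)), requires_grad=True)
        y = np.array([0, 1, 2, 1, 0])
        w = np.array([1.0, 2.0, 1.0, 0.0, 1.0])
        loss = ad.softmax_cross_entropy(logits, y, w)
        loss.backward()

        def f():
            return float(ad.softmax_cross_entropy(Tensor(logits.data), y, w).data)

        np.testing.assert_allclose(logits.grad, _numgrad(f, logits.data),
                                   atol=1e-8)
        # a zero-weight sample contributes no gradient at all
        assert np.abs(logits.grad[3]).max() == 0.0

    def test_no_grad_builds_constant_tensors(self):
        x = Tensor(self.rng.normal(size=(2, 2)), requires_grad=True)
        with ad.no_grad():
            out = ad.relu(ad.matmul(x, x))
        assert not out.requires_grad


class TestArchitectures:
    def test_binary_cnn_shape_algebra(self):
        model = build_binary_cnn((21, 33, 8), seed=0)
        # 33x8 -> 16x4 -> 8x2 -> 4x1 at 64 channels: flatten width 256
        assert model.net.flat_width == 256
        p = model.predict_proba(np.random.default_rng(0).normal(size=(3, 21, 33, 8)))
        assert p.shape == (3, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_multigroup_output_shape_and_probabilities(self):
        model = build_multigroup_model((21, 33, 8), seed=0)
        p = model.predict_proba(np.random.default_rng(1).normal(size=(2, 21, 33, 8)))
        assert p.shape == (2, 8)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_collapsing_input_rejected(self):
        with pytest.raises(ValueError, match="collaps"):
            build_binary_cnn((4, 5, 5), seed=0)

    def test_duplicate_inputs_identical_rows(self):
        model = build_binary_cnn((3, 33, 8), seed=1)
        x = np.random.default_rng(2).normal(size=(3, 33, 8))
        p = model.predict_proba(np.stack([x, x]))
        np.testing.assert_allclose(p[0], p[1])

    def test_shape_mismatch_rejected(self):
        model = build_binary_cnn((3, 33, 8), seed=1)
        with pytest.raises(ValueError, match="shape"):
            model.predict_proba(np.zeros((1, 4, 33, 8)))

    def test_input_gradient_shape_and_class_specificity(self):
        model = build_binary_cnn((3, 33, 8), seed=3)
        x = np.random.default_rng(3).normal(size=(1, 3, 33, 8))
        g0 = model.input_gradient(x, 0)
        g1 = model.input_gradient(x, 1)
        assert g0.shape == x.shape
        assert not np.allclose(g0, g1)
        with pytest.raises(IndexError):
            model.input_gradient(x, 5)


def _toy_separable(n_per_class=30, seed=0):
    """Two classes with disjoint active frequency rows: linearly separable."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for label, rows in (("bckg", slice(0, 10)), ("seiz", slice(20, 30))):
        for _ in range(n_per_class):
            x = rng.normal(0, 0.1, size=(3, 33, 8))
            x[:, rows, :] += 2.0
            xs.append(x)
            ys.append(label)
    return np.array(xs), ys


class TestTraining:
    def test_learns_separable_toy_problem(self):
        x, y = _toy_separable()
        model = build_binary_cnn((3, 33, 8), seed=0)
        _, hist = train_model(model, (x, y), None,
                              TrainingConfig(epochs=20, seed=0))
        assert hist[-1]["train_accuracy"] >= 0.95
        assert len(hist) == 20

    def test_history_records_validation(self):
        x, y = _toy_separable(10)
        model = build_binary_cnn((3, 33, 8), seed=0)
        _, hist = train_model(model, (x, y), (x[:8], y[:8]),
                              TrainingConfig(epochs=2, seed=0))
        assert len(hist) == 2
        for key in ("val_loss", "val_accuracy", "val_auc", "val_recall"):
            assert key in hist[-1]

    def test_training_deterministic_given_seed(self):
        x, y = _toy_separable(8)
        runs = []
        for _ in range(2):
            model = build_binary_cnn((3, 33, 8), seed=5)
            _, hist = train_model(model, (x, y), None,
                                  TrainingConfig(epochs=3, seed=5))
            runs.append(hist[-1]["train_loss"])
        assert runs[0] == runs[1]

    def test_empty_training_set_rejected(self):
        model = build_binary_cnn((3, 33, 8), seed=0)
        with pytest.raises(ValueError, match="empty"):
            train_model(model, (np.zeros((0, 3, 33, 8)), []), None,
                        TrainingConfig(epochs=1))

    def test_unknown_labels_rejected(self):
        x, _ = _toy_separable(2)
        model = build_binary_cnn((3, 33, 8), seed=0)
        with pytest.raises(ValueError, match="outside"):
            train_model(model, (x[:2], ["what", "seiz"]), None,
                        TrainingConfig(epochs=1))

    def test_save_load_round_trip(self, tmp_path):
        x, y = _toy_separable(5)
        model = build_binary_cnn((3, 33, 8), seed=0)
        train_model(model, (x, y), None, TrainingConfig(epochs=1, seed=0))
        path = tmp_path / "m.npz"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_allclose(back.predict_proba(x[:4]),
                                   model.predict_proba(x[:4]))
        assert back.class_labels == model.class_labels


class TestPipeline:
    def test_binary_gate_routes_windows(self):
        """Only windows the detector flags as seizure reach the typer."""
        rng = np.random.default_rng(4)
        xs, y = [], []
        for label, rows in (("bckg", slice(0, 10)), ("seiz", slice(20, 30))):
            for _ in range(15):
                x = rng.normal(0, 0.1, size=(8, 33, 8))
                x[:, rows, :] += 2.0
                xs.append(x)
                y.append(label)
        x = np.array(xs)
        binary = build_binary_cnn((8, 33, 8), seed=0)
        train_model(binary, (x, y), None, TrainingConfig(epochs=15, seed=0))
        mg = build_multigroup_model((8, 33, 8), MultigroupConfig(n_out=8), seed=0)
        out = pipeline_predict(binary, mg, x)
        binary_pred = binary.predict(x)
        for o, b in zip(out, binary_pred):
            if b == "bckg":
                assert o == "bckg"
            else:
                assert o in mg.class_labels

    def test_predict_proba_functional_wrapper(self):
        model = build_binary_cnn((3, 33, 8), seed=0)
        x = np.random.default_rng(1).normal(size=(2, 3, 33, 8))
        np.testing.assert_allclose(predict_proba(model, x),
                                   model.predict_proba(x))
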