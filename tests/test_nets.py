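"""Architecture specs: shape chains, parameter counts, training contracts."""

import numpy as np
import pytest

from rotordetect import nn, nets
from rotordetect.nets import (
    AticnnSpec,
    CrnnSpec,
    SimpleSpec,
    TrainConfig,
    build,
    forward_shapes,
    predict,
    train,
)


def shape_of(shapes, name):
    return dict(shapes)[name]


class TestCrnnShapeChain:
    def test_unipolar_reference_input(self):
        shapes = forward_shapes(CrnnSpec(), (1250, 20))
        assert shape_of(shapes, "zero_pad") == (1324, 20, 1)
        assert shape_of(shapes, "pool1") == (662, 19, 32)
        assert shape_of(shapes, "pool2") == (220, 6, 64)
        assert shape_of(shapes, "pool3") == (55, 1, 64)
        assert shape_of(shapes, "recurrent_input") == (55, 64)
        assert shape_of(shapes, "gru1") == (55, 32)
        assert shape_of(shapes, "gru2") == (32,)
        assert shape_of(shapes, "dense") == (1,)

    def test_bipolar_electrode_axis_chain(self):
        shapes = forward_shapes(CrnnSpec(), (1250, 15))
        assert shape_of(shapes, "zero_pad") == (1324, 15, 1)
        assert shape_of(shapes, "pool1")[1] == 14
        assert shape_of(shapes, "pool2")[1] == 4
        assert shape_of(shapes, "pool3") == (55, 1, 64)

    def test_short_window_time_chain(self):
        shapes = forward_shapes(CrnnSpec(), (250, 20))
        assert shape_of(shapes, "zero_pad")[0] == 324
        assert shape_of(shapes, "pool1")[0] == 162
        assert shape_of(shapes, "pool2")[0] == 54
        assert shape_of(shapes, "pool3")[0] == 13

    def test_too_few_electrodes_rejected(self):
        # 2 electrodes survive pool1 as a single column; pool2 (3x3) fails
        with pytest.raises(ValueError):
            forward_shapes(CrnnSpec(), (250, 2))

    def test_built_model_matches_closed_form(self):
        model = build(CrnnSpec(), (250, 20), seed=0)
        x = np.random.default_rng(0).random((2, 250, 20, 1), dtype=np.float32)
        model.forward(x, training=False)
        actual = {s[1:] for s in model.last_shapes}
        for name in ("zero_pad", "pool1", "pool2", "pool3", "gru1", "gru2"):
            want = shape_of(forward_shapes(CrnnSpec(), (250, 20)), name)
            assert want in actual, f"{name} {want} missing from forward shapes"

    def test_kernel_orientation_flag(self):
        a = CrnnSpec()
        b = CrnnSpec(time_major_kernel=False)
        assert a.kernel_hw == (23, 5) and b.kernel_hw == (5, 23)
        # shape chain identical under size-preserving convolution
        assert forward_shapes(a, (1250, 15)) == forward_shapes(b, (1250, 15))


class TestSimpleSpec:
    def test_parameter_count_for_flattened_input(self):
        model = build(SimpleSpec(), (1250, 20), seed=0)
        expected = (25_000 * 128 + 128) + (128 * 64 + 64) + (64 * 1 + 1)
        assert model.n_params == expected

    def test_exactly_three_dense_layers(self):
        model = build(SimpleSpec(), (100, 4), seed=0)
        assert sum(isinstance(l, nn.Dense) for l in model.layers) == 3


class TestAticnnSpec:
    def test_thirteen_conv_layers_two_lstm(self):
        spec = AticnnSpec()
        assert spec.n_conv_layers == 13
        model = build(spec, (128, 15), seed=0)
        assert sum(isinstance(l, nn.Conv2D) for l in model.layers) == 13
        assert sum(isinstance(l, nn.LSTM) for l in model.layers) == 2

    def test_outputs_are_probabilities(self):
        model = build(AticnnSpec(), (64, 15), seed=0)
        x = np.random.default_rng(1).random((3, 64, 1, 15), dtype=np.float32)
        p = model.predict_proba(x)
        assert p.shape == (3,) and np.all((p >= 0) & (p <= 1))


class TestBuildContracts:
    def test_seeded_initialization_is_reproducible(self):
        a = build(CrnnSpec(), (250, 15), seed=42)
        b = build(CrnnSpec(), (250, 15), seed=42)
        for (pa, _), (pb, _) in zip(a.param_grad_pairs(), b.param_grad_pairs()):
            assert np.array_equal(pa, pb)

    def test_probabilities_in_unit_interval(self):
        model = build(CrnnSpec(), (250, 20), seed=3)
        x = np.random.default_rng(2).random((2, 250, 20, 1), dtype=np.float32)
        p = model.predict_proba(x)
        assert np.all((p >= 0) & (p <= 1))


class TestTrainAndPredict:
    def _toy_set(self, n, rng, t=40, c=4):
        """Separable toy windows: positives carry a strong low channel."""
        x = rng.random((n, t, c)).astype(np.float32)
        y = (rng.random(n) < 0.5).astype(float)
        x[y == 1, :, 0] += 1.0
        return x, y

    def test_simple_model_fits_separable_set(self):
        rng = np.random.default_rng(0)
        x, y = self._toy_set(200, rng)
        xv, yv = self._toy_set(60, rng)
        model = build(SimpleSpec(), (40, 4), seed=0)
        cfg = TrainConfig(lr_grid=(1e-3,), epochs=30, patience=30, seed=0)
        model, hist = train(model, (x, y), (xv, yv), cfg)
        acc = np.mean((model.predict_proba(x) >= 0.5) == y)
        assert acc >= 0.95
        assert hist["best_lr"] == 1e-3

    def test_first_loss_near_chance_level(self):
        # before any update, label-independent inputs and near-0.5 outputs
        # put the cross-entropy at ~ln 2 on balanced labels
        rng = np.random.default_rng(5)
        x = rng.random((64, 40, 4)).astype(np.float32)  # no class signal
        y = np.r_[np.ones(32), np.zeros(32)]
        model = build(SimpleSpec(), (40, 4), seed=1)
        z = model.predict_logits(x)
        z = z - z.mean()
        assert nn.bce_with_logits(z, y) == pytest.approx(np.log(2.0), abs=0.1)
        assert nn.bce_with_logits(np.zeros_like(z), y) == pytest.approx(
            np.log(2.0)
        )

    def test_training_is_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        x, y = self._toy_set(96, rng)
        xv, yv = self._toy_set(32, rng)
        accs = []
        for _ in range(2):
            model = build(SimpleSpec(), (40, 4), seed=7)
            cfg = TrainConfig(lr_grid=(1e-3,), epochs=3, patience=3, seed=7)
            _, hist = train(model, (x, y), (xv, yv), cfg)
            accs.append(hist["best_val_accuracy"])
        assert accs[0] == accs[1]

    def test_lr_grid_selects_best(self):
        rng = np.random.default_rng(3)
        x, y = self._toy_set(120, rng)
        xv, yv = self._toy_set(40, rng)
        model = build(SimpleSpec(), (40, 4), seed=2)
        cfg = TrainConfig(lr_grid=(1e-2, 1e-4), epochs=4, patience=4, seed=2)
        _, hist = train(model, (x, y), (xv, yv), cfg)
        assert hist["best_lr"] in (1e-2, 1e-4)
        assert set(hist["lr"]) == {1e-2, 1e-4}

    def test_predict_threshold_extremes(self):
        rng = np.random.default_rng(1)
        model = build(SimpleSpec(), (40, 4), seed=0)
        x, _ = self._toy_set(10, rng)
        labels0, probs = predict(model, x, threshold=0.0)
        assert labels0.sum() == 10  # every p >= 0
        labels1, _ = predict(model, x, threshold=1.0 + 1e-9)
        assert labels1.sum() == 0
        assert np.all((probs >= 0) & (probs <= 1))

    def test_probabilities_invariant_to_batch_partition(self):
        rng = np.random.default_rng(4)
        model = build(SimpleSpec(), (40, 4), seed=0)
        x, _ = self._toy_set(50, rng)
        a = model.predict_proba(x, batch_size=7)
        b = model.predict_proba(x, batch_size=50)
        assert np.allclose(a, b, atol=1e-6)

    def test_empty_sets_rejected(self):
        model = build(SimpleSpec(), (40, 4), seed=0)
        with pytest.raises(ValueError):
            train(model, (np.empty((0, 40, 4)), np.empty(0)),
                  (np.empty((0, 40, 4)), np.empty(0)), TrainConfig())

    def test_empty_lr_grid_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_grid=())
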