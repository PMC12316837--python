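"""Network architecture arithmetic, gradients, inference properties."""

import numpy as np
import pytest

from hotspotmon import ArchitectureSpec, LayerSpec, build_model, default_architecture, predict
from hotspotmon.hotspot_net import bce_loss, decoder_kernels, load_checkpoint, save_checkpoint
from hotspotmon.nn_core import BatchNorm2D, Conv2D, TransposedConv2D, Upsample2x


def test_default_full_scale_spec_reaches_50():
    spec = default_architecture(in_channels=32, in_size=16, out_size=50, width=64)
    trace = spec.size_trace()
    assert trace[0] == 16 and trace[-1] == 50
    # one upsample doubles 16 -> 32; decoder kernels grow 32 -> 50
    assert 32 in trace
    kernels = [l.kernel for l in spec.layers if l.kind == "tconv"]
    assert kernels == [5, 5, 5, 4, 4]


def test_spec_missing_target_size_rejected():
    spec = default_architecture(32, 16, 50, 8)
    broken = ArchitectureSpec(32, 16, 50, spec.layers[:-2] + (LayerSpec("output"),))
    with pytest.raises(ValueError, match="47"):
        broken.size_trace()


def test_overshooting_spec_names_offending_layer():
    layers = (LayerSpec("tconv", 4, 40), LayerSpec("output"))
    with pytest.raises(ValueError, match="overshoot"):
        ArchitectureSpec(2, 16, 50, layers).size_trace()


def test_transposed_conv_growth_arithmetic():
    rng = np.random.default_rng(0)
    layer = TransposedConv2D(2, 3, 5, rng)
    assert layer.out_size(32) == 36
    y = layer.forward(np.zeros((1, 2, 32, 32), dtype=np.float32), train=True)
    assert y.shape == (1, 3, 36, 36)


def test_decoder_kernel_planner_covers_growth():
    assert decoder_kernels(32, 50, 5) == [5, 5, 5, 4, 4]
    assert sum(k - 1 for k in decoder_kernels(8, 24, 4)) == 16
    with pytest.raises(ValueError):
        decoder_kernels(48, 50, 5)


def _num_grad(f, x, eps=1e-5):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


@pytest.mark.parametrize(
    "layer_factory,in_shape",
    [
        (lambda rng: Conv2D(2, 3, 3, rng, dtype=np.float64), (2, 2, 5, 5)),
        (lambda rng: TransposedConv2D(2, 3, 4, rng, dtype=np.float64), (2, 2, 4, 4)),
        (lambda rng: BatchNorm2D(2, dtype=np.float64), (3, 2, 4, 4)),
        (lambda rng: Upsample2x(), (2, 2, 3, 3)),
    ],
)
def test_layer_gradients_match_finite_differences(layer_factory, in_shape):
    rng = np.random.default_rng(3)
    layer = layer_factory(rng)
    x = rng.standard_normal(in_shape)
    w_out = rng.standard_normal(layer.forward(x, train=True).shape)

    def loss():
        return float(np.sum(layer.forward(x, train=True) * w_out))

    layer.forward(x, train=True)
    dx = layer.backward(w_out.copy())
    np.testing.assert_allclose(dx, _num_grad(loss, x), rtol=1e-5, atol=1e-7)
    for name in layer.params:
        np.testing.assert_allclose(
            layer.grads[name],
            _num_grad(loss, layer.params[name]),
            rtol=1e-5,
            atol=1e-7,
        )


def test_end_to_end_bce_gradient_matches_finite_differences():
    spec = ArchitectureSpec(
        2,
        4,
        10,
        (
            LayerSpec("conv", 3, 3),
            LayerSpec("upsample"),
            LayerSpec("tconv", 2, 3),
            LayerSpec("output"),
        ),
    )
    model = build_model(spec, seed=0, dtype=np.float64)
    rng = np.random.default_rng(1)
    x = rng.standard_normal((2, 2, 4, 4))
    y = (rng.random((2, 10, 10)) > 0.7).astype(float)

    probs = model.forward(x, train=True)
    model.backward_from_bce(probs, y)
    for pname, layer, name in model.parameters():
        def loss():
            return bce_loss(model.forward(x, train=True), y)

        got = layer.grads[name]
        want = _num_grad(loss, layer.params[name], eps=1e-6)
        np.testing.assert_allclose(got, want, rtol=2e-4, atol=1e-8)


def test_probabilities_in_unit_interval_and_deterministic(fixture_model, fixture_dataset):
    model, _ = fixture_model
    x = fixture_dataset.network_inputs(fixture_dataset.splits["test"][:4])
    p1 = model.forward(x)
    p2 = model.forward(x)
    assert np.all((p1 >= 0) & (p1 <= 1))
    np.testing.assert_array_equal(p1, p2)


def test_threshold_nesting_and_limits(fixture_model, fixture_dataset):
    model, _ = fixture_model
    x = fixture_dataset.network_inputs(fixture_dataset.splits["test"][:4])
    prev = None
    for alpha in (0.1, 0.3, 0.5, 0.7, 0.9):
        img, _ = predict(model, x, alpha)
        if prev is not None:
            # raising the threshold never adds a hotspot pixel
            assert np.all(img <= prev)
        prev = img
    img_hi, probs = predict(model, x, 1.0 - 1e-9)
    assert img_hi.sum() == 0 or np.any(probs > 1.0 - 1e-9)
    with pytest.raises(ValueError):
        predict(model, x, 1.5)


def test_checkpoint_round_trip_preserves_outputs(tmp_path, fixture_model, fixture_dataset):
    model, history = fixture_model
    x = fixture_dataset.network_inputs(fixture_dataset.splits["test"][:2])
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, model, extra={"note": "test"})
    model2, extra = load_checkpoint(path)
    assert extra["note"] == "test"
    np.testing.assert_allclose(model.forward(x), model2.forward(x), rtol=1e-6, atol=1e-8)
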