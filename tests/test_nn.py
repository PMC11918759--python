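"""Finite-difference verification of the numpy layer library.

Every layer's analytic backward pass is checked against central
differences through a scalar loss; the optimizer and training loop are
checked for determinism and for actually reducing the loss.
"""

import numpy as np
import pytest

from fnirscad import nn


def _num_grad(f, w, eps=1e-6):
    g = np.zeros_like(w)
    it = np.nditer(w, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = w[idx]
        w[idx] = orig + eps
        fp = f()
        w[idx] = orig - eps
        fm = f()
        w[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g


def _check_layer(layer, in_shape, seed=0, training=True, atol=1e-6):
    rng = np.random.default_rng(seed)
    layer.build(in_shape, rng)
    if isinstance(layer, nn.Dropout):
        layer.rng = np.random.default_rng(99)
    x = rng.normal(size=(3, *in_shape))
    if isinstance(layer, nn.Activation) and layer.kind == "log":
        x = np.abs(x) + 0.1
    proj = rng.normal(size=(3, *layer.out_shape))

    def loss_from(x_):
        if isinstance(layer, nn.Dropout):
            layer.rng = np.random.default_rng(99)  # freeze mask
        return float((layer.forward(x_, training) * proj).sum())

    loss_from(x)
    gx = layer.backward(proj)
    gx_num = _num_grad(lambda: loss_from(x), x)
    np.testing.assert_allclose(gx, gx_num, atol=atol, rtol=1e-4)
    for key, w in layer.params.items():
        loss_from(x)
        layer.backward(proj)
        g_analytic = layer.grads[key].copy()
        g_num = _num_grad(lambda: loss_from(x), w)
        np.testing.assert_allclose(g_analytic, g_num, atol=atol, rtol=1e-4, err_msg=key)


@pytest.mark.parametrize(
    "layer, in_shape",
    [
        (nn.DepthwiseConv1D(4, 2), (10, 3)),
        (nn.DepthwiseConv1D(5, 3), (12, 2)),
        (nn.TemporalConv2D(4, 2), (3, 11)),
        (nn.SpatialCollapse(3), (4, 6)),
        (nn.PointwiseMix(4), (5, 3)),
        (nn.AvgPoolTime(3, 2), (9, 2)),
        (nn.Dense(4), (7,)),
        (nn.Activation("elu"), (5, 3)),
        (nn.Activation("square"), (5, 3)),
        (nn.Activation("log"), (5, 3)),
        (nn.Permute(), (4, 5)),
        (nn.Flatten(), (3, 4)),
        (nn.Dropout(0.3), (6, 2)),
        (nn.ChannelReorder(np.array([2, 0, 3, 1])), (5, 4)),
        (nn.BatchNorm(), (6, 3)),
        (nn.BatchNorm(per_feature=False), (6, 3)),
    ],
    ids=lambda v: getattr(v, "kind", None) or type(v).__name__
    if isinstance(v, nn.Layer)
    else str(v),
)
def test_layer_gradients_match_finite_differences(layer, in_shape):
    _check_layer(layer, in_shape)


def test_batchnorm_train_vs_eval_statistics():
    layer = nn.BatchNorm(momentum=0.5)
    layer.build((4,), np.random.default_rng(0))
    x = np.random.default_rng(1).normal(loc=2.0, scale=3.0, size=(64, 4))
    out = layer.forward(x, training=True)
    np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-10)
    np.testing.assert_allclose(out.std(axis=0), 1.0, atol=1e-6)
    # eval mode uses running statistics, not the batch's
    y = layer.forward(np.zeros((2, 4)), training=False)
    assert not np.allclose(y, 0.0)


def test_max_norm_constraint_caps_column_norms():
    layer = nn.Dense(5, max_norm=0.1)
    layer.build((20,), np.random.default_rng(0))
    layer.params["W"] *= 100.0
    layer.apply_constraints()
    norms = np.linalg.norm(layer.params["W"], axis=0)
    assert (norms <= 0.1 + 1e-12).all()


def test_conv_output_length_formula():
    layer = nn.DepthwiseConv1D(32, 16)
    out = layer.build((246, 68), np.random.default_rng(0))
    assert out == ((246 - 32) // 16 + 1, 68)
    assert out[0] == 14


def _tiny_net(seed=0):
    branches = [
        nn.Sequential([nn.DepthwiseConv1D(4, 2), nn.Activation("elu"), nn.Flatten()])
        for _ in range(2)
    ]
    head = nn.Sequential([nn.Dense(4), nn.Activation("elu"), nn.Dense(2)])
    return nn.EnsembleNet(branches, head, branch_input_shape=(8, 3), seed=seed)


class TestEnsembleTraining:
    def test_full_network_gradient(self):
        net = _tiny_net()
        rng = np.random.default_rng(5)
        x = rng.normal(size=(4, 2, 8, 3))
        y = np.array([0, 1, 0, 1])
        onehot = np.eye(2)[y]

        def loss():
            logits = net.forward(x, training=False)
            p = nn.softmax(logits)
            return float(-(onehot * np.log(p)).sum(axis=1).mean())

        logits = net.forward(x, training=False)
        p = nn.softmax(logits)
        net.backward((p - onehot) / 4)
        w = net.head.layers[0].params["W"]
        g_analytic = net.head.layers[0].grads["W"].copy()
        g_num = _num_grad(loss, w)
        np.testing.assert_allclose(g_analytic, g_num, atol=1e-6, rtol=1e-4)
        wb = net.branches[0].layers[0].params["W"]
        net.forward(x, training=False)
        net.backward((nn.softmax(net.forward(x, training=False)) - onehot) / 4)
        gb = net.branches[0].layers[0].grads["W"].copy()
        gb_num = _num_grad(loss, wb)
        np.testing.assert_allclose(gb, gb_num, atol=1e-6, rtol=1e-4)

    def test_training_reduces_loss_and_is_deterministic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(16, 2, 8, 3))
        y = (x[:, 0, :, 0].mean(axis=1) > 0).astype(int)
        h1 = _tiny_net(seed=3).fit(x, y, epochs=30, batch_size=8)
        h2 = _tiny_net(seed=3).fit(x, y, epochs=30, batch_size=8)
        assert h1.loss[-1] < h1.loss[0]
        assert h1.loss == h2.loss  # bit-identical training

    def test_class_weights_scale_loss(self):
        net = _tiny_net(seed=1)
        x = np.random.default_rng(2).normal(size=(8, 2, 8, 3))
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        h = net.fit(x, y, epochs=1, batch_size=8, class_weight={0: 0.5, 1: 2.0})
        assert np.isfinite(h.loss[0])

    def test_softmax_rows_sum_to_one(self):
        z = np.random.default_rng(0).normal(size=(5, 2)) * 50
        p = nn.softmax(z)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert (p >= 0).all()

    def test_prediction_tie_resolves_to_hc(self):
        net = _tiny_net(seed=4)
        x = np.zeros((2, 2, 8, 3))
        p = net.predict_proba(x)
        pred = net.predict(x)
        expected = (p[:, 1] > p[:, 0]).astype(int)
        np.testing.assert_array_equal(pred, expected)
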