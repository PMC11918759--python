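"""Minimal numpy neural-network core for the fNIRS classifiers.

A purpose-built layer library: exactly the operations the ensemble
architectures need (depthwise 1-D convolutions, the 2-D convolution
specializations used by the EEG-style reference extractors, batch
normalization, ELU/square/log activations, dropout, dense layers), a
weighted softmax cross-entropy loss, and the Adamax optimizer.  Everything
runs in float64 on the CPU; gradients are analytic and covered by
finite-difference tests.

Conventions
-----------
* Arrays are batch-first; layer ``build`` receives the per-sample shape.
* All randomness (weight init, dropout masks, shuffling) flows from a
  single ``numpy.random.Generator`` owned by the network, so a fixed seed
  gives bit-identical training runs on a single thread.
* ``DepthwiseConv1D`` follows the (length, depth) layout: input
  ``(B, L, D)``, one independent kernel of length K per depth index,
  stride along L, valid padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "DepthwiseConv1D",
    "Permute",
    "ChannelReorder",
    "TemporalConv2D",
    "SpatialCollapse",
    "PointwiseMix",
    "AvgPoolTime",
    "BatchNorm",
    "Activation",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "EnsembleNet",
    "Adamax",
    "softmax",
]


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class: parameters, gradients, optional max-norm constraint."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.max_norm: float | None = None
        self.out_shape: tuple[int, ...] | None = None

    def build(self, in_shape: tuple[int, ...], rng: np.random.Generator) -> tuple[int, ...]:
        self.out_shape = in_shape
        return in_shape

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def describe(self) -> dict:
        return {"layer": type(self).__name__}

    def apply_constraints(self) -> None:
        if self.max_norm is None:
            return
        for key in ("W",):
            if key in self.params:
                w = self.params[key]
                axes = tuple(range(w.ndim - 1))
                norms = np.sqrt((w**2).sum(axis=axes, keepdims=True))
                with np.errstate(divide="ignore", invalid="ignore"):
                    scale = np.minimum(1.0, self.max_norm / np.maximum(norms, 1e-12))
                self.params[key] = w * scale


def _conv_out_len(length: int, kernel: int, stride: int) -> int:
    if length < kernel:
        raise ValueError(f"input length {length} shorter than kernel {kernel}")
    return (length - kernel) // stride + 1


class DepthwiseConv1D(Layer):
    """Per-depth-channel 1-D convolution along the first non-batch axis."""

    def __init__(self, kernel: int, stride: int, max_norm: float | None = None) -> None:
        super().__init__()
        self.kernel = kernel
        self.stride = stride
        self.max_norm = max_norm

    def build(self, in_shape, rng):
        length, depth = in_shape
        self.params["W"] = _glorot(rng, (self.kernel, depth), self.kernel, self.kernel)
        self.params["b"] = np.zeros(depth)
        self.out_shape = (_conv_out_len(length, self.kernel, self.stride), depth)
        return self.out_shape

    def forward(self, x, training):
        self._x = x
        win = sliding_window_view(x, self.kernel, axis=1)[:, :: self.stride]
        # win: (B, Lo, D, K)
        self._win = win
        return np.einsum("bldk,kd->bld", win, self.params["W"]) + self.params["b"]

    def backward(self, g):
        W = self.params["W"]
        self.grads["W"] = np.einsum("bld,bldk->kd", g, self._win)
        self.grads["b"] = g.sum(axis=(0, 1))
        gx = np.zeros_like(self._x)
        lo = g.shape[1]
        for k in range(self.kernel):
            gx[:, k : k + self.stride * lo : self.stride, :] += g * W[k][None, None, :]
        return gx

    def describe(self):
        return {
            "layer": "DepthwiseConv1D",
            "kernel": self.kernel,
            "stride": self.stride,
        }


class Permute(Layer):
    """Swap the two per-sample axes, (B, A, C) -> (B, C, A)."""

    def build(self, in_shape, rng):
        self.out_shape = (in_shape[1], in_shape[0])
        return self.out_shape

    def forward(self, x, training):
        return np.swapaxes(x, 1, 2)

    def backward(self, g):
        return np.swapaxes(g, 1, 2)


class ChannelReorder(Layer):
    """Fixed permutation of the trailing (channel) axis; used by C3."""

    def __init__(self, order: np.ndarray) -> None:
        super().__init__()
        self.order = np.asarray(order, dtype=np.intp)
        self._inverse = np.empty_like(self.order)
        self._inverse[self.order] = np.arange(self.order.size)

    def build(self, in_shape, rng):
        if in_shape[-1] != self.order.size:
            raise ValueError("order length does not match channel axis")
        self.out_shape = in_shape
        return in_shape

    def forward(self, x, training):
        return x[..., self.order]

    def backward(self, g):
        return g[..., self._inverse]

    def describe(self):
        return {"layer": "ChannelReorder"}


class TemporalConv2D(Layer):
    """Single-filter (1, K) convolution along time, shared across rows.

    Input ``(B, R, T)``; each row is convolved with the same length-K
    kernel at the given stride; one scalar bias.
    """

    def __init__(self, kernel: int, stride: int, max_norm: float | None = None) -> None:
        super().__init__()
        self.kernel = kernel
        self.stride = stride
        self.max_norm = max_norm

    def build(self, in_shape, rng):
        rows, length = in_shape
        self.params["W"] = _glorot(rng, (self.kernel, 1), self.kernel, self.kernel)
        self.params["b"] = np.zeros(1)
        self.out_shape = (rows, _conv_out_len(length, self.kernel, self.stride))
        return self.out_shape

    def forward(self, x, training):
        self._x = x
        win = sliding_window_view(x, self.kernel, axis=2)[:, :, :: self.stride]
        self._win = win  # (B, R, To, K)
        return np.einsum("brtk,k->brt", win, self.params["W"][:, 0]) + self.params["b"][0]

    def backward(self, g):
        W = self.params["W"][:, 0]
        self.grads["W"] = np.einsum("brt,brtk->k", g, self._win)[:, None]
        self.grads["b"] = np.array([g.sum()])
        gx = np.zeros_like(self._x)
        to = g.shape[2]
        for k in range(self.kernel):
            gx[:, :, k : k + self.stride * to : self.stride] += g * W[k]
        return gx

    def describe(self):
        return {"layer": "TemporalConv2D", "kernel": (1, self.kernel), "stride": (1, self.stride)}


class SpatialCollapse(Layer):
    """Full-height (R, 1) convolution collapsing the row axis into filters.

    Input ``(B, R, T)`` -> output ``(B, T, F)``; equivalently a depthwise
    spatial kernel spanning all rows with F output maps.
    """

    def __init__(self, filters: int, max_norm: float | None = None) -> None:
        super().__init__()
        self.filters = filters
        self.max_norm = max_norm

    def build(self, in_shape, rng):
        rows, length = in_shape
        self.params["W"] = _glorot(rng, (rows, self.filters), rows, self.filters)
        self.params["b"] = np.zeros(self.filters)
        self.out_shape = (length, self.filters)
        return self.out_shape

    def forward(self, x, training):
        self._x = x
        return np.einsum("brt,rf->btf", x, self.params["W"]) + self.params["b"]

    def backward(self, g):
        self.grads["W"] = np.einsum("brt,btf->rf", self._x, g)
        self.grads["b"] = g.sum(axis=(0, 1))
        return np.einsum("btf,rf->brt", g, self.params["W"])

    def describe(self):
        return {"layer": "SpatialCollapse", "filters": self.filters}


class PointwiseMix(Layer):
    """(1, 1) convolution mixing feature maps: (B, T, F) -> (B, T, F_out)."""

    def __init__(self, filters: int, max_norm: float | None = None) -> None:
        super().__init__()
        self.filters = filters
        self.max_norm = max_norm

    def build(self, in_shape, rng):
        length, fin = in_shape
        self.params["W"] = _glorot(rng, (fin, self.filters), fin, self.filters)
        self.params["b"] = np.zeros(self.filters)
        self.out_shape = (length, self.filters)
        return self.out_shape

    def forward(self, x, training):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g):
        self.grads["W"] = np.einsum("btf,btg->fg", self._x, g)
        self.grads["b"] = g.sum(axis=(0, 1))
        return g @ self.params["W"].T

    def describe(self):
        return {"layer": "PointwiseMix", "filters": self.filters}


class AvgPoolTime(Layer):
    """Average pooling along the first per-sample axis of (B, T, F)."""

    def __init__(self, pool: int, stride: int) -> None:
        super().__init__()
        self.pool = pool
        self.stride = stride

    def build(self, in_shape, rng):
        length, feats = in_shape
        self.out_shape = (_conv_out_len(length, self.pool, self.stride), feats)
        return self.out_shape

    def forward(self, x, training):
        self._in_len = x.shape[1]
        win = sliding_window_view(x, self.pool, axis=1)[:, :: self.stride]
        return win.mean(axis=-1)

    def backward(self, g):
        gx = np.zeros((g.shape[0], self._in_len, g.shape[2]))
        to = g.shape[1]
        for k in range(self.pool):
            gx[:, k : k + self.stride * to : self.stride, :] += g / self.pool
        return gx

    def describe(self):
        return {"layer": "AvgPoolTime", "pool": self.pool, "stride": self.stride}


class BatchNorm(Layer):
    """Batch normalization over all axes except the trailing feature axis.

    ``per_feature=False`` gives a single global mean/variance (the case of
    a conceptual trailing feature dimension of 1).  Running statistics use
    ``running = (1 - momentum) * running + momentum * batch``.
    """

    def __init__(self, eps: float = 1e-5, momentum: float = 0.1, per_feature: bool = True) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.per_feature = per_feature

    def build(self, in_shape, rng):
        n = in_shape[-1] if self.per_feature else 1
        self.params["gamma"] = np.ones(n)
        self.params["beta"] = np.zeros(n)
        self.run_mean = np.zeros(n)
        self.run_var = np.ones(n)
        self.out_shape = in_shape
        return in_shape

    def _axes(self, x):
        return tuple(range(x.ndim - 1)) if self.per_feature else tuple(range(x.ndim))

    def forward(self, x, training):
        axes = self._axes(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.run_mean = (1 - m) * self.run_mean + m * np.atleast_1d(mean)
            self.run_var = (1 - m) * self.run_var + m * np.atleast_1d(var)
        else:
            mean = self.run_mean if self.per_feature else self.run_mean[0]
            var = self.run_var if self.per_feature else self.run_var[0]
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._n = x.size // (x.shape[-1] if self.per_feature else 1)
        self._training = training
        gamma = self.params["gamma"] if self.per_feature else self.params["gamma"][0]
        beta = self.params["beta"] if self.per_feature else self.params["beta"][0]
        return gamma * self._xhat + beta

    def backward(self, g):
        axes = self._axes(g)
        gg = (g * self._xhat).sum(axis=axes)
        gb = g.sum(axis=axes)
        self.grads["gamma"] = np.atleast_1d(gg)
        self.grads["beta"] = np.atleast_1d(gb)
        gamma = self.params["gamma"] if self.per_feature else self.params["gamma"][0]
        if not self._training:
            return g * gamma / self._std
        n = self._n
        return (gamma / (n * self._std)) * (n * g - gb - self._xhat * gg)

    def describe(self):
        return {"layer": "BatchNorm", "eps": self.eps, "momentum": self.momentum}


class Activation(Layer):
    """ELU (alpha=1), square, or clipped-log activation."""

    def __init__(self, kind: str) -> None:
        super().__init__()
        if kind not in ("elu", "square", "log"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, x, training):
        if self.kind == "elu":
            self._out = np.where(x > 0, x, np.expm1(x))
            return self._out
        if self.kind == "square":
            self._x = x
            return x**2
        self._xc = np.maximum(x, 1e-6)
        return np.log(self._xc)

    def backward(self, g):
        if self.kind == "elu":
            return g * np.where(self._out > 0, 1.0, self._out + 1.0)
        if self.kind == "square":
            return g * 2.0 * self._x
        return g / self._xc

    def describe(self):
        return {"layer": "Activation", "kind": self.kind}


class Dropout(Layer):
    """Inverted dropout; mask drawn from the owning network's generator."""

    def __init__(self, p: float) -> None:
        super().__init__()
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x, training):
        if not training or self.p <= 0:
            self._mask = None
            return x
        assert self.rng is not None, "dropout layer not bound to a network rng"
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask

    def describe(self):
        return {"layer": "Dropout", "p": self.p}


class Flatten(Layer):
    def build(self, in_shape, rng):
        self.out_shape = (int(np.prod(in_shape)),)
        return self.out_shape

    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, units: int, max_norm: float | None = None) -> None:
        super().__init__()
        self.units = units
        self.max_norm = max_norm

    def build(self, in_shape, rng):
        (fin,) = in_shape
        self.params["W"] = _glorot(rng, (fin, self.units), fin, self.units)
        self.params["b"] = np.zeros(self.units)
        self.out_shape = (self.units,)
        return self.out_shape

    def forward(self, x, training):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g):
        self.grads["W"] = self._x.T @ g
        self.grads["b"] = g.sum(axis=0)
        return g @ self.params["W"].T

    def describe(self):
        return {"layer": "Dense", "units": self.units}


class Sequential:
    """Ordered layer container with chained build/forward/backward."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers
        self.built = False

    def build(self, in_shape, rng) -> tuple[int, ...]:
        shape = in_shape
        for layer in self.layers:
            shape = layer.build(shape, rng)
        self.built = True
        return shape

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def summary(self, in_shape) -> list[dict]:
        rows = []
        for layer in self.layers:
            d = layer.describe()
            d["output_shape"] = layer.out_shape
            rows.append(d)
        return rows


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adamax:
    """Adamax optimizer (infinity-norm Adam variant)."""

    def __init__(self, lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict[int, dict[str, np.ndarray]] = {}
        self._u: dict[int, dict[str, np.ndarray]] = {}

    def step(self, layers: list[Layer]) -> None:
        self.t += 1
        bias = 1.0 - self.beta1**self.t
        for layer in layers:
            lid = id(layer)
            if lid not in self._m:
                self._m[lid] = {k: np.zeros_like(v) for k, v in layer.params.items()}
                self._u[lid] = {k: np.zeros_like(v) for k, v in layer.params.items()}
            for k, w in layer.params.items():
                g = layer.grads.get(k)
                if g is None:
                    continue
                m = self._m[lid][k]
                u = self._u[lid][k]
                m[:] = self.beta1 * m + (1 - self.beta1) * g
                u[:] = np.maximum(self.beta2 * u, np.abs(g))
                w -= (self.lr / bias) * m / (u + self.eps)
            layer.apply_constraints()


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)


class EnsembleNet:
    """Six per-indicator branches, feature concatenation, shared classifier.

    ``branch_input_shape`` is the per-sample shape each branch receives
    (the sample tensor is ``(6,) + branch_input_shape``).  The head sees
    the concatenation of the six flattened branch outputs.
    """

    def __init__(
        self,
        branches: list[Sequential],
        head: Sequential,
        branch_input_shape: tuple[int, ...],
        seed: int = 0,
    ) -> None:
        self.branches = branches
        self.head = head
        self.rng = np.random.default_rng(seed)
        self.branch_input_shape = branch_input_shape
        feat = 0
        for br in self.branches:
            out = br.build(branch_input_shape, self.rng)
            assert len(out) == 1, "each branch must end in Flatten"
            feat += out[0]
        self.n_features = feat
        self.out_shape = self.head.build((feat,), self.rng)
        for seq in [*self.branches, self.head]:
            for layer in seq.layers:
                if isinstance(layer, Dropout):
                    layer.rng = self.rng

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        feats = [br.forward(x[:, i], training) for i, br in enumerate(self.branches)]
        self._splits = np.cumsum([f.shape[1] for f in feats])[:-1]
        return self.head.forward(np.concatenate(feats, axis=1), training)

    def backward(self, g_logits: np.ndarray) -> None:
        g_feat = self.head.backward(g_logits)
        for br, g in zip(self.branches, np.split(g_feat, self._splits, axis=1)):
            br.backward(g)

    def _all_layers(self) -> list[Layer]:
        out = []
        for seq in [*self.branches, self.head]:
            out.extend(seq.layers)
        return out

    # -- training -----------------------------------------------------------
    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int = 32,
        class_weight: dict[int, float] | None = None,
        optimizer: Adamax | None = None,
    ) -> TrainHistory:
        """Minimize weighted softmax cross-entropy with Adamax."""
        opt = optimizer or Adamax()
        n = x.shape[0]
        y = np.asarray(y, dtype=int)
        onehot = np.eye(2)[y]
        weights = np.ones(n)
        if class_weight:
            weights = np.array([class_weight[int(c)] for c in y], dtype=float)
        hist = TrainHistory()
        layers = self._all_layers()
        for _ in range(epochs):
            order = self.rng.permutation(n)
            ep_loss, ep_correct = 0.0, 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb, wb = x[idx], onehot[idx], weights[idx]
                logits = self.forward(xb, training=True)
                p = softmax(logits)
                losses = -(yb * np.log(np.maximum(p, 1e-12))).sum(axis=1)
                ep_loss += float((wb * losses).sum())
                ep_correct += int((p.argmax(axis=1) == yb.argmax(axis=1)).sum())
                g = wb[:, None] * (p - yb) / len(idx)
                self.backward(g)
                opt.step(layers)
            hist.loss.append(ep_loss / n)
            hist.accuracy.append(ep_correct / n)
        return hist

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, training=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        p = self.predict_proba(x)
        # ties at 0.5 resolve to class 0 (HC)
        return (p[:, 1] > p[:, 0]).astype(int)
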