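"""Minimal NumPy computation-graph engine for the T-Net.

The segmentation network needs only a small, fixed vocabulary of layers
(plain and dilated 3x3 convolutions, transposed convolution, batch norm,
ReLU/sigmoid, max/global pooling, shared dense bottleneck, concatenation,
channel-wise gating, nearest upsampling), so the engine implements exactly
those with hand-written backward passes instead of a generic autodiff.

Conventions: tensors are NHWC float32; a network is a DAG of named layers
added in topological order (each layer's inputs must already exist).
Convolutions use "same" padding; the dilated branch pads by the dilation
rate so both T-block branches agree spatially.  Batch-norm parameter counts
follow the common model-summary convention of 4*C (scale, shift, and the
two non-trainable moving statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "Layer", "Input", "Conv2D", "ConvTranspose2D", "BatchNorm", "ReLU",
    "Sigmoid", "MaxPool2", "GlobalAvgPool", "GlobalMaxPool", "SharedDense",
    "AddPaths", "ChannelScale", "Concat", "UpSample2", "ChannelMeanSigmoid",
    "Network", "Adam",
]


class Layer:
    """Base class: named node with named input connections."""

    def __init__(self, name: str, inputs: list[str]):
        self.name = name
        self.inputs = list(inputs)
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}
        self.output_shape: tuple = ()  # without batch dim
        self._cache: tuple = ()

    # -- interface -----------------------------------------------------
    def infer_shape(self, in_shapes: list[tuple]) -> tuple:
        raise NotImplementedError

    def forward(self, xs: list[np.ndarray], training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> list[np.ndarray]:
        raise NotImplementedError

    def param_count(self) -> int:
        n = sum(int(p.size) for p in self.params.values())
        n += sum(int(b.size) for k, b in self.buffers.items()
                 if not k.startswith("_"))
        return n

    def zero_grad(self) -> None:
        for k, p in self.params.items():
            self.grads[k] = np.zeros_like(p)


class Input(Layer):
    def __init__(self, name: str, shape: tuple):
        super().__init__(name, [])
        self.output_shape = tuple(shape)

    def infer_shape(self, in_shapes):
        return self.output_shape

    def forward(self, xs, training):
        raise RuntimeError("Input layer is fed directly by the network")

    def backward(self, grad):
        return []


def _he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2D(Layer):
    """Same-padded KxK convolution with optional dilation, NHWC.

    Implemented as a sum of K*K shifted matrix products, which keeps peak
    memory low and lets BLAS do the heavy lifting.
    """

    def __init__(self, name, inputs, c_in: int, filters: int, kernel: int = 3,
                 dilation: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__(name, inputs)
        self.c_in, self.filters = c_in, filters
        self.kernel, self.dilation = kernel, dilation
        self.use_bias = bias
        rng = rng or np.random.default_rng(0)
        self.params["w"] = _he_uniform(
            rng, (kernel, kernel, c_in, filters), kernel * kernel * c_in)
        if bias:
            self.params["b"] = np.zeros(filters, dtype=np.float32)

    def infer_shape(self, in_shapes):
        h, w, c = in_shapes[0]
        if c != self.c_in:
            raise ValueError(f"{self.name}: expected {self.c_in} channels, got {c}")
        return (h, w, self.filters)

    def forward(self, xs, training):
        x = xs[0]
        n, h, w, _ = x.shape
        k, d = self.kernel, self.dilation
        pad = d * (k - 1) // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        wgt = self.params["w"]
        out = np.zeros((n * h * w, self.filters), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                xs_ = xp[:, i * d:i * d + h, j * d:j * d + w, :]
                out += xs_.reshape(-1, self.c_in) @ wgt[i, j]
        if self.use_bias:
            out += self.params["b"]
        self._cache = (xp, (n, h, w))
        return out.reshape(n, h, w, self.filters)

    def backward(self, grad):
        xp, (n, h, w) = self._cache
        k, d = self.kernel, self.dilation
        pad = d * (k - 1) // 2
        wgt = self.params["w"]
        g2 = grad.reshape(-1, self.filters).astype(np.float32)
        dxp = np.zeros_like(xp)
        dw = self.grads["w"]
        for i in range(k):
            for j in range(k):
                xs_ = xp[:, i * d:i * d + h, j * d:j * d + w, :]
                dw[i, j] += xs_.reshape(-1, self.c_in).T @ g2
                dxp[:, i * d:i * d + h, j * d:j * d + w, :] += \
                    (g2 @ wgt[i, j].T).reshape(n, h, w, self.c_in)
        if self.use_bias:
            self.grads["b"] += g2.sum(axis=0)
        if pad:
            dx = dxp[:, pad:-pad, pad:-pad, :]
        else:
            dx = dxp
        return [dx]


class ConvTranspose2D(Layer):
    """3x3 stride-2 learnable upsampler: zero-stuff then same-padded conv.

    Parameter count matches the usual transposed-convolution accounting,
    K*K*c_in*filters + filters.
    """

    def __init__(self, name, inputs, c_in: int, filters: int, kernel: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__(name, inputs)
        self.c_in, self.filters, self.kernel = c_in, filters, kernel
        rng = rng or np.random.default_rng(0)
        self.params["w"] = _he_uniform(
            rng, (kernel, kernel, c_in, filters), kernel * kernel * c_in)
        self.params["b"] = np.zeros(filters, dtype=np.float32)
        self._conv = Conv2D.__new__(Conv2D)
        Layer.__init__(self._conv, "_", [])
        self._conv.c_in, self._conv.filters = c_in, filters
        self._conv.kernel, self._conv.dilation = kernel, 1
        self._conv.use_bias = True
        self._conv.params = self.params

    def infer_shape(self, in_shapes):
        h, w, c = in_shapes[0]
        if c != self.c_in:
            raise ValueError(f"{self.name}: expected {self.c_in} channels, got {c}")
        return (2 * h, 2 * w, self.filters)

    def _stuffed(self, x):
        n, h, w, c = x.shape
        z = np.zeros((n, 2 * h, 2 * w, c), dtype=np.float32)
        z[:, ::2, ::2, :] = x
        return z

    def forward(self, xs, training):
        z = self._stuffed(xs[0])
        self._conv.params = self.params
        return self._conv.forward([z], training)

    def backward(self, grad):
        conv = self._conv
        conv.grads = self.grads
        (dz,) = conv.backward(grad)
        return [dz[:, ::2, ::2, :]]


class BatchNorm(Layer):
    """Channel-wise batch normalization over (N, H, W)."""

    def __init__(self, name, inputs, channels: int,
                 eps: float = 1e-3, momentum: float = 0.99):
        super().__init__(name, inputs)
        self.channels = channels
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        # debiased exponential moving statistics: raw EMAs start at zero
        # and are divided by (1 - momentum**steps) at eval, so short runs
        # are calibrated from the first update (underscored buffers are
        # bookkeeping, excluded from the summary parameter count)
        self.buffers["moving_mean"] = np.zeros(channels, dtype=np.float32)
        self.buffers["moving_var"] = np.ones(channels, dtype=np.float32)
        self.buffers["_steps"] = np.zeros(1, dtype=np.float64)

    def infer_shape(self, in_shapes):
        return in_shapes[0]

    def forward(self, xs, training):
        x = xs[0]
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            steps = self.buffers["_steps"]
            if steps[0] == 0:
                self.buffers["moving_mean"][:] = 0.0
                self.buffers["moving_var"][:] = 0.0
            self.buffers["moving_mean"] = (m * self.buffers["moving_mean"]
                                           + (1 - m) * mean).astype(np.float32)
            self.buffers["moving_var"] = (m * self.buffers["moving_var"]
                                          + (1 - m) * var).astype(np.float32)
            steps[0] += 1
        else:
            steps = float(self.buffers["_steps"][0])
            if steps == 0:
                mean = self.buffers["moving_mean"]
                var = self.buffers["moving_var"]
            else:
                debias = 1.0 - self.momentum ** steps
                mean = self.buffers["moving_mean"] / debias
                var = self.buffers["moving_var"] / debias
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, x.shape, training)
        return (self.params["gamma"] * xhat + self.params["beta"]).astype(np.float32)

    def backward(self, grad):
        xhat, inv, shape, training = self._cache
        axes = tuple(range(len(shape) - 1))
        m = np.prod([shape[a] for a in axes])
        self.grads["gamma"] += (grad * xhat).sum(axis=axes)
        self.grads["beta"] += grad.sum(axis=axes)
        gg = grad * self.params["gamma"]
        if training:
            dx = (inv / m) * (m * gg - gg.sum(axis=axes)
                              - xhat * (gg * xhat).sum(axis=axes))
        else:
            dx = gg * inv
        return [dx.astype(np.float32)]


class ReLU(Layer):
    def __init__(self, name, inputs):
        super().__init__(name, inputs)

    def infer_shape(self, in_shapes):
        return in_shapes[0]

    def forward(self, xs, training):
        x = xs[0]
        self._cache = (x > 0,)
        return np.maximum(x, 0.0)

    def backward(self, grad):
        return [grad * self._cache[0]]


class Sigmoid(Layer):
    def __init__(self, name, inputs):
        super().__init__(name, inputs)

    def infer_shape(self, in_shapes):
        return in_shapes[0]

    def forward(self, xs, training):
        # numerically safe logistic
        x = np.clip(xs[0], -60.0, 60.0)
        y = 1.0 / (1.0 + np.exp(-x))
        self._cache = (y,)
        return y.astype(np.float32)

    def backward(self, grad):
        y = self._cache[0]
        return [grad * y * (1.0 - y)]


class MaxPool2(Layer):
    """2x2 max pooling, stride 2."""

    def __init__(self, name, inputs):
        super().__init__(name, inputs)

    def infer_shape(self, in_shapes):
        h, w, c = in_shapes[0]
        return (h // 2, w // 2, c)

    def forward(self, xs, training):
        x = xs[0]
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        self._cache = (x, out)
        return out

    def backward(self, grad):
        x, out = self._cache
        n, h, w, c = x.shape
        up = np.repeat(np.repeat(out, 2, axis=1), 2, axis=2)
        mask = (x == up)
        # distribute equally across ties within each window
        counts = mask.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))
        gup = np.repeat(np.repeat(grad / counts, 2, axis=1), 2, axis=2)
        return [(gup * mask).astype(np.float32)]


class GlobalAvgPool(Layer):
    def __init__(self, name, inputs):
        super().__init__(name, inputs)

    def infer_shape(self, in_shapes):
        return (in_shapes[0][-1],)

    def forward(self, xs, training):
        x = xs[0]
        self._cache = (x.shape,)
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        (shape,) = self._cache
        n, h, w, c = shape
        g = np.broadcast_to(grad[:, None, None, :] / (h * w), shape)
        return [g.astype(np.float32)]


class GlobalMaxPool(Layer):
    def __init__(self, name, inputs):
        super().__init__(name, inputs)

    def infer_shape(self, in_shapes):
        return (in_shapes[0][-1],)

    def forward(self, xs, training):
        x = xs[0]
        out = x.max(axis=(1, 2))
        self._cache = (x, out)
        return out

    def backward(self, grad):
        x, out = self._cache
        mask = (x == out[:, None, None, :])
        counts = mask.sum(axis=(1, 2))
        g = mask * (grad / counts)[:, None, None, :]
        return [g.astype(np.float32)]


class SharedDense(Layer):
    """Fully connected layer with weights shared across parallel paths.

    With several inputs (e.g. the average- and max-pooled channel vectors)
    they are stacked on a leading path axis; a single already-stacked input
    passes through unchanged.  Used twice to form the squeeze-excite
    bottleneck of the channel-attention module.
    """

    def __init__(self, name, inputs, c_in: int, c_out: int,
                 activation: str | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__(name, inputs)
        self.c_in, self.c_out = c_in, c_out
        self.activation = activation
        rng = rng or np.random.default_rng(0)
        self.params["w"] = _he_uniform(rng, (c_in, c_out), c_in)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def infer_shape(self, in_shapes):
        n_paths = len(in_shapes) if len(in_shapes) > 1 else \
            (in_shapes[0][0] if len(in_shapes[0]) == 2 else 1)
        return (n_paths, self.c_out) if n_paths > 1 else (self.c_out,)

    def forward(self, xs, training):
        x = np.stack(xs, axis=0) if len(xs) > 1 else xs[0]
        y = x @ self.params["w"] + self.params["b"]
        mask = None
        if self.activation == "relu":
            mask = y > 0
            y = np.maximum(y, 0.0)
        self._cache = (x, mask, len(xs))
        return y.astype(np.float32)

    def backward(self, grad):
        x, mask, n_in = self._cache
        if mask is not None:
            grad = grad * mask
        flat_g = grad.reshape(-1, self.c_out)
        flat_x = x.reshape(-1, self.c_in)
        self.grads["w"] += flat_x.T @ flat_g
        self.grads["b"] += flat_g.sum(axis=0)
        dx = grad @ self.params["w"].T
        if n_in > 1:
            return [dx[i] for i in range(n_in)]
        return [dx.astype(np.float32)]


class AddPaths(Layer):
    """Sum over the leading path axis of a stacked tensor (or sum inputs)."""

    def __init__(self, name, inputs):
        super().__init__(name, inputs)

    def infer_shape(self, in_shapes):
        s = in_shapes[0]
        return s[1:] if len(in_shapes) == 1 else s

    def forward(self, xs, training):
        if len(xs) == 1:
            self._cache = (1, xs[0].shape)
            return xs[0].sum(axis=0)
        self._cache = (len(xs), xs[0].shape)
        return np.sum(xs, axis=0)

    def backward(self, grad):
        n_in, shape = self._cache
        if n_in == 1:
            return [np.broadcast_to(grad, shape).astype(np.float32)]
        return [grad.copy() for _ in range(n_in)]


class ChannelScale(Layer):
    """Gate a feature map by a per-channel attention vector: x * a."""

    def __init__(self, name, inputs):
        super().__init__(name, inputs)

    def infer_shape(self, in_shapes):
        return in_shapes[0]

    def forward(self, xs, training):
        x, a = xs
        self._cache = (x, a)
        return x * a[:, None, None, :]

    def backward(self, grad):
        x, a = self._cache
        dx = grad * a[:, None, None, :]
        da = (grad * x).sum(axis=(1, 2))
        return [dx.astype(np.float32), da.astype(np.float32)]


class Concat(Layer):
    def __init__(self, name, inputs):
        super().__init__(name, inputs)

    def infer_shape(self, in_shapes):
        h, w, _ = in_shapes[0]
        return (h, w, sum(s[-1] for s in in_shapes))

    def forward(self, xs, training):
        self._cache = ([x.shape[-1] for x in xs],)
        return np.concatenate(xs, axis=-1)

    def backward(self, grad):
        (widths,) = self._cache
        splits = np.cumsum(widths)[:-1]
        return list(np.split(grad, splits, axis=-1))


class UpSample2(Layer):
    """Nearest-neighbour 2x spatial upsampling (parameter-free)."""

    def __init__(self, name, inputs):
        super().__init__(name, inputs)

    def infer_shape(self, in_shapes):
        h, w, c = in_shapes[0]
        return (2 * h, 2 * w, c)

    def forward(self, xs, training):
        return np.repeat(np.repeat(xs[0], 2, axis=1), 2, axis=2)

    def backward(self, grad):
        n, h, w, c = grad.shape
        g = grad.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))
        return [g.astype(np.float32)]


class ChannelMeanSigmoid(Layer):
    """Parameter-free head: sigmoid of the channel average, one output map."""

    def __init__(self, name, inputs):
        super().__init__(name, inputs)

    def infer_shape(self, in_shapes):
        h, w, _ = in_shapes[0]
        return (h, w, 1)

    def forward(self, xs, training):
        x = xs[0]
        z = np.clip(x.mean(axis=-1, keepdims=True), -60.0, 60.0)
        y = 1.0 / (1.0 + np.exp(-z))
        self._cache = (y, x.shape[-1])
        return y.astype(np.float32)

    def backward(self, grad):
        y, c = self._cache
        dz = grad * y * (1.0 - y)
        return [(np.repeat(dz, c, axis=-1) / c).astype(np.float32)]


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class Network:
    """Named-layer DAG executed in insertion (topological) order."""

    def __init__(self, input_name: str = "Input"):
        self.layers: dict[str, Layer] = {}
        self.input_name = input_name
        self._outputs: dict[str, np.ndarray] = {}

    def add(self, layer: Layer) -> Layer:
        if layer.name in self.layers:
            raise ValueError(f"duplicate layer name {layer.name}")
        for dep in layer.inputs:
            if dep not in self.layers:
                raise ValueError(f"{layer.name} references unknown layer {dep}")
        if not isinstance(layer, Input):
            in_shapes = [self.layers[d].output_shape for d in layer.inputs]
            layer.output_shape = layer.infer_shape(in_shapes)
        self.layers[layer.name] = layer
        return layer

    @property
    def output_name(self) -> str:
        return next(reversed(self.layers))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        outs: dict[str, np.ndarray] = {self.input_name: x.astype(np.float32)}
        for name, layer in self.layers.items():
            if isinstance(layer, Input):
                continue
            outs[name] = layer.forward([outs[d] for d in layer.inputs], training)
        self._outputs = outs
        return outs[self.output_name]

    def layer_output(self, name: str) -> np.ndarray:
        return self._outputs[name]

    def backward(self, grad_out: np.ndarray) -> None:
        """Accumulate parameter gradients from dLoss/dOutput."""
        for layer in self.layers.values():
            layer.zero_grad()
        pending: dict[str, np.ndarray] = {self.output_name: grad_out.astype(np.float32)}
        for name in reversed(self.layers):
            layer = self.layers[name]
            if isinstance(layer, Input) or name not in pending:
                continue
            in_grads = layer.backward(pending.pop(name))
            for dep, g in zip(layer.inputs, in_grads):
                if dep in pending:
                    pending[dep] = pending[dep] + g
                else:
                    pending[dep] = g

    def parameters(self) -> Iterator[tuple[str, str, np.ndarray, np.ndarray]]:
        for lname, layer in self.layers.items():
            for k in layer.params:
                yield lname, k, layer.params[k], layer.grads.get(k)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for lname, layer in self.layers.items():
            for k, v in layer.params.items():
                state[f"{lname}/{k}"] = v.copy()
            for k, v in layer.buffers.items():
                state[f"{lname}/buffer/{k}"] = v.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for lname, layer in self.layers.items():
            for k in layer.params:
                layer.params[k] = state[f"{lname}/{k}"].copy()
            for k in layer.buffers:
                layer.buffers[k] = state[f"{lname}/buffer/{k}"].copy()

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict(dict(data))


@dataclass
class Adam:
    """Adam optimizer over every trainable parameter of a network."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    _m: dict = field(default_factory=dict)
    _v: dict = field(default_factory=dict)
    _t: int = 0

    def step(self, net: Network) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for lname, k, p, g in net.parameters():
            if g is None:
                continue
            key = f"{lname}/{k}"
            m = self._m.setdefault(key, np.zeros_like(p))
            v = self._v.setdefault(key, np.zeros_like(p))
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self._t)
            vhat = v / (1 - b2 ** self._t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
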