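"""Minimal NumPy neural-network core.

Layers operate on NHWC float32 tensors, carry their own parameters and
gradients, and support exact backpropagation (stride-1 'same' convolutions,
2x2/stride-2 max pooling, nearest-neighbour 2x upsampling, dense layers and
the usual activations). An Adam optimiser updates parameters in place.

The layer set is deliberately small: it is exactly what the convolutional
autoencoder, the DCGAN-style balancer and Grad-CAM need, with deterministic
initialisation from an explicit seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import ShapeError

FLOAT = np.float32


class Layer:
    """Base layer: no parameters, identity shapes."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (or any odd k) stride-1 convolution with zero 'same' padding.

    Weight layout: (k*k*c_in, c_out), matching the im2col patch layout
    (rows scan the window as (c_in, ki, kj) flattened C-order after the
    sliding-window view, i.e. (c_in, k, k)).
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        if k % 2 != 1:
            raise ShapeError(f"kernel size must be odd, got {k}")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.W = w.astype(FLOAT)
        self.b = np.zeros(c_out, dtype=FLOAT)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._cols = None
        self._in_shape = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # (N, H, W, c, k, k) view -> (N*H*W, c*k*k) copy
        win = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        n, h, w = x.shape[0], x.shape[1], x.shape[2]
        return win.reshape(n * h * w, self.c_in * self.k * self.k)

    def forward(self, x, train=False):
        if x.shape[-1] != self.c_in:
            raise ShapeError(f"expected {self.c_in} channels, got {x.shape[-1]}")
        self._in_shape = x.shape
        cols = self._im2col(x.astype(FLOAT, copy=False))
        self._cols = cols if train else None
        y = cols @ self.W + self.b
        return y.reshape(x.shape[0], x.shape[1], x.shape[2], self.c_out)

    def backward(self, dy):
        n, h, w, _ = self._in_shape
        dyf = dy.reshape(n * h * w, self.c_out).astype(FLOAT, copy=False)
        if self._cols is not None:  # inference-mode backward (e.g. Grad-CAM) skips dW
            self.grads[0][...] = self._cols.T @ dyf
            self.grads[1][...] = dyf.sum(axis=0)
        # dx = 'same' convolution of dy with the flipped, transposed kernel
        wr = self.W.reshape(self.c_in, self.k, self.k, self.c_out)
        wr = wr[:, ::-1, ::-1, :]  # rotate 180
        wr = wr.transpose(3, 1, 2, 0).reshape(self.c_out * self.k * self.k, self.c_in)
        p = self.k // 2
        dyp = np.pad(dy.reshape(n, h, w, self.c_out), ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(dyp, (self.k, self.k), axis=(1, 2))
        cols = win.reshape(n * h * w, self.c_out * self.k * self.k)
        return (cols @ wr).reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)).astype(FLOAT)
        self.b = np.zeros(d_out, dtype=FLOAT)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._x = None

    def forward(self, x, train=False):
        if x.shape[-1] != self.W.shape[0]:
            raise ShapeError(
                f"dense layer expects {self.W.shape[0]} features, got {x.shape[-1]}"
            )
        self._x = x.astype(FLOAT, copy=False)
        return self._x @ self.W + self.b

    def backward(self, dy):
        dy = dy.astype(FLOAT, copy=False)
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; gradient routed to the argmax."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ShapeError(f"max pooling needs even spatial dims, got {h}x{w}")
        r = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        r = r.reshape(n, h // 2, w // 2, c, 4)
        self._idx = r.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(r, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, h, w, c = self._in_shape
        out = np.zeros((n, h // 2, w // 2, c, 4), dtype=FLOAT)
        np.put_along_axis(out, self._idx[..., None], dy[..., None].astype(FLOAT), axis=-1)
        out = out.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return out.reshape(n, h, w, c)


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling; gradient sums over each 2x2 block."""

    def forward(self, x, train=False):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy):
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Flatten(Layer):
    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]):
        super().__init__()
        self.shape = shape

    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(FLOAT, copy=False)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(FLOAT, copy=False)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x).astype(FLOAT, copy=False)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy).astype(FLOAT, copy=False)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = sigmoid(x)
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ShapeError(f"dropout rate must be in [0,1), got {p}")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(FLOAT) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Sequential:
    """Ordered layer container with full and partial backpropagation."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads]

    def forward(self, x, train=False):
        self._outputs = []
        for l in self.layers:
            x = l.forward(x, train=train)
            self._outputs.append(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy

    def backward_to(self, dy, layer_index: int) -> np.ndarray:
        """Backpropagate from the output down to the output of layer_index."""
        for l in reversed(self.layers[layer_index + 1 :]):
            dy = l.backward(dy)
        return dy

    def output_of(self, layer_index: int) -> np.ndarray:
        return self._outputs[layer_index]

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        own = self.params
        if len(arrays) != len(own):
            raise ShapeError(
                f"state has {len(arrays)} arrays, model has {len(own)} parameters"
            )
        for p, a in zip(own, arrays):
            if p.shape != a.shape:
                raise ShapeError(f"parameter shape {p.shape} != stored {a.shape}")
            p[...] = a


class Adam:
    """Adaptive moment estimation, updating parameter arrays in place.

    ``l2`` adds decoupled-style L2 gradient (l2 * W) for parameters with
    ndim > 1 (weights, not biases).
    """

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, l2=0.0):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps, self.l2 = lr, betas[0], betas[1], eps, l2
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(p.dtype, copy=False)
            if self.l2 and p.ndim > 1:
                g = g + self.l2 * p
            m[...] = self.b1 * m + (1.0 - self.b1) * g
            v[...] = self.b2 * v + (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=FLOAT)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
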