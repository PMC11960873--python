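"""Minimal CNN layer framework: forward, backprop, Adam.

Layers operate on NHWC float32 arrays (or NxF for dense layers) and retain
the activations needed both for gradient backpropagation and for the
relevance-propagation pass in :mod:`caprivox.explain`.  Convolutions are
stride-1 with 'same' zero padding, implemented as an offset-sliced im2col
followed by one BLAS matmul; the adjoint convolution used in the backward
pass is a correlation with channel-swapped, spatially flipped kernels and
is reused by the relevance rules.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "MaxPool2x2", "Flatten", "Dense", "Dropout", "Adam",
           "conv2d", "conv2d_transpose", "softmax", "cross_entropy"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N, H, W, k*k*C) patches with same zero padding."""
    p = k // 2
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    cols = np.empty((n, h, w, k * k * c), dtype=x.dtype)
    i = 0
    for ky in range(k):
        for kx in range(k):
            cols[..., i * c : (i + 1) * c] = xp[:, ky : ky + h, kx : kx + w, :]
            i += 1
    return cols


def _weights_2d(weights: np.ndarray) -> np.ndarray:
    """(out_ch, in_ch, k, k) -> (k*k*in_ch, out_ch) matching _im2col order."""
    out_ch, in_ch, k, _ = weights.shape
    return np.ascontiguousarray(weights.transpose(2, 3, 1, 0).reshape(k * k * in_ch, out_ch))


def conv2d(x: np.ndarray, weights: np.ndarray, cols: np.ndarray | None = None) -> np.ndarray:
    """Stride-1 same-padding correlation; x NHWC, weights (out_ch, in_ch, k, k)."""
    k = weights.shape[2]
    if cols is None:
        cols = _im2col(x, k)
    return cols @ _weights_2d(weights)


def conv2d_transpose(g: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`conv2d`: maps output-shaped tensors back to input shape."""
    w_adj = np.ascontiguousarray(weights[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    return conv2d(g, w_adj)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []
        self.last_input: np.ndarray | None = None
        self.last_output: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """kxk conv, stride 1, same padding, optional fused ReLU; channels last."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, relu: bool = True,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k * k
        self.W = (rng.standard_normal((out_ch, in_ch, k, k)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.k = k
        self.relu = relu
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._cols: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self.last_input = x
        cols = _im2col(x, self.k)
        self._cols = cols if train else None
        z = cols @ _weights_2d(self.W) + self.b
        self._pre_act = z if self.relu else None
        out = np.maximum(z, 0.0) if self.relu else z
        self.last_output = out
        return out

    def backward(self, grad: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        if self.relu:
            grad = grad * (self._pre_act > 0)
        cols = self._cols if self._cols is not None else _im2col(self.last_input, self.k)
        out_ch, in_ch, k = self.W.shape[0], self.W.shape[1], self.k
        gflat = grad.reshape(-1, out_ch)
        dW2 = cols.reshape(-1, cols.shape[-1]).T @ gflat  # (k*k*in, out)
        self.grads[0][...] = dW2.reshape(k, k, in_ch, out_ch).transpose(3, 2, 0, 1)
        self.grads[1][...] = gflat.sum(axis=0)
        if not need_input_grad:
            return None
        return conv2d_transpose(grad, self.W)

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self.last_input = x
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xv = x[:, : h2 * 2, : w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
        out = xv.max(axis=(2, 4))
        # winners mask (ties share), reused by backward and relevance routing
        mask = xv == out[:, :, np.newaxis, :, np.newaxis, :]
        self._mask = mask / mask.sum(axis=(2, 4), keepdims=True)
        self._trim = (h2 * 2, w2 * 2)
        self.last_output = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.route(grad)

    def route(self, grad: np.ndarray) -> np.ndarray:
        """Distribute an output-shaped tensor back onto the max positions."""
        n, h2, w2, c = grad.shape
        g = self._mask * grad[:, :, np.newaxis, :, np.newaxis, :]
        out = np.zeros_like(self.last_input)
        out[:, : self._trim[0], : self._trim[1], :] = g.reshape(n, h2 * 2, w2 * 2, c)
        return out


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self.last_input = x
        self.last_output = x.reshape(x.shape[0], -1)
        return self.last_output

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self.last_input.shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, relu: bool = True,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.W = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.relu = relu
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self.last_input = x
        z = x @ self.W + self.b
        self._pre_act = z if self.relu else None
        out = np.maximum(z, 0.0) if self.relu else z
        self.last_output = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.relu:
            grad = grad * (self._pre_act > 0)
        self.grads[0][...] = self.last_input.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T

    @property
    def n_channels(self) -> int:
        return self.W.shape[1]


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self.last_input = x
        if train and self.rate > 0.0:
            self._mask = ((self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)).astype(np.float32)
            out = x * self._mask
        else:
            self._mask = None
            out = x
        self.last_output = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean NLL and the gradient w.r.t. the logits (softmax already applied)."""
    n = len(y)
    loss = -np.mean(np.log(probs[np.arange(n), y] + 1e-12))
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


class Adam:
    def __init__(self, layers: list[Layer], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.v = [[np.zeros_like(p) for p in l.params] for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m[...] = self.b1 * m + (1 - self.b1) * g
                v[...] = self.b2 * v + (1 - self.b2) * g * g
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
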