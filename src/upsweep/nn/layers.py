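"""Neural-net layers built on the autodiff engine.

Layers own parameter tensors (Glorot-uniform initialized from a caller
supplied generator) and expose ``__call__``; stateless transforms
(``dropout``, ``flatten``, ``max_pool_2x2``) are free functions.  All
convolutions are 'valid' with stride 1, matching classic LeNet.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor, stack, take

__all__ = [
    "Layer",
    "Conv2D",
    "Conv1D",
    "Dense",
    "BatchNorm",
    "GRU",
    "dropout",
    "flatten",
    "max_pool_2x2",
]

DTYPE = np.float32


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    def params(self) -> list[Tensor]:
        return [v for v in vars(self).values() if isinstance(v, Tensor) and v.requires_grad]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Tensor(_glorot(rng, (n_in, n_out), n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Conv2D(Layer):
    """Valid 2-D convolution, stride 1.  Input (N, C, H, W) -> (N, F, H', W')."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        k = kernel
        fan_in, fan_out = c_in * k * k, c_out * k * k
        self.kernel = k
        self.W = Tensor(
            _glorot(rng, (c_out, c_in, k, k), fan_in, fan_out), requires_grad=True
        )
        self.b = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        k = self.kernel
        W, b = self.W, self.b
        xd, wd = x.data, W.data
        n, c, h, w = xd.shape
        f = wd.shape[0]
        ho, wo = h - k + 1, w - k + 1
        # (N, C, H', W', k, k) view -> (N*H'*W', C*k*k) copy for BLAS
        view = sliding_window_view(xd, (k, k), axis=(2, 3))
        cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * k * k
        )
        wmat = wd.reshape(f, c * k * k).T  # (C*k*k, F)
        out = (cols @ wmat + b.data).reshape(n, ho, wo, f).transpose(0, 3, 1, 2)

        def backward(g):
            gf = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, f)
            gw = (cols.T @ gf).T.reshape(wd.shape)
            gb = gf.sum(axis=0)
            gcols = (gf @ wmat.T).reshape(n, ho, wo, c, k, k)
            gx = np.zeros_like(xd)
            for i in range(k):
                for j in range(k):
                    gx[:, :, i : i + ho, j : j + wo] += gcols[:, :, :, :, i, j].transpose(
                        0, 3, 1, 2
                    )
            return (gx, gw, gb)

        return Tensor._node(out, (x, W, b), backward)


class Conv1D(Layer):
    """Valid 1-D convolution along time.  Input (N, T, C) -> (N, T', F)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        k = kernel
        self.kernel = k
        self.W = Tensor(
            _glorot(rng, (k * c_in, c_out), k * c_in, c_out), requires_grad=True
        )
        self.b = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        k = self.kernel
        W, b = self.W, self.b
        xd = x.data
        n, t, c = xd.shape
        to = t - k + 1
        view = sliding_window_view(xd, k, axis=1)  # (N, T', C, k)
        cols = np.ascontiguousarray(view.transpose(0, 1, 3, 2)).reshape(n * to, k * c)
        out = (cols @ W.data + b.data).reshape(n, to, -1)

        def backward(g):
            gf = g.reshape(n * to, -1)
            gw = cols.T @ gf
            gb = gf.sum(axis=0)
            gcols = (gf @ W.data.T).reshape(n, to, k, c)
            gx = np.zeros_like(xd)
            for i in range(k):
                gx[:, i : i + to, :] += gcols[:, :, i, :]
            return (gx, gw, gb)

        return Tensor._node(out, (x, W, b), backward)


def max_pool_2x2(x: Tensor) -> Tensor:
    """Non-overlapping 2x2 max pooling on (N, C, H, W); H, W must be even."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("max_pool_2x2 needs even spatial dimensions")
    h2, w2 = h // 2, w // 2
    blocks = (
        x.data.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h2, w2, 4
        )
    )
    arg = blocks.argmax(axis=-1)
    out = np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        gblocks = np.zeros_like(blocks)
        np.put_along_axis(gblocks, arg[..., None], g[..., None], axis=-1)
        gx = gblocks.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h, w
        )
        return (gx,)

    return Tensor._node(out, (x,), backward)


def flatten(x: Tensor) -> Tensor:
    n = x.data.shape[0]
    return x.reshape(n, -1)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout: at train time zero each unit with prob ``p`` and
    rescale by 1/(1-p); identity at inference."""
    if not training or p <= 0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(DTYPE) / DTYPE(1.0 - p)
    return x * Tensor(mask)


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (channel) axis.

    Tracks running moments (momentum 0.9) for inference.
    """

    def __init__(self, n_channels: int, eps: float = 1e-5, momentum: float = 0.9):
        self.gamma = Tensor(np.ones(n_channels, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(n_channels, dtype=DTYPE), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(n_channels, dtype=DTYPE)
        self.running_var = np.ones(n_channels, dtype=DTYPE)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        axes = tuple(range(x.data.ndim - 1))
        if training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mu
            ).astype(DTYPE)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(DTYPE)
        else:
            mu, var = self.running_mean, self.running_var
        gamma, beta = self.gamma, self.beta
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv_std
        out = xhat * gamma.data + beta.data
        m = float(np.prod([x.data.shape[a] for a in axes]))

        def backward(g):
            ggamma = (g * xhat).sum(axis=axes)
            gbeta = g.sum(axis=axes)
            if training:
                gx = (
                    gamma.data
                    * inv_std
                    * (
                        g
                        - g.mean(axis=axes)
                        - xhat * (g * xhat).sum(axis=axes) / m
                    )
                )
            else:
                gx = g * gamma.data * inv_std
            return (gx, ggamma, gbeta)

        return Tensor._node(out, (x, gamma, beta), backward)


class GRU(Layer):
    """Gated recurrent unit layer; returns the full output sequence.

    Input (N, T, C); output (N, T, H).  Gates follow the standard
    formulation: z = sigmoid(xWz + hUz + bz), r = sigmoid(xWr + hUr + br),
    htilde = tanh(xWh + (r*h)Uh + bh), h' = (1-z)*h + z*htilde.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        for name in ("Wz", "Wr", "Wh"):
            setattr(
                self,
                name,
                Tensor(_glorot(rng, (n_in, n_hidden), n_in, n_hidden), requires_grad=True),
            )
        for name in ("Uz", "Ur", "Uh"):
            setattr(
                self,
                name,
                Tensor(
                    _glorot(rng, (n_hidden, n_hidden), n_hidden, n_hidden),
                    requires_grad=True,
                ),
            )
        for name in ("bz", "br", "bh"):
            setattr(self, name, Tensor(np.zeros(n_hidden, dtype=DTYPE), requires_grad=True))

    def __call__(self, x: Tensor) -> Tensor:
        n, t, _ = x.data.shape
        h = Tensor(np.zeros((n, self.n_hidden), dtype=x.data.dtype))
        outs = []
        grad_input = x.requires_grad
        for step in range(t):
            # constant inputs are sliced outside the graph to keep the tape small
            xt = take(x, step, axis=1) if grad_input else Tensor(x.data[:, step, :])
            z = (xt @ self.Wz + h @ self.Uz + self.bz).sigmoid()
            r = (xt @ self.Wr + h @ self.Ur + self.br).sigmoid()
            htilde = (xt @ self.Wh + (r * h) @ self.Uh + self.bh).tanh()
            h = (1.0 - z) * h + z * htilde
            outs.append(h)
        return stack(outs, axis=1)
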