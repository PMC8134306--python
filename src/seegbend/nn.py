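"""Minimal feed-forward neural-network kernel (numpy, CPU).

Implements exactly the layer vocabulary the bending-regression networks
need — dense, PReLU, leaky ReLU, dropout, 1D batch normalization, 3D
convolution (3x3x3, zero padding), 2x2x2 max pooling — with hand-written
reverse-mode gradients, the Adam optimizer with (coupled) L2 weight
decay, and a reduce-on-plateau learning-rate scheduler.  Gradients are
verified against central finite differences in the test suite.

Forward-pass modes:

* ``train=True``      — dropout active, batch-norm uses batch statistics.
* ``stochastic=True`` — dropout active, batch-norm frozen at running
  statistics (the Monte-Carlo-dropout inference mode).
* neither             — fully deterministic evaluation.
"""

from __future__ import annotations

import copy

import numpy as np

__all__ = [
    "Param", "Layer", "Dense", "PReLU", "ReLU", "LeakyReLU", "Dropout",
    "BatchNorm1d", "Conv3d", "MaxPool3d", "Flatten", "Sequential",
    "Adam", "ReduceLROnPlateau", "mse_loss",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list:
        return []

    def forward(self, x, *, train=False, stochastic=False, rng=None):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError

    # state beyond Params (e.g. batch-norm running stats)
    def extra_state(self) -> dict:
        return {}

    def load_extra_state(self, state: dict) -> None:
        pass


class Dense(Layer):
    """Affine layer y = x W + b, He-normal initialization.

    ``init_scale`` shrinks the initial weights; the output head of a
    regression network targeting millimetre-scale labels starts near
    zero so early training is not dominated by the random head.
    """

    def __init__(self, n_in: int, n_out: int, rng, init_scale: float = 1.0):
        scale = init_scale * np.sqrt(2.0 / n_in)
        self.W = Param("W", rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param("b", np.zeros(n_out))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, **kw):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class PReLU(Layer):
    """Parametric rectifier with a single learned negative slope."""

    def __init__(self, init: float = 0.25):
        self.a = Param("a", np.array([init]))
        self._x = None

    def params(self):
        return [self.a]

    def forward(self, x, **kw):
        self._x = x
        return np.where(x > 0, x, self.a.value[0] * x)

    def backward(self, dout):
        x = self._x
        self.a.grad += np.array([np.sum(dout * np.where(x > 0, 0.0, x))])
        return dout * np.where(x > 0, 1.0, self.a.value[0])


class ReLU(Layer):
    def forward(self, x, **kw):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x, **kw):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class Dropout(Layer):
    """Inverted dropout; active in train and stochastic (MC) modes."""

    def __init__(self, p: float = 0.1):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self._mask = None

    def forward(self, x, *, train=False, stochastic=False, rng=None):
        if (train or stochastic) and self.p > 0:
            if rng is None:
                raise ValueError("dropout in train/stochastic mode needs an rng")
            self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
            return x * self._mask
        self._mask = None
        return x

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class BatchNorm1d(Layer):
    """Per-feature batch normalization with running statistics.

    Uses batch statistics when ``train=True`` and frozen running
    statistics otherwise — including during stochastic MC-dropout passes,
    where only dropout is resampled.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param("gamma", np.ones(dim))
        self.beta = Param("beta", np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def extra_state(self):
        return {"running_mean": self.running_mean.copy(),
                "running_var": self.running_var.copy()}

    def load_extra_state(self, state):
        self.running_mean = np.asarray(state["running_mean"], dtype=float).copy()
        self.running_var = np.asarray(state["running_var"], dtype=float).copy()

    def forward(self, x, *, train=False, stochastic=False, rng=None):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            n = x.shape[0]
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            )
            unbiased = var * n / max(n - 1, 1)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * unbiased
            )
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std, train, x.shape[0])
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout):
        xhat, inv_std, trained, n = self._cache
        self.gamma.grad += np.sum(dout * xhat, axis=0)
        self.beta.grad += dout.sum(axis=0)
        dxhat = dout * self.gamma.value
        if not trained:
            return dxhat * inv_std
        return (inv_std / n) * (
            n * dxhat
            - dxhat.sum(axis=0)
            - xhat * np.sum(dxhat * xhat, axis=0)
        )


class Conv3d(Layer):
    """3D convolution, kernel 3x3x3, stride 1, zero padding (same size).

    Input (B, C_in, D, H, W) -> output (B, C_out, D, H, W).  Implemented
    via im2col: patches are gathered into a (B*D*H*W, C_in*k^3) matrix
    and both passes reduce to matrix products.
    """

    def __init__(self, in_ch: int, out_ch: int, rng, kernel: int = 3,
                 input_grad: bool = True):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.k = kernel
        self.input_grad = input_grad  # False when this is the input layer
        fan_in = in_ch * kernel**3
        scale = np.sqrt(2.0 / fan_in)
        self.W = Param("W", rng.normal(0.0, scale,
                                       size=(out_ch, in_ch, kernel, kernel, kernel)))
        self.b = Param("b", np.zeros(out_ch))
        self._cols = None

    def params(self):
        return [self.W, self.b]

    @staticmethod
    def _im2col(x: np.ndarray, k: int) -> np.ndarray:
        """Zero-padded sliding patches: (B, C, D, H, W) -> (B*D*H*W, C*k^3)."""
        p = k // 2
        B, C, D, H, W_ = x.shape
        xpad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(
            xpad, (k, k, k), axis=(2, 3, 4)
        )
        return np.ascontiguousarray(
            win.transpose(0, 2, 3, 4, 1, 5, 6, 7)
        ).reshape(B * D * H * W_, C * k**3)

    def forward(self, x, **kw):
        B, C, D, H, W_ = x.shape
        self._inshape = x.shape
        self._cols = self._im2col(x, self.k)
        out_ch = self.W.value.shape[0]
        y = self._cols @ self.W.value.reshape(out_ch, -1).T + self.b.value
        return (y.reshape(B, D, H, W_, out_ch)
                 .transpose(0, 4, 1, 2, 3))

    def backward(self, dout):
        B, C, D, H, W_ = self._inshape
        out_ch = self.W.value.shape[0]
        dy = np.ascontiguousarray(
            dout.transpose(0, 2, 3, 4, 1)
        ).reshape(-1, out_ch)
        self.W.grad += (dy.T @ self._cols).reshape(self.W.value.shape)
        self.b.grad += dy.sum(axis=0)
        if not self.input_grad:
            return None
        # dx = correlation of dout with the spatially flipped kernel,
        # input/output channels swapped
        w_flip = np.flip(self.W.value, axis=(2, 3, 4)).transpose(1, 0, 2, 3, 4)
        dcols = self._im2col(dout, self.k)
        dx = dcols @ w_flip.reshape(C, -1).T
        return dx.reshape(B, D, H, W_, C).transpose(0, 4, 1, 2, 3)


class MaxPool3d(Layer):
    """Non-overlapping max pooling (default 2x2x2, floor division)."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, **kw):
        s = self.size
        B, C, D, H, W_ = x.shape
        d, h, w = D // s, H // s, W_ // s
        self._inshape = x.shape
        xc = x[:, :, : d * s, : h * s, : w * s]
        xr = (
            xc.reshape(B, C, d, s, h, s, w, s)
            .transpose(0, 1, 2, 4, 6, 3, 5, 7)
            .reshape(B, C, d, h, w, s**3)
        )
        self._argmax = xr.argmax(axis=-1)
        return xr.max(axis=-1)

    def backward(self, dout):
        s = self.size
        B, C, D, H, W_ = self._inshape
        d, h, w = D // s, H // s, W_ // s
        dxr = np.zeros((B, C, d, h, w, s**3))
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=-1)
        dxc = (
            dxr.reshape(B, C, d, h, w, s, s, s)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(B, C, d * s, h * s, w * s)
        )
        dx = np.zeros(self._inshape)
        dx[:, :, : d * s, : h * s, : w * s] = dxc
        return dx


class Flatten(Layer):
    def forward(self, x, **kw):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, **kw):
        for layer in self.layers:
            x = layer.forward(x, **kw)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def extra_state(self):
        return {i: l.extra_state() for i, l in enumerate(self.layers)
                if l.extra_state()}

    def load_extra_state(self, state):
        for i, s in state.items():
            self.layers[int(i)].load_extra_state(s)


# ---------------------------------------------------------------------------
# optimization


def mse_loss(y_pred: np.ndarray, y_true: np.ndarray):
    """Mean squared error over samples *and* components, with its gradient.

    L = (1/(N*K)) sum_nk (y_nk - yhat_nk)^2 for (N, K) arrays — the
    per-component convention under which reported values are displayed
    x10^3.
    """
    diff = y_pred - y_true
    loss = float(np.mean(diff * diff))
    grad = 2.0 * diff / diff.size
    return loss, grad


class Adam:
    """Adam with coupled L2 weight decay (grad += wd * param)."""

    def __init__(self, params, lr=1e-3, weight_decay=0.0,
                 betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad + self.weight_decay * p.value
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Drop the learning rate by ``factor`` when the monitored loss plateaus."""

    def __init__(self, optimizer: Adam, factor=0.1, patience=10,
                 threshold=1e-4, min_lr=1e-6):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.threshold = threshold
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0
        self.drop_epochs: list = []

    def step(self, loss: float, epoch: int | None = None):
        if loss < self.best * (1 - self.threshold):
            self.best = loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                if self.opt.lr > self.min_lr * (1 + 1e-9):
                    self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                    self.drop_epochs.append(epoch)
                self.bad_epochs = 0


def clone_state(params, extra_state) -> dict:
    return {
        "params": [p.value.copy() for p in params],
        "extra": copy.deepcopy(extra_state),
    }


def load_state(params, load_extra, state: dict) -> None:
    for p, v in zip(params, state["params"]):
        p.value[...] = v
    load_extra(state["extra"])
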