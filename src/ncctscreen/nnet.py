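"""A compact sequential CNN engine on numpy.

Implements exactly the layer set the screening models need — 2-D
convolution, batch normalization (1-D and 2-D), max pooling, dense,
ReLU/sigmoid, dropout — with manual backpropagation and an Adam optimizer
supporting per-step learning-rate decay lr/(1+decay*step).  Convolutions
use im2col/col2im so the heavy lifting is one matrix multiply per layer.

All randomness (initialization, dropout) flows through a caller-supplied
``numpy.random.Generator``; single-threaded numpy makes runs bit-reproducible
for a fixed seed.

Array layout: images are (N, C, H, W) float32; dense activations (N, F).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "Dense",
    "BatchNorm",
    "ReLU",
    "Sigmoid",
    "Dropout",
    "MaxPool2D",
    "Flatten",
    "Network",
    "Adam",
    "categorical_crossentropy",
    "mse_loss",
]


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    """Base layer: forward caches what backward needs; params/grads are lists."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def describe(self) -> dict:
        return {"type": type(self).__name__}


def im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N*OH*OW, C*kh*kw) patches, stride 1."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh, ow = h + 2 * pad - kh + 1, w + 2 * pad - kw + 1
    s0, s1, s2, s3 = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x, shape=(n, c, oh, ow, kh, kw), strides=(s0, s1, s2, s3, s2, s3)
    )
    return patches.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)


def col2im(cols: np.ndarray, x_shape: tuple[int, ...], kh: int, kw: int, pad: int) -> np.ndarray:
    """Adjoint of im2col (scatter-add), stride 1."""
    n, c, h, w = x_shape
    oh, ow = h + 2 * pad - kh + 1, w + 2 * pad - kw + 1
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + oh, j : j + ow] += cols[:, :, i, j]
    return xp[:, :, pad : pad + h, pad : pad + w] if pad else xp


class Conv2D(Layer):
    """3x3 (or kxk) stride-1 convolution with 'same' or 'valid' padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, padding: str = "same",
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.pad = kernel // 2 if padding == "same" else 0
        fan_in = in_ch * kernel * kernel
        w = _he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in)
        b = np.zeros(out_ch, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x_shape = x.shape
        n, _, h, w = x.shape
        k = self.kernel
        self._cols = im2col(x, k, k, self.pad)
        wmat = self.params[0].reshape(self.out_ch, -1)
        out = self._cols @ wmat.T + self.params[1]
        oh = h + 2 * self.pad - k + 1
        ow = w + 2 * self.pad - k + 1
        return out.reshape(n, oh, ow, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, oc, oh, ow = grad.shape
        gmat = grad.transpose(0, 2, 3, 1).reshape(-1, oc)
        self.grads[0][...] = (gmat.T @ self._cols).reshape(self.params[0].shape)
        self.grads[1][...] = gmat.sum(axis=0)
        dcols = gmat @ self.params[0].reshape(oc, -1)
        return col2im(dcols, self._x_shape, self.kernel, self.kernel, self.pad)

    def describe(self) -> dict:
        return {"type": "Conv2D", "in_channels": self.in_ch, "out_channels": self.out_ch,
                "kernel": self.kernel, "padding": self.pad}


class Dense(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w = _he_init(rng, (in_f, out_f), in_f)
        b = np.zeros(out_f, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self.in_f, self.out_f = in_f, out_f

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.params[0].T

    @property
    def n_params(self) -> int:
        return (self.in_f + 1) * self.out_f

    def describe(self) -> dict:
        return {"type": "Dense", "units": self.out_f, "n_params": self.n_params}


class BatchNorm(Layer):
    """Batch normalization over features (2-D input) or channels (4-D input).

    Training uses batch statistics and maintains exponential running moments
    for inference.
    """

    def __init__(self, n_feat: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        gamma = np.ones(n_feat, dtype=np.float32)
        beta = np.zeros(n_feat, dtype=np.float32)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]
        self.running_mean = np.zeros(n_feat, dtype=np.float32)
        self.running_var = np.ones(n_feat, dtype=np.float32)
        self.momentum, self.eps, self.n_feat = momentum, eps, n_feat

    @staticmethod
    def _moments_axes(x: np.ndarray):
        if x.ndim == 2:
            return 0
        if x.ndim == 4:
            return (0, 2, 3)
        raise ValueError(f"BatchNorm expects 2-D or 4-D input, got {x.ndim}-D")

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = self._moments_axes(x)
        shape = [1] * x.ndim
        shape[1] = x.shape[1]
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._xhat = (x - mean.reshape(shape)) / np.sqrt(var.reshape(shape) + self.eps)
        self._var, self._axes, self._shape = var, axes, shape
        self._m = x.size // x.shape[1]
        self._training = training
        return self.params[0].reshape(shape) * self._xhat + self.params[1].reshape(shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        shape, axes = self._shape, self._axes
        self.grads[0][...] = (grad * self._xhat).sum(axis=axes)
        self.grads[1][...] = grad.sum(axis=axes)
        g = grad * self.params[0].reshape(shape)
        if not self._training:
            return g / np.sqrt(self._var.reshape(shape) + self.eps)
        m = self._m
        inv_sd = 1.0 / np.sqrt(self._var.reshape(shape) + self.eps)
        sum_g = g.sum(axis=axes).reshape(shape)
        sum_gx = (g * self._xhat).sum(axis=axes).reshape(shape)
        return (inv_sd / m) * (m * g - sum_g - self._xhat * sum_gx)

    def describe(self) -> dict:
        return {"type": "BatchNorm", "features": self.n_feat}


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._y * (1.0 - self._y)

    def describe(self) -> dict:
        return {"type": "Sigmoid"}


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask

    def describe(self) -> dict:
        return {"type": "Dropout", "rate": self.rate}


class MaxPool2D(Layer):
    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        s = self.size
        if h % s or w % s:
            raise ValueError(f"MaxPool2D: spatial dims {h}x{w} not divisible by {s}")
        xr = x.reshape(n, c, h // s, s, w // s, s)
        out = xr.max(axis=(3, 5))
        self._argmask = xr == out[:, :, :, None, :, None]
        self._x_shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        s = self.size
        g = grad[:, :, :, None, :, None] * self._argmask
        # split ties evenly so the adjoint stays exact
        counts = self._argmask.sum(axis=(3, 5), keepdims=True)
        return (g / counts).reshape(self._x_shape)

    def describe(self) -> dict:
        return {"type": "MaxPool2D", "size": self.size}


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Network:
    """A plain sequential stack with a JSON-able architecture manifest."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def recalibrate_batchnorm(self, batches) -> None:
        """Re-estimate BatchNorm inference statistics ("precise BN").

        Dropout layers upstream of a BatchNorm inflate its train-time batch
        moments, so exponential running averages collected during training
        misrepresent the dropout-free inference distribution.  This pass
        replays representative batches with dropout off, normalizing each
        BatchNorm with its batch statistics while accumulating them, then
        installs the averaged moments as the inference statistics.
        """
        bns = [l for l in self.layers if isinstance(l, BatchNorm)]
        if not bns:
            return
        acc = {id(bn): [] for bn in bns}
        for xb in batches:
            x = xb
            for layer in self.layers:
                if isinstance(layer, BatchNorm):
                    axes = layer._moments_axes(x)
                    mean = x.mean(axis=axes)
                    var = x.var(axis=axes)
                    acc[id(layer)].append((mean, var))
                    shape = [1] * x.ndim
                    shape[1] = x.shape[1]
                    xhat = (x - mean.reshape(shape)) / np.sqrt(var.reshape(shape) + layer.eps)
                    x = layer.params[0].reshape(shape) * xhat + layer.params[1].reshape(shape)
                elif isinstance(layer, Dropout):
                    x = layer.forward(x, training=False)
                else:
                    x = layer.forward(x, training=False)
        for bn in bns:
            means, variances = zip(*acc[id(bn)])
            bn.running_mean = np.mean(means, axis=0).astype(np.float32)
            bn.running_var = np.mean(variances, axis=0).astype(np.float32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def manifest(self) -> list[dict]:
        return [layer.describe() for layer in self.layers]

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                state[f"layer{i}.param{j}"] = p
            if isinstance(layer, BatchNorm):
                state[f"layer{i}.running_mean"] = layer.running_mean
                state[f"layer{i}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j in range(len(layer.params)):
                layer.params[j][...] = state[f"layer{i}.param{j}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = state[f"layer{i}.running_mean"]
                layer.running_var[...] = state[f"layer{i}.running_var"]

    def save(self, path: str) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path: str) -> None:
        with np.load(path) as data:
            self.load_state_dict(dict(data))


class Adam:
    """Adam with optional per-step learning-rate decay lr_t = lr/(1+decay*t)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7, decay: float = 0.0) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps, self.decay = lr, beta1, beta2, eps, decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr / (1.0 + self.decay * (self.t - 1))
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= lr_t * mhat / (np.sqrt(vhat) + self.eps)


def categorical_crossentropy(probs: np.ndarray, onehot: np.ndarray,
                             eps: float = 1e-7) -> tuple[float, np.ndarray]:
    """Loss and gradient w.r.t. the (sigmoid) output activations.

    Per the usual framework convention for categorical crossentropy on
    probabilities, outputs are renormalized to sum to one across classes
    before the log-loss — this is what makes the per-unit sigmoid output
    head trainable with this loss.
    """
    p = np.clip(probs, eps, None)
    z = p.sum(axis=1, keepdims=True)
    q = p / z
    n = probs.shape[0]
    loss = float(-(onehot * np.log(np.clip(q, eps, 1.0))).sum() / n)
    grad = (-(onehot / p) + onehot.sum(axis=1, keepdims=True) / z) / n
    return loss, grad


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    loss = float(np.mean(diff**2))
    return loss, 2.0 * diff / diff.size
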