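"""Minimal NumPy compute engine for 3-D convolutional networks.

Implements exactly the layer set the classifier needs — 3-D convolution
(im2col + BLAS matmul), batch normalization, LeakyReLU, 2x2x2 max pooling,
squeeze-and-excitation channel attention, dropout, and a dense head — each
with an analytic backward pass, plus He initialization, softmax
cross-entropy, and Adam.  Everything is deterministic given the generator
passed at construction; dtype is float32 by default (float64 for gradient
checks).

Tensors are laid out channels-first: (N, C, H, W, D).
"""

from __future__ import annotations

import numpy as np

from .io_core import DimensionError, TrainingError

__all__ = [
    "Param", "Layer", "Conv3d", "BatchNorm3d", "LeakyReLU", "MaxPool3d",
    "SEBlock", "Dropout", "Flatten", "Dense", "Network", "Adam",
    "softmax", "cross_entropy_with_logits", "se_squeeze", "se_excite",
    "se_scale",
]


class Param:
    """A trainable array with its gradient and an L2-decay flag."""

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = False):
        self.value = value
        self.grad = np.zeros_like(value)
        self.decay = decay


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# Convolution
# ---------------------------------------------------------------------------

class Conv3d(Layer):
    """3-D convolution, 'same' zero padding or 'valid'.

    ``kernel='full'`` makes a valid convolution whose kernel equals the
    input's remaining spatial extent (resolved at build time), collapsing it
    to 1x1x1 — used by the wide head convolution.
    """

    def __init__(self, in_ch: int, out_ch: int,
                 kernel: tuple[int, int, int] = (3, 3, 3),
                 padding: str = "same", rng: np.random.Generator | None = None,
                 dtype=np.float32):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel = tuple(kernel)
        self.padding = padding
        fan_in = in_ch * int(np.prod(self.kernel))
        rng = rng or np.random.default_rng(0)
        w = rng.standard_normal((out_ch, in_ch, *self.kernel)) * np.sqrt(2.0 / fan_in)
        self.weight = Param(w.astype(dtype), decay=True)
        self.bias = Param(np.zeros(out_ch, dtype=dtype))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _pads(self) -> tuple[tuple[int, int], ...]:
        if self.padding == "valid":
            return ((0, 0),) * 3
        # 'same' for odd kernels: symmetric k//2
        return tuple((k // 2, k // 2) for k in self.kernel)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.shape[1] != self.in_ch:
            raise DimensionError(
                f"conv expects {self.in_ch} channels, got {x.shape[1]}")
        kh, kw, kd = self.kernel
        pads = self._pads()
        xp = np.pad(x, ((0, 0), (0, 0), *pads)) if self.padding == "same" else x
        N = x.shape[0]
        oh, ow, od = (xp.shape[2] - kh + 1, xp.shape[3] - kw + 1,
                      xp.shape[4] - kd + 1)
        if min(oh, ow, od) < 1:
            raise DimensionError(
                f"kernel {self.kernel} larger than padded input {xp.shape[2:]}")
        # accumulate over kernel offsets: batched GEMM per tap avoids the
        # im2col copy, which dominates at these tensor sizes
        W = self.weight.value
        out = np.zeros((N, self.out_ch, oh * ow * od), dtype=x.dtype)
        for i in range(kh):
            for j in range(kw):
                for l in range(kd):
                    xs = np.ascontiguousarray(
                        xp[:, :, i:i + oh, j:j + ow, l:l + od]
                    ).reshape(N, self.in_ch, -1)
                    out += W[:, :, i, j, l] @ xs
        out = out.reshape(N, self.out_ch, oh, ow, od)
        out += self.bias.value[None, :, None, None, None]
        if train:
            self._cache = (xp, x.shape, (oh, ow, od))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp, x_shape, (oh, ow, od) = self._cache
        N = x_shape[0]
        kh, kw, kd = self.kernel
        g = np.ascontiguousarray(grad).reshape(N, self.out_ch, -1)
        self.bias.grad += grad.sum(axis=(0, 2, 3, 4))
        W = self.weight.value
        dxp = np.zeros(xp.shape, dtype=grad.dtype)
        for i in range(kh):
            for j in range(kw):
                for l in range(kd):
                    xs = np.ascontiguousarray(
                        xp[:, :, i:i + oh, j:j + ow, l:l + od]
                    ).reshape(N, self.in_ch, -1)
                    # dW tap: sum_n g_n @ xs_n^T
                    self.weight.grad[:, :, i, j, l] += np.einsum(
                        'nfv,ncv->fc', g, xs, optimize=True)
                    dxs = (W[:, :, i, j, l].T @ g).reshape(
                        N, self.in_ch, oh, ow, od)
                    dxp[:, :, i:i + oh, j:j + ow, l:l + od] += dxs
        if self.padding == "same":
            (ph, _), (pw, _), (pd, _) = self._pads()
            dxp = dxp[:, :, ph:ph + x_shape[2], pw:pw + x_shape[3],
                      pd:pd + x_shape[4]]
        self._cache = None
        return np.ascontiguousarray(dxp)


# ---------------------------------------------------------------------------
# Batch normalization
# ---------------------------------------------------------------------------

class BatchNorm3d(Layer):
    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.n_ch = n_ch
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(n_ch, dtype=dtype))
        self.beta = Param(np.zeros(n_ch, dtype=dtype))
        self.running_mean = np.zeros(n_ch, dtype=dtype)
        self.running_var = np.ones(n_ch, dtype=dtype)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(x.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        shape = (1, -1, 1, 1, 1)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        if train:
            self._cache = (xhat, inv)
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        axes = (0, 2, 3, 4)
        m = grad.shape[0] * grad.shape[2] * grad.shape[3] * grad.shape[4]
        shape = (1, -1, 1, 1, 1)
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value.reshape(shape)
        dx = (inv.reshape(shape) / m) * (
            m * g
            - g.sum(axis=axes).reshape(shape)
            - xhat * (g * xhat).sum(axis=axes).reshape(shape))
        self._cache = None
        return dx


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        mask = x >= 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = np.where(self._mask, grad, self.slope * grad)
        self._mask = None
        return g


# ---------------------------------------------------------------------------
# Max pooling
# ---------------------------------------------------------------------------

class MaxPool3d(Layer):
    """2x2x2 max pool, stride 2; axes of size 1 pass through and odd sizes
    are floor-cropped (the trailing slice gets zero gradient)."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        ks = tuple(2 if s >= 2 else 1 for s in x.shape[2:])
        oh, ow, od = (x.shape[2] // ks[0], x.shape[3] // ks[1],
                      x.shape[4] // ks[2])
        xc = x[:, :, :oh * ks[0], :ow * ks[1], :od * ks[2]]
        xr = xc.reshape(x.shape[0], x.shape[1], oh, ks[0], ow, ks[1], od, ks[2])
        out = xr.max(axis=(3, 5, 7))
        if train:
            self._cache = (xr, out, x.shape, ks)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xr, out, x_shape, ks = self._cache
        expand = out[:, :, :, None, :, None, :, None]
        mask = (xr == expand)
        counts = mask.sum(axis=(3, 5, 7), keepdims=True)  # ties share gradient
        g = mask * (grad[:, :, :, None, :, None, :, None] / counts)
        N, C = x_shape[0], x_shape[1]
        oh, ow, od = out.shape[2:]
        dxc = g.reshape(N, C, oh * ks[0], ow * ks[1], od * ks[2])
        dx = np.zeros(x_shape, dtype=grad.dtype)
        dx[:, :, :oh * ks[0], :ow * ks[1], :od * ks[2]] = dxc
        self._cache = None
        return dx


# ---------------------------------------------------------------------------
# Squeeze-and-excitation
# ---------------------------------------------------------------------------

def se_squeeze(U: np.ndarray) -> np.ndarray:
    """Global average pooling: (.., F, H, W, D) -> (.., F)."""
    return U.mean(axis=(-3, -2, -1))


def se_excite(z: np.ndarray, reduce_weights: np.ndarray,
              expand_weights: np.ndarray) -> np.ndarray:
    """s = sigmoid(W_expand @ relu(W_reduce @ z)); channel gates in (0, 1)."""
    if reduce_weights.shape[1] != z.shape[-1]:
        raise DimensionError(
            f"reduce matrix expects {reduce_weights.shape[1]} channels, "
            f"got {z.shape[-1]}")
    if expand_weights.shape[1] != reduce_weights.shape[0]:
        raise DimensionError("expand/reduce bottleneck widths disagree")
    h = np.maximum(z @ reduce_weights.T, 0.0)
    return _sigmoid(h @ expand_weights.T)


def se_scale(U: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Multiply channel f of U by scalar s_f."""
    if s.shape[-1] != U.shape[-4]:
        raise DimensionError(
            f"gate length {s.shape[-1]} != channel count {U.shape[-4]}")
    return U * s[..., :, None, None, None]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class SEBlock(Layer):
    """Channel attention: squeeze (global average pool), excite (bottleneck
    of reduction ratio r with ReLU then sigmoid), rescale channels.

    ``force_identity`` bypasses the gates (s = 1), which must make the
    surrounding network identical to one without the block.
    """

    def __init__(self, n_ch: int, reduction: int = 16,
                 rng: np.random.Generator | None = None, dtype=np.float32,
                 force_identity: bool = False):
        self.n_ch = n_ch
        self.bottleneck = max(1, n_ch // reduction)
        rng = rng or np.random.default_rng(0)
        self.reduce = Param((rng.standard_normal((self.bottleneck, n_ch))
                             * np.sqrt(2.0 / n_ch)).astype(dtype), decay=False)
        self.expand = Param((rng.standard_normal((n_ch, self.bottleneck))
                             * np.sqrt(2.0 / self.bottleneck)).astype(dtype),
                            decay=False)
        self.force_identity = force_identity
        self._cache = None

    def params(self) -> list[Param]:
        return [self.reduce, self.expand]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if self.force_identity:
            return x
        z = se_squeeze(x)                                   # (N, F)
        h = np.maximum(z @ self.reduce.value.T, 0.0)        # (N, B)
        s = _sigmoid(h @ self.expand.value.T)               # (N, F)
        out = se_scale(x, s)
        if train:
            self._cache = (x, z, h, s)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.force_identity:
            return grad
        x, z, h, s = self._cache
        spatial = x.shape[2] * x.shape[3] * x.shape[4]
        dx = grad * s[:, :, None, None, None]
        ds = (grad * x).sum(axis=(2, 3, 4))                 # (N, F)
        dpre = ds * s * (1.0 - s)                           # sigmoid'
        self.expand.grad += dpre.T @ h
        dh = (dpre @ self.expand.value) * (h > 0)
        self.reduce.grad += dh.T @ z
        dz = dh @ self.reduce.value                         # (N, F)
        dx += dz[:, :, None, None, None] / spatial
        self._cache = None
        return dx


# ---------------------------------------------------------------------------
# Dropout / dense
# ---------------------------------------------------------------------------

class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        self._mask = mask
        return x * mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        g = grad * self._mask
        self._mask = None
        return g


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.weight = Param((rng.standard_normal((n_out, n_in))
                             * np.sqrt(2.0 / n_in)).astype(dtype), decay=True)
        self.bias = Param(np.zeros(n_out, dtype=dtype))
        self._x = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        dx = grad @ self.weight.value
        self._x = None
        return dx


# ---------------------------------------------------------------------------
# Network container
# ---------------------------------------------------------------------------

class Network:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def se_blocks(self) -> list[SEBlock]:
        return [l for l in self.layers if isinstance(l, SEBlock)]


# ---------------------------------------------------------------------------
# Loss and optimizer
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_with_logits(logits: np.ndarray, labels: np.ndarray,
                              ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(logits.dtype)


class Adam:
    def __init__(self, params: list[Param], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 l2_weight: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.l2_weight = l2_weight
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.l2_weight and p.decay:
                g = g + self.l2_weight * p.value
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if not np.all(np.isfinite(p.value)):
                raise TrainingError("non-finite parameter after optimizer step")
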