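"""Minimal CPU neural-network layers with explicit backprop.

Implements exactly the pieces the residual SSVEP classifier needs — 2-D
convolution (via im2col), batch normalization, ELU, dropout, a dense layer,
softmax cross-entropy and Adam with L2 weight decay — as plain numpy with
hand-written gradients.  Layer semantics (initialization, batch-norm
running statistics, Adam update, weight-decay-as-L2) follow the common
deep-learning-framework defaults so the training protocol transfers
unchanged.  Everything is deterministic given the seeding Generator, and
eval-mode forwards are bit-reproducible.

Gradient correctness is established by finite-difference checks in the test
suite rather than trusted by construction.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Module", "Conv2d", "BatchNorm2d", "ELU", "Dropout",
    "Linear", "Flatten", "Sequential", "Adam", "softmax",
    "cross_entropy_with_grad",
]


class Param:
    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = value
        self.grad = np.zeros_like(value)
        self.decay = decay  # whether L2 weight decay applies


class Module:
    def params(self) -> list:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _kaiming_uniform(rng, shape, fan_in):
    # fan-in-scaled uniform init (the torch conv/linear default, a=sqrt(5))
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def _im2col(xp, kh, kw, sh, sw, oh, ow):
    n, c = xp.shape[:2]
    s = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, (n, c, kh, kw, oh, ow),
        (s[0], s[1], s[2], s[3], s[2] * sh, s[3] * sw))
    return np.ascontiguousarray(cols).reshape(n, c * kh * kw, oh * ow)


class Conv2d(Module):
    """2-D convolution (cross-correlation) with stride and zero padding."""

    def __init__(self, c_in, c_out, kernel, stride=(1, 1), padding=(0, 0),
                 bias=True, rng=None):
        self.c_in, self.c_out = c_in, c_out
        self.kh, self.kw = kernel
        self.sh, self.sw = stride
        self.ph, self.pw = padding
        fan_in = c_in * self.kh * self.kw
        rng = rng or np.random.default_rng()
        self.weight = Param(_kaiming_uniform(rng, (c_out, c_in, self.kh, self.kw), fan_in))
        self.bias = Param(_kaiming_uniform(rng, (c_out,), fan_in), decay=False) if bias else None
        self._cache = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def out_shape(self, h, w):
        oh = (h + 2 * self.ph - self.kh) // self.sh + 1
        ow = (w + 2 * self.pw - self.kw) // self.sw + 1
        return oh, ow

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        oh, ow = self.out_shape(h, w)
        if oh < 1 or ow < 1:
            raise ValueError(f"input ({h},{w}) too small for kernel/stride")
        xp = np.pad(x, ((0, 0), (0, 0), (self.ph, self.ph), (self.pw, self.pw)))
        cols = _im2col(xp, self.kh, self.kw, self.sh, self.sw, oh, ow)
        wmat = self.weight.value.reshape(self.c_out, -1)
        y = np.matmul(wmat, cols).reshape(n, self.c_out, oh, ow)
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        self._cache = (cols, xp.shape, (oh, ow))
        return y

    def backward(self, dy):
        cols, xp_shape, (oh, ow) = self._cache
        n = dy.shape[0]
        dyf = dy.reshape(n, self.c_out, oh * ow)
        wmat = self.weight.value.reshape(self.c_out, -1)
        # dW[o,k] = sum_n dyf[n] @ cols[n].T, folded into one GEMM
        dyf_flat = np.ascontiguousarray(dyf.transpose(1, 0, 2)).reshape(self.c_out, -1)
        cols_flat = np.ascontiguousarray(cols.transpose(1, 0, 2)).reshape(cols.shape[1], -1)
        self.weight.grad += (dyf_flat @ cols_flat.T).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        dcols = np.matmul(wmat.T, dyf)  # (n, c*kh*kw, oh*ow)
        d = dcols.reshape(n, self.c_in, self.kh, self.kw, oh, ow)
        dxp = np.zeros(xp_shape)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, :, i:i + self.sh * oh:self.sh,
                    j:j + self.sw * ow:self.sw] += d[:, :, i, j]
        h, w = xp_shape[2] - 2 * self.ph, xp_shape[3] - 2 * self.pw
        return dxp[:, :, self.ph:self.ph + h, self.pw:self.pw + w]


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = Param(np.ones(c), decay=False)
        self.beta = Param(np.zeros(c), decay=False)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            axes = (0, 2, 3)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = x.shape[0] * x.shape[2] * x.shape[3]
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            # running variance uses the unbiased estimate, as frameworks do
            unbiased = var * m / max(m - 1, 1)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        y = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return y

    def backward(self, dy):
        xhat, inv, train, shape = self._cache
        g = self.gamma.value[None, :, None, None]
        axes = (0, 2, 3)
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        if not train:
            return dy * g * inv[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        dxhat = dy * g
        # standard batch-norm backward over the (batch, h, w) axes
        dx = (inv[None, :, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True)
        )
        return dx


class ELU(Module):
    def __init__(self, alpha=1.0):
        self.alpha = alpha
        self._cache = None

    def forward(self, x, train=True):
        y = np.where(x > 0, x, self.alpha * np.expm1(x))
        self._cache = (x, y)
        return y

    def backward(self, dy):
        x, y = self._cache
        return dy * np.where(x > 0, 1.0, y + self.alpha)


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate, rng):
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train=True):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Module):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Linear(Module):
    def __init__(self, n_in, n_out, rng=None):
        rng = rng or np.random.default_rng()
        self.weight = Param(_kaiming_uniform(rng, (n_out, n_in), n_in))
        self.bias = Param(_kaiming_uniform(rng, (n_out,), n_in), decay=False)
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy):
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


class Sequential(Module):
    def __init__(self, *modules):
        self.modules = list(modules)

    def params(self):
        return [p for m in self.modules for p in m.params()]

    def forward(self, x, train=True):
        for m in self.modules:
            x = m.forward(x, train)
        return x

    def backward(self, dy):
        for m in reversed(self.modules):
            dy = m.backward(dy)
        return dy


def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_with_grad(logits, labels):
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(n), labels] + eps))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Adam:
    """Adam with L2 weight decay added to the gradient (classic Adam+wd)."""

    def __init__(self, params, lr=8e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.value
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
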