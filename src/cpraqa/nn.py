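"""Minimal NumPy neural-network layers with hand-written backpropagation.

Tensors flow in ``(batch, time, joints, channels)`` layout.  Each layer
caches what its backward pass needs during ``forward`` and returns the
gradient with respect to its input from ``backward``; parameters accumulate
gradients in ``Param.grad``.  Everything is dtype-generic so the whole model
can be run in float64 for finite-difference gradient checking and float32
for training speed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Layer", "SpatialGraphConv", "TemporalConv", "BatchNorm", "InputNorm",
    "ReLU", "GlobalAvgPool", "Dense", "Adam", "fan_in_uniform",
]


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self):
        self.grad[...] = 0


def fan_in_uniform(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Layer:
    train_mode: bool = True

    def params(self) -> list[Param]:
        return []

    def set_mode(self, train: bool):
        self.train_mode = train


class SpatialGraphConv(Layer):
    """Per-frame graph convolution: out_t = A_hat @ X_t @ W.

    A_hat is the symmetric degree-normalised adjacency (fixed); W mixes
    channels.  Node mixing and channel mixing are both linear, so the
    backward pass is two transposed matmuls.
    """

    def __init__(self, a_hat: np.ndarray, c_in: int, c_out: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.a_hat = np.asarray(a_hat, dtype=dtype)
        self.w = Param(fan_in_uniform(rng, (c_in, c_out), c_in, dtype), "sgc.w")
        self._x = None

    def params(self):
        return [self.w]

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (B, T, N, C_in)
        self._x = x
        xw = x @ self.w.value                     # (B,T,N,C_out)
        return np.matmul(self.a_hat, xw)          # broadcast over (B,T)

    def backward(self, g: np.ndarray) -> np.ndarray:
        ag = np.matmul(self.a_hat.T, g)           # (B,T,N,C_out)
        x = self._x
        self.w.grad += np.tensordot(x, ag, axes=([0, 1, 2], [0, 1, 2]))
        return ag @ self.w.value.T


class TemporalConv(Layer):
    """Per-joint 1-D convolution along time with 'same' padding.

    Kernel size 9 by default (the standard skeleton-network choice); stride
    subsamples time.  Implemented as im2col + matmul.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.kernel = kernel
        self.stride = stride
        self.c_in = c_in
        self.c_out = c_out
        self.w = Param(fan_in_uniform(rng, (kernel * c_in, c_out), kernel * c_in, dtype),
                       "tconv.w")
        self.b = Param(np.zeros(c_out, dtype=dtype), "tconv.b")
        self._xp = None
        self._shape = None

    def params(self):
        return [self.w, self.b]

    def _pads(self, T: int) -> tuple[int, int]:
        t_out = -(-T // self.stride)  # ceil
        needed = max((t_out - 1) * self.stride + self.kernel - T, 0)
        return needed // 2, needed - needed // 2

    def _tap(self, k: int, t_out: int) -> slice:
        return slice(k, k + self.stride * (t_out - 1) + 1, self.stride)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, N, C = x.shape
        if T == 0:
            raise ValueError("empty time axis")
        p0, p1 = self._pads(T)
        xp = np.pad(x, ((0, 0), (p0, p1), (0, 0), (0, 0)))
        t_out = -(-T // self.stride)
        # one GEMM per kernel tap: out += X[:, k::stride] @ W_k
        out = np.broadcast_to(self.b.value, (B, t_out, N, self.c_out)).copy()
        flat = out.reshape(-1, self.c_out)
        for k in range(self.kernel):
            seg = xp[:, self._tap(k, t_out)].reshape(-1, C)
            flat += seg @ self.w.value[k * C:(k + 1) * C]
        self._xp = xp
        self._shape = (B, T, N, C, p0, p1, t_out)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        B, T, N, C, p0, p1, t_out = self._shape
        self.b.grad += g.sum(axis=(0, 1, 2))
        gm = g.reshape(-1, self.c_out)
        gxp = np.zeros_like(self._xp)
        for k in range(self.kernel):
            tap = self._tap(k, t_out)
            seg = self._xp[:, tap].reshape(-1, C)
            self.w.grad[k * C:(k + 1) * C] += seg.T @ gm
            gxp[:, tap] += (gm @ self.w.value[k * C:(k + 1) * C].T).reshape(
                B, t_out, N, C)
        return gxp[:, p0:T + p0]


class BatchNorm(Layer):
    """Per-channel normalisation over (batch, time, joints) with affine
    scale/shift and running statistics for inference."""

    def __init__(self, c: int, dtype=np.float32, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(c, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(c, dtype=dtype), "bn.beta")
        self.eps = eps
        self.momentum = momentum
        self.run_mean = np.zeros(c, dtype=dtype)
        self.run_var = np.ones(c, dtype=dtype)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.train_mode:
            axes = (0, 1, 2)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.run_mean = (1 - m) * self.run_mean + m * mean
            self.run_var = (1 - m) * self.run_var + m * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, x.shape)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        self.gamma.grad += (g * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += g.sum(axis=(0, 1, 2))
        gxhat = g * self.gamma.value
        if not self.train_mode:
            return gxhat * inv
        m = shape[0] * shape[1] * shape[2]
        term = gxhat - gxhat.mean(axis=(0, 1, 2)) \
            - xhat * (gxhat * xhat).sum(axis=(0, 1, 2)) / m
        return term * inv


class InputNorm(Layer):
    """Per-(joint, channel) normalisation of the raw pose input over
    (batch, time), with affine parameters and running statistics.

    Joint positions mix large static offsets (body geometry) with small
    task-relevant excursions (centimeter-scale compressions); whitening
    each joint-channel brings the discriminative variance to unit scale
    before the first convolution, as in standard skeleton-network stacks.
    """

    def __init__(self, n_joints: int, c: int, dtype=np.float32,
                 eps: float = 1e-5, momentum: float = 0.1):
        shape = (n_joints, c)
        self.gamma = Param(np.ones(shape, dtype=dtype), "inorm.gamma")
        self.beta = Param(np.zeros(shape, dtype=dtype), "inorm.beta")
        self.eps = eps
        self.momentum = momentum
        self.run_mean = np.zeros(shape, dtype=dtype)
        self.run_var = np.ones(shape, dtype=dtype)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.train_mode:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            m = self.momentum
            self.run_mean = (1 - m) * self.run_mean + m * mean
            self.run_var = (1 - m) * self.run_var + m * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, x.shape)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        self.gamma.grad += (g * xhat).sum(axis=(0, 1))
        self.beta.grad += g.sum(axis=(0, 1))
        gxhat = g * self.gamma.value
        if not self.train_mode:
            return gxhat * inv
        m = shape[0] * shape[1]
        term = gxhat - gxhat.mean(axis=(0, 1)) \
            - xhat * (gxhat * xhat).sum(axis=(0, 1)) / m
        return term * inv


class ReLU(Layer):
    def forward(self, x):
        self._pos = x > 0
        return x * self._pos

    def backward(self, g):
        return g * self._pos


class GlobalAvgPool(Layer):
    """Average over time and joints: (B, T, N, C) -> (B, C)."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, g):
        B, T, N, C = self._shape
        return np.broadcast_to(g[:, None, None, :] / (T * N), self._shape).astype(g.dtype)


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        self.w = Param(fan_in_uniform(rng, (c_in, c_out), c_in, dtype), "dense.w")
        self.b = Param(np.zeros(c_out, dtype=dtype), "dense.b")

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, g):
        self.w.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.w.value.T


class Adam:
    """Adam with decoupled weight decay (applied directly to the weights,
    outside the moment estimates)."""

    def __init__(self, params: list[Param], lr: float = 0.01, weight_decay: float = 0.1,
                 betas=(0.9, 0.999), eps: float = 1e-8, lr_decay_tau: float | None = None):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.lr_decay_tau = lr_decay_tau
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        self.t += 1
        lr = self.lr
        if self.lr_decay_tau:
            lr = lr / (1.0 + self.t / self.lr_decay_tau)
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.value)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
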