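"""Minimal trainable 3D conv-net engine (numpy/BLAS, manual backprop).

Layers operate on channels-last batches of shape ``(N, rows, cols, slices, C)``
in float32. Each layer caches what its backward pass needs during ``forward``
and accumulates parameter gradients into ``Param.grad`` during ``backward``,
so two losses back-propagated in sequence sum their gradients — the behaviour
the shared-encoder training scheme relies on.

Convolutions are evaluated as im2col matrix products so the heavy lifting is
a single BLAS GEMM per layer; the column matrix is rebuilt in the backward
pass instead of cached, trading a memory copy for a much smaller peak
footprint.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    """A trainable tensor with an accumulated gradient buffer."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    """Base class: stateless unless it owns Params or a forward cache."""

    training = True

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _pad_spatial(x: np.ndarray) -> np.ndarray:
    return np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))


# The 27 kernel taps of a 3x3x3 convolution, centre tap last-varying.
_OFFSETS = [(dr, dc, ds) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
            for ds in (-1, 0, 1)]

# Below this flattened-volume size the 27 per-tap GEMMs are dominated by
# call overhead and a single im2col GEMM is faster (threshold measured on
# one CPU core across the layer shapes this package trains).
_IM2COL_MAX = 2000


class Conv3d(Layer):
    """3x3x3 same-padded convolution.

    Evaluated as 27 shift-and-matmul accumulations over the *flattened*
    zero-padded batch: for each kernel tap, the shifted operand is a
    contiguous slice of the padded array, so every GEMM runs on contiguous
    memory with no gather/scatter.  Tap shifts that cross row/volume
    boundaries only ever touch output positions inside the padding margin,
    which the final crop discards, so the result is an exact same-padded
    convolution.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        # He (fan-in) initialisation: std = sqrt(2 / fan_in)
        fan_in = 27 * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(27, c_in, c_out))
        self.w = Param(w)
        self.b = Param(np.zeros(c_out))
        self.c_in = c_in
        self.c_out = c_out
        self.need_input_grad = True  # the net's first conv turns this off
        self._xp: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    @staticmethod
    def _tap_offset(dr, dc, ds, cp, sp):
        return (dr * cp * sp + dc * sp + ds)

    def _im2col(self, xp):
        n, rp, cp, sp, ci = xp.shape
        r, c, s = rp - 2, cp - 2, sp - 2
        nv = n * r * c * s
        cols = np.empty((nv, 27 * ci), dtype=xp.dtype)
        for k, (dr, dc, ds) in enumerate(_OFFSETS):
            block = xp[:, 1 + dr:1 + dr + r, 1 + dc:1 + dc + c,
                       1 + ds:1 + ds + s, :]
            cols[:, k * ci:(k + 1) * ci] = block.reshape(nv, ci)
        return cols

    def forward(self, x):
        n, r, c, s, ci = x.shape
        if ci != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {ci}")
        xp = _pad_spatial(np.ascontiguousarray(x, dtype=F32))
        _, rp, cp, sp, _ = xp.shape
        m = n * rp * cp * sp
        self._xp = xp if self.training else None
        w = self.w.value
        if n * r * c * s <= _IM2COL_MAX:
            cols = self._im2col(xp)
            y = cols @ w.reshape(27 * ci, self.c_out)
            y += self.b.value
            return np.ascontiguousarray(y.reshape(n, r, c, s, self.c_out))
        xf = xp.reshape(m, ci)
        yf = np.zeros((m, self.c_out), dtype=F32)
        for k, (dr, dc, ds) in enumerate(_OFFSETS):
            o = self._tap_offset(dr, dc, ds, cp, sp)
            a, b = max(0, -o), m - max(0, o)
            yf[a:b] += xf[a + o:b + o] @ w[k]
        yf += self.b.value
        return np.ascontiguousarray(
            yf.reshape(n, rp, cp, sp, self.c_out)[:, 1:-1, 1:-1, 1:-1, :])

    def backward(self, dy):
        xp = self._xp
        n, rp, cp, sp, ci = xp.shape
        r, c, s = rp - 2, cp - 2, sp - 2
        m = n * rp * cp * sp
        nv = n * r * c * s
        self.b.grad += dy.reshape(-1, self.c_out).sum(axis=0)
        w = self.w.value
        dw = self.w.grad
        if nv <= _IM2COL_MAX:
            cols = self._im2col(xp)
            dy2 = dy.reshape(nv, self.c_out)
            dw += (cols.T @ dy2).reshape(27, ci, self.c_out)
            self._xp = None
            if not self.need_input_grad:
                return None
            dcols = dy2 @ w.reshape(27 * ci, self.c_out).T
            dxp = np.zeros_like(xp)
            for k, (dr, dc, ds) in enumerate(_OFFSETS):
                dxp[:, 1 + dr:1 + dr + r, 1 + dc:1 + dc + c,
                    1 + ds:1 + ds + s, :] += dcols[
                        :, k * ci:(k + 1) * ci].reshape(n, r, c, s, ci)
            return np.ascontiguousarray(dxp[:, 1:-1, 1:-1, 1:-1, :])
        xf = xp.reshape(m, ci)
        dyp = np.zeros((n, rp, cp, sp, self.c_out), dtype=F32)
        dyp[:, 1:-1, 1:-1, 1:-1, :] = dy
        dyf = dyp.reshape(m, self.c_out)
        dxf = np.zeros((m, ci), dtype=F32) if self.need_input_grad else None
        for k, (dr, dc, ds) in enumerate(_OFFSETS):
            o = self._tap_offset(dr, dc, ds, cp, sp)
            a, b = max(0, -o), m - max(0, o)
            dw[k] += xf[a + o:b + o].T @ dyf[a:b]
            if dxf is not None:
                dxf[a + o:b + o] += dyf[a:b] @ w[k].T
        self._xp = None
        if dxf is None:
            return None
        return np.ascontiguousarray(
            dxf.reshape(n, rp, cp, sp, ci)[:, 1:-1, 1:-1, 1:-1, :])


class ReLU(Layer):
    def forward(self, x):
        y = np.maximum(x, 0.0)
        if self.training:
            self._mask = x > 0
        return y

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalisation with explicitly calibrated
    inference statistics.

    Training (and validation) normalise with the current batch statistics
    over batch and spatial axes.  Inference statistics are *not* tracked by
    an exponential running average — with only a few hundred updates per run
    that average reflects the last handful of batches and makes eval-mode
    outputs depend on the recent batch composition.  Instead, after training
    the model runs one frozen-weight calibration pass over its own training
    streams (``begin_calibration``/``end_calibration``): the population
    statistics are the plain average of batch statistics over that pass.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.pop_mean = np.zeros(channels, dtype=F32)
        self.pop_var = np.ones(channels, dtype=F32)
        self.eps = eps
        self._calibrating = False
        self._acc = None

    def params(self):
        return [self.gamma, self.beta]

    def begin_calibration(self):
        self._calibrating = True
        self._acc = [np.zeros_like(self.pop_mean, dtype=np.float64),
                     np.zeros_like(self.pop_var, dtype=np.float64), 0]

    def end_calibration(self):
        s_mean, s_var, n = self._acc
        if n > 0:
            self.pop_mean = (s_mean / n).astype(F32)
            self.pop_var = (s_var / n).astype(F32)
        self._calibrating = False
        self._acc = None

    def forward(self, x):
        ax = (0, 1, 2, 3)
        if self.training:
            mean = x.mean(axis=ax)
            var = x.var(axis=ax)
            if self._calibrating:
                self._acc[0] += mean
                self._acc[1] += var
                self._acc[2] += 1
        else:
            mean, var = self.pop_mean, self.pop_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if self.training:
            self._xhat = xhat.astype(F32)
            self._inv = inv.astype(F32)
        return (self.gamma.value * xhat + self.beta.value).astype(F32)

    def backward(self, dy):
        ax = (0, 1, 2, 3)
        m = dy.shape[0] * dy.shape[1] * dy.shape[2] * dy.shape[3]
        xhat, inv = self._xhat, self._inv
        self.gamma.grad += (dy * xhat).sum(axis=ax)
        self.beta.grad += dy.sum(axis=ax)
        g = self.gamma.value
        dxhat = dy * g
        dx = (inv / m) * (m * dxhat - dxhat.sum(axis=ax)
                          - xhat * (dxhat * xhat).sum(axis=ax))
        self._xhat = self._inv = None
        return dx.astype(F32)


class MaxPool221(Layer):
    """Max pooling with window and stride 2x2x1 (slices untouched)."""

    def forward(self, x):
        n, r, c, s, ch = x.shape
        if r % 2 or c % 2:
            raise ValueError("in-plane dims must be even for 2x2x1 pooling")
        xr = x.reshape(n, r // 2, 2, c // 2, 2, s, ch)
        xw = xr.transpose(0, 1, 3, 5, 6, 2, 4).reshape(
            n, r // 2, c // 2, s, ch, 4)
        idx = xw.argmax(axis=-1)
        y = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
        if self.training:
            self._idx = idx
            self._inshape = x.shape
        return np.ascontiguousarray(y)

    def backward(self, dy):
        n, r, c, s, ch = self._inshape
        dxw = np.zeros((n, r // 2, c // 2, s, ch, 4), dtype=F32)
        np.put_along_axis(dxw, self._idx[..., None], dy[..., None], axis=-1)
        dx = dxw.reshape(n, r // 2, c // 2, s, ch, 2, 2).transpose(
            0, 1, 5, 2, 6, 3, 4).reshape(n, r, c, s, ch)
        self._idx = None
        return np.ascontiguousarray(dx)


class Upsample221(Layer):
    """Nearest-neighbour 2x2x1 upsampling."""

    def forward(self, x):
        self._inshape = x.shape
        return np.ascontiguousarray(np.repeat(np.repeat(x, 2, axis=1), 2, axis=2))

    def backward(self, dy):
        n, r, c, s, ch = self._inshape
        dyr = dy.reshape(n, r, 2, c, 2, s, ch)
        return np.ascontiguousarray(dyr.sum(axis=(2, 4)), dtype=F32)


class ChannelSoftmax(Layer):
    """Softmax over the channel axis, applied per voxel."""

    def forward(self, x):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        if self.training:
            self._p = p.astype(F32)
        return p.astype(F32)

    def backward(self, dy):
        p = self._p
        dx = p * (dy - (dy * p).sum(axis=-1, keepdims=True))
        self._p = None
        return dx.astype(F32)


class InstanceNorm(Layer):
    """Per-sample, per-channel normalisation over the spatial axes.

    Used in the pretext head: classification of a single volume must not
    depend on batch composition or on externally estimated statistics, so
    each sample is normalised by its own spatial moments.  Train and eval
    behave identically.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        ax = (1, 2, 3)
        mean = x.mean(axis=ax, keepdims=True)
        var = x.var(axis=ax, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if self.training:
            self._xhat = xhat.astype(F32)
            self._inv = inv.astype(F32)
        return (self.gamma.value * xhat + self.beta.value).astype(F32)

    def backward(self, dy):
        ax = (1, 2, 3)
        m = dy.shape[1] * dy.shape[2] * dy.shape[3]
        xhat, inv = self._xhat, self._inv
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 1, 2, 3))
        g = self.gamma.value
        dxhat = dy * g
        dx = (inv / m) * (m * dxhat - dxhat.sum(axis=ax, keepdims=True)
                          - xhat * (dxhat * xhat).sum(axis=ax, keepdims=True))
        self._xhat = self._inv = None
        return dx.astype(F32)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy


def set_training(root: Layer, flag: bool) -> None:
    """Recursively switch train/eval mode on a layer tree."""
    stack = [root]
    while stack:
        lay = stack.pop()
        lay.training = flag
        for attr in vars(lay).values():
            if isinstance(attr, Layer):
                stack.append(attr)
            elif isinstance(attr, (list, tuple)):
                stack.extend(a for a in attr if isinstance(a, Layer))


class Adam:
    """Adam optimiser over a fixed parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
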