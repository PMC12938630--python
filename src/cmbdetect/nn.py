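"""Minimal seeded numpy/numba layer library for the two 3D architectures.

Implements exactly the primitives the detector needs — 3D convolution
(kernel 1 or 3, "same" padding), batch normalization, 2x2x2 max pooling,
stride-2 kernel-2 transposed convolution, dense layers, weighted
binary-cross-entropy with logits, and Adam — with hand-derived backward
passes.

Internally all spatial tensors are batch-last, ``(C, X, Y, Z, N)``
float32, so the innermost (contiguous) axis is the window batch: the
numba convolution kernels vectorize over it, and the public ``(N, X, Y,
Z, C)`` interface converts once per forward/backward pass. When numba is
unavailable an equivalent pure-numpy convolution path is used.

Everything is deterministic: parameter initialization is driven by a
numpy Generator and the kernels are single-threaded, so identical seeds
give bit-identical training runs.
"""

from __future__ import annotations

import numpy as np

try:  # numba accelerates the conv kernels; the numpy path is equivalent
    from numba import njit

    _USE_NUMBA = True
except ImportError:  # pragma: no cover
    _USE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco


@njit(cache=True, fastmath=True)
def _conv3d_fwd(xp, W, b, out):
    # xp (cin, X+2, Y+2, Z+2, N); W (3,3,3,cin,cout); out (cout, X, Y, Z, N)
    cin, Xp, Yp, Zp, N = xp.shape
    cout = W.shape[4]
    X, Y, Z = Xp - 2, Yp - 2, Zp - 2
    for x in range(X):
        for y in range(Y):
            for co in range(cout):
                for z in range(Z):
                    for n in range(N):
                        out[co, x, y, z, n] = b[co]
                    for ci in range(cin):
                        for dx in range(3):
                            for dy in range(3):
                                for dz in range(3):
                                    w = W[dx, dy, dz, ci, co]
                                    for n in range(N):
                                        out[co, x, y, z, n] += (
                                            w * xp[ci, x + dx, y + dy, z + dz, n]
                                        )


@njit(cache=True, fastmath=True)
def _conv3d_bwd_dx(dy, W, dxp):
    # dy (cout, X, Y, Z, N); dxp zeros (cin, X+2, Y+2, Z+2, N)
    cout, X, Y, Z, N = dy.shape
    cin = W.shape[3]
    for x in range(X):
        for y in range(Y):
            for ci in range(cin):
                for co in range(cout):
                    for dx in range(3):
                        for dy_ in range(3):
                            for dz in range(3):
                                w = W[dx, dy_, dz, ci, co]
                                for z in range(Z):
                                    for n in range(N):
                                        dxp[ci, x + dx, y + dy_, z + dz, n] += (
                                            w * dy[co, x, y, z, n]
                                        )


@njit(cache=True, fastmath=True)
def _conv3d_bwd_dw(xp, dy, dW):
    # accumulates into dW (3,3,3,cin,cout)
    cout, X, Y, Z, N = dy.shape
    cin = xp.shape[0]
    for x in range(X):
        for y in range(Y):
            for co in range(cout):
                for ci in range(cin):
                    for dx in range(3):
                        for dy_ in range(3):
                            for dz in range(3):
                                acc = 0.0
                                for z in range(Z):
                                    for n in range(N):
                                        acc += (
                                            xp[ci, x + dx, y + dy_, z + dz, n]
                                            * dy[co, x, y, z, n]
                                        )
                                dW[dx, dy_, dz, ci, co] += acc


__all__ = [
    "Conv3d",
    "BatchNorm",
    "ReLU",
    "MaxPool3d",
    "ConvTranspose3d",
    "Dense",
    "Adam",
    "sigmoid",
    "bce_with_logits",
    "UNet3D",
    "CNN3D",
]

F = np.float32


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(
    z: np.ndarray, y: np.ndarray, pos_weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Mean weighted binary cross-entropy and its gradient w.r.t. logits."""
    z = z.astype(np.float64)
    y = y.astype(np.float64)
    w = np.where(y > 0.5, pos_weight, 1.0)
    # numerically stable: max(z,0) - z*y + log(1+exp(-|z|))
    loss_el = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    n = z.size
    loss = float((w * loss_el).sum() / n)
    grad = (w * (sigmoid(z) - y) / n).astype(F)
    return loss, grad


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


def _pad1(x: np.ndarray) -> np.ndarray:
    c, X, Y, Z, n = x.shape
    xp = np.zeros((c, X + 2, Y + 2, Z + 2, n), dtype=F)
    xp[:, 1:-1, 1:-1, 1:-1, :] = x
    return xp


class Conv3d(Layer):
    """3D convolution, kernel size 1 or 3, stride 1, 'same' padding.

    Operates on batch-last tensors ``(cin, X, Y, Z, N)``.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, ksize: int = 3):
        if ksize not in (1, 3):
            raise ValueError("ksize must be 1 or 3")
        self.k = ksize
        fan_in = cin * ksize**3
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        self.W = rng.normal(0, std, size=(ksize, ksize, ksize, cin, cout)).astype(F)
        self.b = np.zeros(cout, dtype=F)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if self.k == 1:
            if train:
                self._x = x
            return np.tensordot(self.W[0, 0, 0], x, axes=([0], [0])) + self.b.reshape(
                -1, 1, 1, 1, 1
            )
        cin, X, Y, Z, N = x.shape
        xp = _pad1(x)
        if train:
            self._xp, self._shape = xp, x.shape
        if _USE_NUMBA:
            out = np.empty((self.W.shape[-1], X, Y, Z, N), dtype=F)
            _conv3d_fwd(xp, self.W, self.b, out)
            return out
        out = np.zeros((self.W.shape[-1], X, Y, Z, N), dtype=F)
        out += self.b.reshape(-1, 1, 1, 1, 1)
        for dx in range(3):
            for dy in range(3):
                for dz in range(3):
                    out += np.tensordot(
                        self.W[dx, dy, dz],
                        xp[:, dx : dx + X, dy : dy + Y, dz : dz + Z, :],
                        axes=([0], [0]),
                    )
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.k == 1:
            self.dW[0, 0, 0] = np.tensordot(
                self._x, dy, axes=([1, 2, 3, 4], [1, 2, 3, 4])
            )
            self.db[...] = dy.sum(axis=(1, 2, 3, 4))
            return np.tensordot(self.W[0, 0, 0], dy, axes=([1], [0]))
        xp, (cin, X, Y, Z, N) = self._xp, self._shape
        if _USE_NUMBA:
            self.dW[...] = 0
            _conv3d_bwd_dw(xp, dy, self.dW)
            dxp = np.zeros_like(xp)
            _conv3d_bwd_dx(dy, self.W, dxp)
        else:
            dxp = np.zeros_like(xp)
            for dx in range(3):
                for dy_ in range(3):
                    for dz in range(3):
                        sl = (
                            slice(None),
                            slice(dx, dx + X),
                            slice(dy_, dy_ + Y),
                            slice(dz, dz + Z),
                        )
                        self.dW[dx, dy_, dz] = np.tensordot(
                            xp[sl], dy, axes=([1, 2, 3, 4], [1, 2, 3, 4])
                        )
                        dxp[sl] += np.tensordot(
                            self.W[dx, dy_, dz], dy, axes=([1], [0])
                        )
        self.db[...] = dy.sum(axis=(1, 2, 3, 4))
        self._xp = None
        return dxp[:, 1:-1, 1:-1, 1:-1, :]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class BatchNorm(Layer):
    """Per-channel batch normalization over (X, Y, Z, N)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=F)
        self.beta = np.zeros(c, dtype=F)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    @staticmethod
    def _bc(v: np.ndarray) -> np.ndarray:
        return v.reshape(-1, 1, 1, 1, 1)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (1, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes, dtype=np.float64)
            var = x.var(axis=axes, dtype=np.float64)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            inv = (1.0 / np.sqrt(var + self.eps)).astype(F)
            xhat = ((x - self._bc(mean.astype(F))) * self._bc(inv)).astype(F)
            self._xhat, self._inv = xhat, inv
            return xhat * self._bc(self.gamma) + self._bc(self.beta)
        # eval: a single fused affine map per channel
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = (self.gamma * inv).astype(F)
        shift = (self.beta - self.gamma * self.running_mean * inv).astype(F)
        return x * self._bc(scale) + self._bc(shift)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = (1, 2, 3, 4)
        xhat, inv = self._xhat, self._inv
        self.dgamma[...] = (dy * xhat).sum(axis=axes)
        self.dbeta[...] = dy.sum(axis=axes)
        dxhat = dy * self._bc(self.gamma)
        dx = (
            dxhat
            - self._bc(dxhat.mean(axis=axes, dtype=np.float64).astype(F))
            - xhat * self._bc((dxhat * xhat).mean(axis=axes, dtype=np.float64).astype(F))
        ) * self._bc(inv)
        return dx.astype(F)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
            return np.where(self._mask, x, 0)
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0)


class MaxPool3d(Layer):
    """Non-overlapping 2x2x2 max pooling; spatial dims must divide evenly."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        C, X, Y, Z, N = x.shape
        r = x.reshape(C, X // 2, 2, Y // 2, 2, Z // 2, 2, N)
        out = r.max(axis=(2, 4, 6))
        if train:
            mask = r == out[:, :, None, :, None, :, None, :]
            # split gradient equally among ties for determinism
            self._mask = mask / mask.sum(axis=(2, 4, 6), keepdims=True)
            self._shape = x.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        g = self._mask * dy[:, :, None, :, None, :, None, :]
        return g.reshape(self._shape).astype(F)


class ConvTranspose3d(Layer):
    """Kernel-2 stride-2 learned upsampling (offsets do not overlap)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / cin)
        self.W = rng.normal(0, std, size=(2, 2, 2, cin, cout)).astype(F)
        self.b = np.zeros(cout, dtype=F)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        cin, X, Y, Z, N = x.shape
        cout = self.W.shape[-1]
        out = np.empty((cout, 2 * X, 2 * Y, 2 * Z, N), dtype=F)
        bb = self.b.reshape(-1, 1, 1, 1, 1)
        for dx in range(2):
            for dy in range(2):
                for dz in range(2):
                    out[:, dx::2, dy::2, dz::2, :] = (
                        np.tensordot(self.W[dx, dy, dz], x, axes=([0], [0])) + bb
                    )
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        dx = np.zeros_like(x)
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    block = dy[:, i::2, j::2, k::2, :]
                    self.dW[i, j, k] = np.tensordot(
                        x, block, axes=([1, 2, 3, 4], [1, 2, 3, 4])
                    )
                    dx += np.tensordot(self.W[i, j, k], block, axes=([1], [0]))
        self.db[...] = dy.sum(axis=(1, 2, 3, 4))
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Dense(Layer):
    """Fully connected layer on (N, features) tensors."""

    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / nin)
        self.W = rng.normal(0, std, size=(nin, nout)).astype(F)
        self.b = np.zeros(nout, dtype=F)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g.astype(np.float64) ** 2
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)


def _conv_block(cin: int, cout: int, rng: np.random.Generator) -> list[Layer]:
    return [Conv3d(cin, cout, rng), BatchNorm(cout), ReLU()]


def _run(blocks: list[Layer], x: np.ndarray, train: bool) -> np.ndarray:
    for layer in blocks:
        x = layer.forward(x, train)
    return x


def _back(blocks: list[Layer], dy: np.ndarray) -> np.ndarray:
    for layer in reversed(blocks):
        dy = layer.backward(dy)
    return dy


def _to_batch_last(x: np.ndarray) -> np.ndarray:
    # (N, X, Y, Z, C) -> (C, X, Y, Z, N)
    return np.ascontiguousarray(x.transpose(4, 1, 2, 3, 0))


def _to_batch_first(x: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(x.transpose(4, 1, 2, 3, 0))


class UNet3D:
    """Depth-3 3D U-Net with batch norm: two pooling stages, skip
    connections by channel concatenation, transposed-convolution
    upsampling, and a 1x1x1 logit head (sigmoid applied by the caller).

    Input and output share the window shape; each spatial axis must be
    divisible by 4 (two 2x pools). Public tensors are ``(N, X, Y, Z, 1)``.
    """

    def __init__(self, base_filters: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        f = base_filters
        self.enc1 = _conv_block(1, f, rng) + _conv_block(f, f, rng)
        self.pool1 = MaxPool3d()
        self.enc2 = _conv_block(f, 2 * f, rng) + _conv_block(2 * f, 2 * f, rng)
        self.pool2 = MaxPool3d()
        self.bott = _conv_block(2 * f, 4 * f, rng) + _conv_block(4 * f, 4 * f, rng)
        self.up2 = ConvTranspose3d(4 * f, 2 * f, rng)
        self.dec2 = _conv_block(4 * f, 2 * f, rng) + _conv_block(2 * f, 2 * f, rng)
        self.up1 = ConvTranspose3d(2 * f, f, rng)
        self.dec1 = _conv_block(2 * f, f, rng) + _conv_block(f, f, rng)
        self.head = Conv3d(f, 1, rng, ksize=1)
        self._blocks = (
            self.enc1
            + [self.pool1]
            + self.enc2
            + [self.pool2]
            + self.bott
            + [self.up2]
            + self.dec2
            + [self.up1]
            + self.dec1
            + [self.head]
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if any(s % 4 for s in x.shape[1:4]):
            raise ValueError(f"spatial dims {x.shape[1:4]} must be divisible by 4")
        h = _to_batch_last(x.astype(F))
        e1 = _run(self.enc1, h, train)
        e2 = _run(self.enc2, self.pool1.forward(e1, train), train)
        b = _run(self.bott, self.pool2.forward(e2, train), train)
        u2 = self.up2.forward(b, train)
        d2 = _run(self.dec2, np.concatenate([u2, e2], axis=0), train)
        u1 = self.up1.forward(d2, train)
        d1 = _run(self.dec1, np.concatenate([u1, e1], axis=0), train)
        self._c2, self._c1 = u2.shape[0], u1.shape[0]
        return _to_batch_first(self.head.forward(d1, train))

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(_to_batch_last(dlogits))
        d = _back(self.dec1, d)
        du1, de1 = d[: self._c1], d[self._c1 :]
        d = self.up1.backward(du1)
        d = _back(self.dec2, d)
        du2, de2 = d[: self._c2], d[self._c2 :]
        d = self.up2.backward(du2)
        d = _back(self.bott, d)
        d = self.pool2.backward(d) + de2
        d = _back(self.enc2, d)
        d = self.pool1.backward(d) + de1
        _back(self.enc1, d)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward(x, train=False))

    def params(self) -> list[np.ndarray]:
        return [p for l in self._blocks for p in l.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for l in self._blocks for g in l.grads()]


class CNN3D:
    """Patch classifier: conv-BN stacks, one max-pooling stage, flatten,
    two dense layers, scalar logit for "CMB at the window center".

    With ``base_filters=32`` this is the conv(32)-conv(64)-pool-conv(64)-
    dense(128)-dense(1) stack; smaller bases shrink every width
    proportionally. Public input is ``(N, X, Y, Z, 1)``, output ``(N,)``.
    """

    def __init__(
        self,
        base_filters: int = 32,
        seed: int = 0,
        window: tuple[int, int, int] = (20, 20, 16),
    ):
        rng = np.random.default_rng(seed)
        c = base_filters
        self.features = (
            _conv_block(1, c, rng)
            + _conv_block(c, 2 * c, rng)
            + [MaxPool3d()]
            + _conv_block(2 * c, 2 * c, rng)
        )
        flat = 2 * c * (window[0] // 2) * (window[1] // 2) * (window[2] // 2)
        self.fc1 = Dense(flat, 4 * c, rng)
        self.fc_relu = ReLU()
        self.fc2 = Dense(4 * c, 1, rng)
        self._blocks = self.features + [self.fc1, self.fc_relu, self.fc2]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = _run(self.features, _to_batch_last(x.astype(F)), train)
        self._fshape = h.shape
        n = h.shape[-1]
        h = np.ascontiguousarray(h.transpose(4, 0, 1, 2, 3)).reshape(n, -1)
        h = self.fc_relu.forward(self.fc1.forward(h, train), train)
        return self.fc2.forward(h, train)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc2.backward(dlogits[:, None].astype(F))
        d = self.fc1.backward(self.fc_relu.backward(d))
        c, X, Y, Z, n = self._fshape
        d = np.ascontiguousarray(d.reshape(n, c, X, Y, Z).transpose(1, 2, 3, 4, 0))
        _back(self.features, d)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward(x, train=False))

    def params(self) -> list[np.ndarray]:
        return [p for l in self._blocks for p in l.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for l in self._blocks for g in l.grads()]
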