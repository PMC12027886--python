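"""Minimal NumPy neural-network engine for the shallow grading CNN.

Implements exactly the layer types the grading network needs — valid 2-D
convolution (im2col + BLAS matmul), batch normalization, ReLU, 2x2 max
pooling, inverted dropout, dense layers — plus softmax cross-entropy loss
and the Adam optimizer.  Everything runs in float32; layouts are NHWC.

Each layer exposes ``forward(x, train)`` and ``backward(grad)`` and lists
its parameters and gradients; :class:`Adam` updates the flat parameter list
in place.  Dropout draws its masks from a generator shared across the whole
network so that training is reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Valid convolution, stride 1, He-initialized, NHWC.

    Implemented as a single large GEMM per pass: the kernel is scattered
    into a width-banded weight matrix ``B`` of shape
    ``(k * W * C, OW * F)`` and the input is gathered into row-shifted
    blocks ``(N * OH, k * W * C)``.  The banding wastes a factor ~W/k of
    multiplies on structural zeros but keeps every operation one
    well-shaped BLAS call, which is far faster here than patch-wise im2col.

    ``needs_input_grad=False`` (set on the first layer of a network) skips
    the input-gradient GEMM and scatter entirely.
    """

    kind = "conv"

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.k, self.in_ch, self.out_ch = k, in_ch, out_ch
        fan_in = k * k * in_ch
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (k, k, in_ch, out_ch))
        self.W = w.astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.needs_input_grad = True
        self._plan_for_w: int | None = None

    def _plan(self, w: int) -> None:
        """Pick a width-tile size and build the band scatter indices.

        The banded K dimension is ``k * (cw + k - 1) * C`` per tile, so the
        wasted multiplies shrink with the tile width ``cw``; the GEMM's N
        dimension is ``cw * F``, which must stay wide enough for BLAS to
        run near peak.  ``cw`` is the smallest divisor of OW with
        ``cw * F >= 32`` (falling back to OW itself).
        """
        k, c_in, f = self.k, self.in_ch, self.out_ch
        ow = w - k + 1
        divisors = [d for d in range(1, ow + 1) if ow % d == 0]
        cands = [d for d in divisors if d * f >= 32]
        cw = min(cands) if cands else ow
        in_w = cw + k - 1
        i, dj, j, c, ff = np.meshgrid(
            np.arange(k), np.arange(k), np.arange(cw), np.arange(c_in),
            np.arange(f), indexing="ij",
        )
        row = i * (in_w * c_in) + (j + dj) * c_in + c
        col = j * f + ff
        self._band_dest = (row * (cw * f) + col).ravel()
        self._w_src = (((i * k + dj) * c_in + c) * f + ff).ravel()
        self._band_shape = (k * in_w * c_in, cw * f)
        self._cw, self._in_w, self._ow = cw, in_w, ow
        self._plan_for_w = w

    def _band_matrix(self) -> np.ndarray:
        band = np.zeros(self._band_shape[0] * self._band_shape[1], dtype=np.float32)
        band[self._band_dest] = self.W.ravel()[self._w_src]
        return band.reshape(self._band_shape)

    def _gather(self, x: np.ndarray) -> np.ndarray:
        """(N, H, W, C) -> stacked tile rows (n_tiles*N*OH, k*in_w*C)."""
        k, c = self.k, self.in_ch
        n, h, w, _ = x.shape
        oh = h - k + 1
        cw, in_w = self._cw, self._in_w
        n_tiles = self._ow // cw
        xa = np.empty((n_tiles, n, oh, k, in_w * c), dtype=np.float32)
        x3 = x.reshape(n, h, w * c)
        for s in range(n_tiles):
            lo = s * cw * c
            for i in range(k):
                xa[s, :, :, i, :] = x3[:, i : i + oh, lo : lo + in_w * c]
        return xa.reshape(-1, k * in_w * c)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k = self.k
        n, h, w, _ = x.shape
        oh = h - k + 1
        if self._plan_for_w != w:
            self._plan(w)
        cw, ow = self._cw, self._ow
        n_tiles = ow // cw
        self._band = self._band_matrix()
        self._xa = self._gather(x)
        self._in_shape = x.shape
        y = self._xa @ self._band  # (n_tiles*N*OH, cw*F)
        y = y.reshape(n_tiles, n, oh, cw, self.out_ch)
        y = np.ascontiguousarray(y.transpose(1, 2, 0, 3, 4))
        return y.reshape(n, oh, ow, self.out_ch) + self.b

    def _stack_grad(self, g: np.ndarray) -> np.ndarray:
        n, oh, ow, f = g.shape
        cw = self._cw
        gs = g.reshape(n, oh, ow // cw, cw, f).transpose(2, 0, 1, 3, 4)
        return np.ascontiguousarray(gs).reshape(-1, cw * f)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, oh, ow, f = g.shape
        k, c, cw, in_w = self.k, self.in_ch, self._cw, self._in_w
        g2 = self._stack_grad(g)
        dband = self._xa.T @ g2
        vals = dband.ravel()[self._band_dest].reshape(k, k, cw, c, f)
        self.grads[0][...] = vals.sum(axis=2)
        gr = g.reshape(-1, f)
        self.grads[1][...] = np.ones(gr.shape[0], dtype=np.float32) @ gr
        dx = None
        if self.needs_input_grad:
            h, w = self._in_shape[1:3]
            n_tiles = ow // cw
            dxa = (g2 @ self._band.T).reshape(n_tiles, n, oh, k, in_w * c)
            dx3 = np.zeros((n, h, w * c), dtype=np.float32)
            for s in range(n_tiles):
                lo = s * cw * c
                for i in range(k):
                    dx3[:, i : i + oh, lo : lo + in_w * c] += dxa[s, :, :, i, :]
            dx = dx3.reshape(self._in_shape)
        self._xa = None
        self._band = None
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization over all leading axes (NHWC or NC)."""

    kind = "batchnorm"

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = np.ones(ch, dtype=np.float32)
        self.beta = np.zeros(ch, dtype=np.float32)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        # normalization folded into one fused affine pass y = a*x + b;
        # column sums via GEMV (ones @ x), which BLAS runs far faster than
        # a strided axis-0 reduction
        c = x.shape[-1]
        x2 = x.reshape(-1, c)
        if train:
            m_rows = x2.shape[0]
            ones = np.ones(m_rows, dtype=np.float32)
            s1 = ones @ x2
            s2 = ones @ np.square(x2)
            mean = s1 / m_rows
            var = np.maximum(s2 / m_rows - mean * mean, 0.0)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._mean = mean.astype(np.float32)
        self._std = np.sqrt(var + self.eps).astype(np.float32)
        self._x = x
        a = self.gamma / self._std
        b = self.beta - self._mean * a
        return a * x + b

    def backward(self, g: np.ndarray) -> np.ndarray:
        c = g.shape[-1]
        x2 = self._x.reshape(-1, c)
        g2 = g.reshape(-1, c)
        m = g2.shape[0]
        ones = np.ones(m, dtype=np.float32)
        s_g = ones @ g2
        s_gx = np.einsum("nc,nc->c", g2, x2, optimize=True)
        # dgamma = sum(g * xhat) expressed through raw-x sums
        s_gxhat = (s_gx - self._mean * s_g) / self._std
        self.grads[0][...] = s_gxhat
        self.grads[1][...] = s_g
        # dx = (gamma/std) * (g - s_g/m - xhat * s_gxhat/m), expanded into
        # one fused expression over g and x
        a = self.gamma / self._std
        c2 = -a * s_gxhat / (m * self._std)
        c3 = -a * s_g / m - c2 * self._mean
        dx = a * g + c2 * self._x + c3
        self._x = None
        return dx


class ReLU(Layer):
    """Rectifier; clips in place (inputs are always fresh intermediates)."""

    kind = "relu"

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0.0, out=x)
        self._y = y
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = g * (self._y > 0)
        self._y = None
        return g


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped.

    Backward routes the gradient to the first maximal element of each
    window (raster order), so ties break deterministically.
    """

    kind = "pool"

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h2, w2 = x.shape[1] // 2, x.shape[2] // 2
        self._x = x
        views = (
            x[:, : 2 * h2 : 2, : 2 * w2 : 2],
            x[:, : 2 * h2 : 2, 1 : 2 * w2 : 2],
            x[:, 1 : 2 * h2 : 2, : 2 * w2 : 2],
            x[:, 1 : 2 * h2 : 2, 1 : 2 * w2 : 2],
        )
        m = np.maximum(np.maximum(views[0], views[1]),
                       np.maximum(views[2], views[3]))
        self._m = m
        return m

    def backward(self, g: np.ndarray) -> np.ndarray:
        x, m = self._x, self._m
        h2, w2 = g.shape[1], g.shape[2]
        dx = np.zeros_like(x)
        taken = np.zeros(g.shape, dtype=bool)
        slices = (
            (slice(None), slice(0, 2 * h2, 2), slice(0, 2 * w2, 2)),
            (slice(None), slice(0, 2 * h2, 2), slice(1, 2 * w2, 2)),
            (slice(None), slice(1, 2 * h2, 2), slice(0, 2 * w2, 2)),
            (slice(None), slice(1, 2 * h2, 2), slice(1, 2 * w2, 2)),
        )
        for sl in slices:
            hit = (x[sl] == m) & ~taken
            dx[sl] = g * hit
            taken |= hit
        self._x = None
        self._m = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference and when rate == 0."""

    kind = "dropout"

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        u = self.rng.random(x.shape, dtype=np.float32)
        self._mask = np.where(u < keep, np.float32(1.0 / keep), np.float32(0.0))
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


class Dense(Layer):
    kind = "dense"

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.W = w.astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        self._x = None
        return g @ self.W.T


class Flatten(Layer):
    kind = "flatten"

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits.

    ``targets`` are integer class indices.
    """
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), targets], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Adam:
    """Adam with the standard bias correction (b1=0.9, b2=0.999)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
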