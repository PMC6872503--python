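"""Neural-network layers with explicit forward/backward passes.

Everything here operates on plain numpy arrays.  Each layer caches what it
needs during ``forward`` and consumes it in ``backward``; parameters and their
gradients are exposed through ``params()`` as ``(value, grad)`` pairs so an
optimizer can update them in place.

Convolutions are implemented with ``sliding_window_view`` (no copies on the
forward pass) and an offset loop for the input gradient, which is fast for the
small kernels used here.  The first layer of a network never needs its input
gradient, so ``backward`` takes a ``need_input_grad`` flag.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class; stateless layers only implement forward/backward."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray, need_input_grad: bool = True):
        raise NotImplementedError

    def params(self):
        return []

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params()))


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: float | None = None):
        if scale is None:
            scale = np.sqrt(2.0 / n_in)  # He init, suits ReLU-family nets
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float64)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad, need_input_grad=True):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T if need_input_grad else None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad, need_input_grad=True):
        return grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad, need_input_grad=True):
        return np.where(self._mask, grad, self.alpha * grad)


class Tanh(Layer):
    def forward(self, x, train=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad, need_input_grad=True):
        return grad * (1.0 - self._y ** 2)


class Conv3D(Layer):
    """3D convolution over (N, C, D, H, W) inputs.

    ``stride`` is ``(sd, sh, sw)``; ``padding`` is ``"valid"`` or ``"same"``
    (zero padding; with stride 1 the spatial shape is preserved).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride=(1, 1, 1), padding: str = "valid", *,
                 rng: np.random.Generator, name: str = "conv"):
        k = kernel_size
        fan_in = in_channels * k ** 3
        self.W = (rng.standard_normal((out_channels, in_channels, k, k, k))
                  * np.sqrt(2.0 / fan_in))
        self.b = np.zeros(out_channels)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k = k
        self.stride = tuple(int(s) for s in stride)
        if padding not in ("valid", "same"):
            raise ValueError(f"padding must be 'valid' or 'same', got {padding!r}")
        self.padding = padding
        self.name = name
        self._idx_cache: dict[tuple, np.ndarray] = {}

    def _pad_widths(self):
        if self.padding == "valid":
            return (0, 0)
        lo = (self.k - 1) // 2
        return (lo, self.k - 1 - lo)

    def out_shape(self, spatial):
        lo, hi = self._pad_widths()
        out = []
        for dim, s in zip(spatial, self.stride):
            padded = dim + lo + hi
            if padded < self.k:
                raise ValueError(
                    f"layer {self.name!r}: spatial dim {dim} too small for "
                    f"kernel {self.k} (padded size {padded})")
            out.append((padded - self.k) // s + 1)
        return tuple(out)

    def _flat_index(self, padded_spatial, out_spatial, channels):
        """(n_out, C*k^3) gather indices into the flattened (C, D, H, W) volume."""
        key = (tuple(padded_spatial), channels)
        if key in self._idx_cache:
            return self._idx_cache[key]
        Dp, Hp, Wp = padded_spatial
        sd, sh, sw = self.stride
        d0 = np.arange(out_spatial[0]) * sd
        h0 = np.arange(out_spatial[1]) * sh
        w0 = np.arange(out_spatial[2]) * sw
        kd, kh, kw = np.meshgrid(np.arange(self.k), np.arange(self.k),
                                 np.arange(self.k), indexing="ij")
        koff = (kd * Hp * Wp + kh * Wp + kw).ravel()               # (k^3,)
        base = (d0[:, None, None] * Hp * Wp + h0[None, :, None] * Wp
                + w0[None, None, :]).ravel()                       # (n_out,)
        spatial_size = Dp * Hp * Wp
        chan = np.arange(channels) * spatial_size                  # (C,)
        idx = (base[:, None, None] + chan[None, :, None]
               + koff[None, None, :]).reshape(len(base), -1)       # (n_out, C*k^3)
        self._idx_cache[key] = idx
        return idx

    def forward(self, x, train=False):
        lo, hi = self._pad_widths()
        if lo or hi:
            x = np.pad(x, ((0, 0), (0, 0), (lo, hi), (lo, hi), (lo, hi)))
        self._xp_shape = x.shape
        n, c = x.shape[:2]
        out_spatial = []
        for dim, s in zip(x.shape[2:], self.stride):
            if dim < self.k:
                raise ValueError(
                    f"layer {self.name!r}: spatial dim {dim} too small for kernel {self.k}")
            out_spatial.append((dim - self.k) // s + 1)
        idx = self._flat_index(x.shape[2:], out_spatial, c)
        # np.take keeps the gather C-contiguous (a sliced fancy index does not)
        col = np.take(x.reshape(n, -1), idx, axis=1)   # (N, n_out, C*k^3)
        n_out = col.shape[1]
        col2d = col.reshape(n * n_out, -1)
        self._col2d = col2d
        wmat = self.W.reshape(self.W.shape[0], -1)     # (F, C*k^3)
        out = (col2d @ wmat.T).reshape(n, n_out, -1).transpose(0, 2, 1)
        out = out.reshape(n, -1, *out_spatial)
        return out + self.b[None, :, None, None, None]

    def backward(self, grad, need_input_grad=True):
        n, f = grad.shape[:2]
        g2 = grad.reshape(n, f, -1).transpose(0, 2, 1).reshape(-1, f)  # (N*n_out, F)
        self.dW[...] = (g2.T @ self._col2d).reshape(self.W.shape)
        self.db[...] = grad.sum(axis=(0, 2, 3, 4))
        if not need_input_grad:
            return None
        # dcol[n,c,d,h,w,x,y,z] scattered back over kernel offsets
        dx = np.zeros(self._xp_shape)
        sd, sh, sw = self.stride
        n_out = grad.shape[2:]
        for kx in range(self.k):
            for ky in range(self.k):
                for kz in range(self.k):
                    piece = np.einsum("nodhw,oc->ncdhw", grad,
                                      self.W[:, :, kx, ky, kz], optimize=True)
                    dx[:, :,
                       kx:kx + sd * n_out[0]:sd,
                       ky:ky + sh * n_out[1]:sh,
                       kz:kz + sw * n_out[2]:sw] += piece
        lo, hi = self._pad_widths()
        if lo or hi:
            sl = slice(lo, dx.shape[2] - hi)
            dx = dx[:, :, sl, sl, sl] if dx.shape[2] == dx.shape[3] == dx.shape[4] else dx[
                :, :,
                slice(lo, dx.shape[2] - hi),
                slice(lo, dx.shape[3] - hi),
                slice(lo, dx.shape[4] - hi)]
        return dx

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class MaxPool3D(Layer):
    """2x2x2 max pooling with stride 2 and ceil-mode -inf padding.

    Ceil mode keeps every spatial dimension >= 1, so deep schedules stay
    valid on small grids.
    """

    def forward(self, x, train=False):
        n, c, d, h, w = x.shape
        pd, ph, pw = (-d) % 2, (-h) % 2, (-w) % 2
        self._in_shape = x.shape
        self._pads = (pd, ph, pw)
        xp = np.pad(x, ((0, 0), (0, 0), (0, pd), (0, ph), (0, pw)),
                    constant_values=-np.inf)
        self._xp = xp
        r = xp.reshape(n, c, (d + pd) // 2, 2, (h + ph) // 2, 2, (w + pw) // 2, 2)
        out = r.max(axis=(3, 5, 7))
        self._out = out
        return out

    def backward(self, grad, need_input_grad=True):
        n, c, d, h, w = self._in_shape
        pd, ph, pw = self._pads
        up_out = np.repeat(np.repeat(np.repeat(self._out, 2, axis=2), 2, axis=3),
                           2, axis=4)
        up_grad = np.repeat(np.repeat(np.repeat(grad, 2, axis=2), 2, axis=3),
                            2, axis=4)
        mask = self._xp == up_out
        dxp = np.where(mask, up_grad, 0.0)
        return dxp[:, :, :d, :h, :w]


class GlobalAveragePool(Layer):
    """Collapse each feature channel to its spatial mean: (N,C,D,H,W) -> (N,C)."""

    def forward(self, x, train=False):
        self._spatial = x.shape[2:]
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad, need_input_grad=True):
        d, h, w = self._spatial
        g = grad[:, :, None, None, None] / (d * h * w)
        return np.broadcast_to(g, grad.shape + (d, h, w)).copy()


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad, need_input_grad=True):
        return grad.reshape(self._shape)
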