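"""Neural-network building blocks with explicit forward/backward passes.

All layers operate on arrays laid out as ``(B, C, H, W)``: batch, feature
maps, spatial (electrode) axis, time axis.  Each layer owns its
parameters and the gradients of the last backward pass; the model object
wires layers together and assigns them to named parameter groups.

Correctness of every backward pass is pinned by central-difference
gradient checks in the test suite, and the closed-form parameter counts
of the complexity module are cross-checked against these layers' actual
parameter census.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft as sfft


class Layer:
    """Base class: a named, optionally trainable computation node."""

    def __init__(self, name: str):
        self.name = name
        self.trainable = True
        self._p: dict[str, np.ndarray] = {}
        self._g: dict[str, np.ndarray] = {}

    # parameters -----------------------------------------------------------
    @property
    def params(self) -> dict[str, np.ndarray]:
        return self._p

    @property
    def grads(self) -> dict[str, np.ndarray]:
        return self._g

    def n_params(self) -> int:
        return int(sum(p.size for p in self._p.values()))

    def init(self, rng: np.random.Generator) -> None:  # pragma: no cover
        pass

    # computation ----------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class TemporalConv(Layer):
    """T filters of shape (1, k) convolved along time, 'same' padding.

    Input ``(B, 1, M, S)`` → output ``(B, T, M, S)``; the same temporal
    filter bank is applied to every electrode row.  Both passes run as
    frequency-domain products (exact up to float rounding, with an FFT
    length covering the full linear convolution so nothing wraps), which
    is far cheaper than sliding windows for kernels this long.
    """

    def __init__(self, n_filters: int, kernel: int, name: str = "temporal_conv"):
        super().__init__(name)
        self.t, self.k = n_filters, kernel
        self.pad_l = (kernel - 1) // 2
        self.pad_r = kernel - 1 - self.pad_l
        self._p = {"w": np.zeros((self.t, self.k)), "b": np.zeros(self.t)}

    def init(self, rng: np.random.Generator) -> None:
        self._p["w"] = _glorot(rng, (self.t, self.k), self.k, self.k * self.t)
        self._p["b"] = np.zeros(self.t)

    def forward(self, x, training=False, rng=None):
        if x.shape[1] != 1:
            raise ValueError(f"{self.name}: expected a single input map")
        s = x.shape[3]
        if s < self.k:
            raise ValueError(
                f"{self.name}: S={s} shorter than kernel {self.k}"
            )
        xs = x[:, 0]                                   # (B, M, S)
        self._s = s
        self._L = sfft.next_fast_len(s + self.k - 1)
        self._xs = xs
        xf = sfft.rfft(xs, n=self._L)                  # (B, M, F)
        wf = sfft.rfft(self._p["w"][:, ::-1], n=self._L)   # (T, F)
        y = sfft.irfft(xf[:, None, :, :] * wf[None, :, None, :], n=self._L)
        out = y[..., self.pad_r:self.pad_r + s]
        return out + self._p["b"][None, :, None, None]

    def backward(self, g):
        s, L = self._s, self._L
        gf = sfft.rfft(g, n=L)                         # (B, T, M, F)
        # dL/dw[t, k'] = sum_{b,m,s} x_padded[b, m, s+k'] g[b, t, m, s]
        xp = np.pad(self._xs, ((0, 0), (0, 0), (self.pad_l, self.pad_r)))
        xpf = sfft.rfft(xp, n=L)                       # (B, M, F)
        corr = np.einsum("bmf,btmf->tf", xpf, gf.conj(), optimize=True)
        self._g["w"] = sfft.irfft(corr, n=L)[:, : self.k]
        self._g["b"] = g.sum(axis=(0, 2, 3))
        # dL/dx: full convolution of g with the (un-reversed) kernels
        wf = sfft.rfft(self._p["w"], n=L)              # (T, F)
        gx = sfft.irfft(
            (gf * wf[None, :, None, :]).sum(axis=1), n=L
        )[..., self.pad_l:self.pad_l + s]
        return gx[:, None]


class DepthwiseSpatialConv(Layer):
    """Per-map spatial filters spanning all M electrodes ((M, 1) kernel).

    Each of the T input maps gets DP spatial filters, collapsing the
    electrode axis: ``(B, T, M, S)`` → ``(B, T*DP, 1, S)``.
    """

    def __init__(self, n_in: int, depth_multiplier: int, n_channels: int,
                 name: str = "depthwise_conv"):
        super().__init__(name)
        self.t, self.dp, self.m = n_in, depth_multiplier, n_channels
        self._p = {
            "w": np.zeros((self.t, self.dp, self.m)),
            "b": np.zeros(self.t * self.dp),
        }

    def init(self, rng):
        self._p["w"] = _glorot(
            rng, (self.t, self.dp, self.m), self.m, self.m * self.dp
        )
        self._p["b"] = np.zeros(self.t * self.dp)

    def forward(self, x, training=False, rng=None):
        b, t, m, s = x.shape
        if (t, m) != (self.t, self.m):
            raise ValueError(
                f"{self.name}: expected ({self.t},{self.m},*) maps, got {x.shape}"
            )
        self._x = x
        out = np.einsum("btms,tdm->btds", x, self._p["w"], optimize=True)
        out = out.reshape(b, self.t * self.dp, 1, s)
        return out + self._p["b"][None, :, None, None]

    def backward(self, g):
        b, _, _, s = g.shape
        gr = g.reshape(b, self.t, self.dp, s)
        self._g["w"] = np.einsum("btds,btms->tdm", gr, self._x, optimize=True)
        self._g["b"] = g.sum(axis=(0, 2, 3))
        return np.einsum("btds,tdm->btms", gr, self._p["w"], optimize=True)


class SeparableConvTime(Layer):
    """Depthwise temporal conv (1, k) followed by a pointwise 1×1 mix.

    ``(B, C, H, W)`` → ``(B, P, H, W)`` with 'same' padding along time.
    The bias sits on the pointwise stage only.
    """

    def __init__(self, n_in: int, n_filters: int, kernel: int,
                 name: str = "separable_conv"):
        super().__init__(name)
        self.c, self.p_out, self.k = n_in, n_filters, kernel
        self.pad_l = (kernel - 1) // 2
        self.pad_r = kernel - 1 - self.pad_l
        self._p = {
            "wd": np.zeros((self.c, self.k)),
            "wp": np.zeros((self.p_out, self.c)),
            "b": np.zeros(self.p_out),
        }

    def init(self, rng):
        self._p["wd"] = _glorot(rng, (self.c, self.k), self.k, self.k)
        self._p["wp"] = _glorot(rng, (self.p_out, self.c), self.c, self.p_out)
        self._p["b"] = np.zeros(self.p_out)

    def forward(self, x, training=False, rng=None):
        if x.shape[1] != self.c:
            raise ValueError(f"{self.name}: expected {self.c} maps, got {x.shape}")
        if x.shape[3] < self.k:
            raise ValueError(
                f"{self.name}: W={x.shape[3]} shorter than kernel {self.k}"
            )
        xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (self.pad_l, self.pad_r)))
        self._win = sliding_window_view(xp, self.k, axis=-1)  # (B,C,H,W,k)
        self._mid = np.einsum("bchwk,ck->bchw", self._win, self._p["wd"],
                              optimize=True)
        out = np.einsum("bchw,pc->bphw", self._mid, self._p["wp"],
                        optimize=True)
        return out + self._p["b"][None, :, None, None]

    def backward(self, g):
        self._g["wp"] = np.einsum("bphw,bchw->pc", g, self._mid, optimize=True)
        self._g["b"] = g.sum(axis=(0, 2, 3))
        gmid = np.einsum("bphw,pc->bchw", g, self._p["wp"], optimize=True)
        self._g["wd"] = np.einsum("bchw,bchwk->ck", gmid, self._win,
                                  optimize=True)
        gp = np.pad(gmid, ((0, 0), (0, 0), (0, 0), (self.pad_r, self.pad_l)))
        gwin = sliding_window_view(gp, self.k, axis=-1)
        return np.einsum("bchwk,ck->bchw", gwin, self._p["wd"][:, ::-1],
                         optimize=True)


class BatchNorm(Layer):
    """Per-feature-map normalization with running statistics.

    When the layer's group is frozen (``trainable = False``) the running
    statistics are used even during training and are not updated — the
    strict reading of "weights unchanged" for transfer schemes.
    """

    def __init__(self, n_maps: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "batchnorm"):
        super().__init__(name)
        self.c, self.momentum, self.eps = n_maps, momentum, eps
        self._p = {"gamma": np.ones(n_maps), "beta": np.zeros(n_maps)}
        self.running_mean = np.zeros(n_maps)
        self.running_var = np.ones(n_maps)

    def init(self, rng):
        self._p["gamma"] = np.ones(self.c)
        self._p["beta"] = np.zeros(self.c)
        self.running_mean = np.zeros(self.c)
        self.running_var = np.ones(self.c)

    def forward(self, x, training=False, rng=None):
        use_batch = training and self.trainable
        if use_batch:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        self._ivstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * self._ivstd[None, :, None, None]
        self._batch_mode = use_batch
        self._n = x.shape[0] * x.shape[2] * x.shape[3]
        return (
            self._p["gamma"][None, :, None, None] * self._xhat
            + self._p["beta"][None, :, None, None]
        )

    def backward(self, g):
        gamma = self._p["gamma"]
        self._g["gamma"] = np.einsum("bchw,bchw->c", g, self._xhat,
                                     optimize=True)
        self._g["beta"] = g.sum(axis=(0, 2, 3))
        scale = (gamma * self._ivstd)[None, :, None, None]
        if not self._batch_mode:
            return g * scale
        n = self._n
        sum_g = g.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_gx = self._g["gamma"][None, :, None, None]
        return scale / n * (n * g - sum_g - self._xhat * sum_gx)


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        super().__init__(name)

    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class MaxPoolTime(Layer):
    """Non-overlapping max pooling along the time axis."""

    def __init__(self, pool: int, name: str = "maxpool"):
        super().__init__(name)
        self.pool = pool

    def forward(self, x, training=False, rng=None):
        b, c, h, w = x.shape
        wo = w // self.pool
        if wo == 0:
            raise ValueError(
                f"{self.name}: time axis {w} shorter than pool {self.pool}"
            )
        self._in_shape = x.shape
        xr = x[..., : wo * self.pool].reshape(b, c, h, wo, self.pool)
        self._arg = xr.argmax(axis=-1)
        return xr.max(axis=-1)

    def backward(self, g):
        b, c, h, w = self._in_shape
        wo = g.shape[-1]
        gx = np.zeros((b, c, h, wo, self.pool))
        np.put_along_axis(gx, self._arg[..., None], g[..., None], axis=-1)
        out = np.zeros(self._in_shape)
        out[..., : wo * self.pool] = gx.reshape(b, c, h, wo * self.pool)
        return out


class Dropout(Layer):
    """Inverted dropout; identity outside training passes."""

    def __init__(self, p: float, name: str = "dropout"):
        super().__init__(name)
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def forward(self, x, training=False, rng=None):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError(f"{self.name}: training pass needs an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        super().__init__(name)

    def forward(self, x, training=False, rng=None):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._in_shape)


class Dense(Layer):
    """Fully connected classifier head with a max-norm weight constraint.

    After every optimizer step :meth:`apply_constraint` rescales any
    incoming-weight row whose L2 norm exceeds ``maxnorm`` back onto the
    constraint sphere.
    """

    def __init__(self, n_in: int, n_out: int, maxnorm: float | None = None,
                 name: str = "dense"):
        super().__init__(name)
        self.f, self.k_out, self.maxnorm = n_in, n_out, maxnorm
        self._p = {"w": np.zeros((n_out, n_in)), "b": np.zeros(n_out)}

    def init(self, rng):
        self._p["w"] = _glorot(rng, (self.k_out, self.f), self.f, self.k_out)
        self._p["b"] = np.zeros(self.k_out)

    def forward(self, x, training=False, rng=None):
        if x.shape[1] != self.f:
            raise ValueError(
                f"{self.name}: expected {self.f} features, got {x.shape[1]}"
            )
        self._x = x
        return x @ self._p["w"].T + self._p["b"]

    def backward(self, g):
        self._g["w"] = g.T @ self._x
        self._g["b"] = g.sum(axis=0)
        return g @ self._p["w"]

    def apply_constraint(self) -> None:
        if self.maxnorm is None:
            return
        w = self._p["w"]
        norms = np.linalg.norm(w, axis=1, keepdims=True)
        factor = np.minimum(1.0, self.maxnorm / np.maximum(norms, 1e-12))
        w *= factor


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    b = logits.shape[0]
    probs = softmax(logits)
    eps = 1e-12
    loss = -np.mean(np.log(probs[np.arange(b), labels] + eps))
    grad = probs.copy()
    grad[np.arange(b), labels] -= 1.0
    return float(loss), grad / b
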