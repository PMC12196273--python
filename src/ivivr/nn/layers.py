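"""Differentiable layers (forward + manual backward), float32, NCHW."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base layer; stateless unless it declares params or caches."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Param]:
        return []

    def set_rng(self, rng: np.random.Generator) -> None:  # dropout hooks in
        pass

    def out_shape(self, shape: tuple[int, int, int]) -> tuple[int, int, int]:
        """(C, H, W) -> (C, H, W) shape inference, used at build time."""
        return shape

    def plan(self) -> dict:
        return {"op": type(self).__name__.lower()}


class Conv2D(Layer):
    """3x3/5x5/1x1 convolution via im2col; 'same' padding by default."""

    def __init__(self, cin: int, cout: int, ksize: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        self.cin, self.cout, self.k, self.stride = cin, cout, ksize, stride
        self.pad = ksize // 2
        rng = rng or np.random.default_rng(0)
        fan_in = cin * ksize * ksize
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in))
        self.W = Param(w, "conv.W")
        self.b = Param(np.zeros(cout), "conv.b")
        self._cache = None

    def parameters(self) -> list[Param]:
        return [self.W, self.b]

    def out_shape(self, shape):
        c, h, w = shape
        assert c == self.cin, f"expected {self.cin} input planes, got {c}"
        ho = (h + 2 * self.pad - self.k) // self.stride + 1
        wo = (w + 2 * self.pad - self.k) // self.stride + 1
        return (self.cout, ho, wo)

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        n, c, h, w = x.shape
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # win: (N, C, Ho, Wo, k, k) -> cols (N*Ho*Wo, C*k*k)
        n_, c_, ho, wo = win.shape[:4]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * k * k)
        return cols, (x.shape, ho, wo)

    def forward(self, x, train=False):
        cols, (xshape, ho, wo) = self._im2col(x)
        out = cols @ self.W.value.T + self.b.value
        n = x.shape[0]
        out = out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)
        self._cache = (cols, xshape, ho, wo)
        return np.ascontiguousarray(out)

    def backward(self, g):
        cols, xshape, ho, wo = self._cache
        n, c, h, w = xshape
        k, p, s = self.k, self.pad, self.stride
        gf = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.W.grad += gf.T @ cols
        self.b.grad += gf.sum(axis=0)
        dcols = (gf @ self.W.value).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp

    def plan(self):
        return {"op": "conv", "filters": self.cout, "ksize": self.k,
                "stride": self.stride}


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask

    def plan(self):
        return {"op": "relu"}


class MaxPool2D(Layer):
    """2x2, stride-2 max pooling (spatial dims must be even)."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2D needs even spatial dims, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g):
        n, c, h, w = self._inshape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(out, self._idx[..., None], g[..., None], axis=-1)
        out = out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(out).reshape(n, c, h, w)

    def out_shape(self, shape):
        c, h, w = shape
        return (c, h // 2, w // 2)

    def plan(self):
        return {"op": "maxpool", "size": 2}


class MaxPoolSame3(Layer):
    """3x3, stride-1, 'same' max pooling (inception pooled branch)."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)),
                    constant_values=-np.inf)
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))
        flat = np.ascontiguousarray(win).reshape(n, c, h, w, 9)
        self._idx = flat.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g):
        n, c, h, w = self._inshape
        dxp = np.zeros((n, c, h + 2, w + 2), dtype=np.float32)
        di, dj = np.divmod(self._idx, 3)
        ii = np.arange(h)[None, None, :, None] + di
        jj = np.arange(w)[None, None, None, :] + dj
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (nn, cc, ii, jj), g)
        return dxp[:, :, 1:-1, 1:-1]

    def plan(self):
        return {"op": "maxpool_same", "size": 3}


class BatchNorm2D(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels), "bn.gamma")
        self.beta = Param(np.zeros(channels), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std, train)
        return self.gamma.value[None, :, None, None] * xhat + \
            self.beta.value[None, :, None, None]

    def backward(self, g):
        xhat, std, was_train = self._cache
        self.gamma.grad += (g * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += g.sum(axis=(0, 2, 3))
        gsc = g * self.gamma.value[None, :, None, None]
        if not was_train:
            return gsc / std[None, :, None, None]
        m = g.shape[0] * g.shape[2] * g.shape[3]
        t1 = gsc.sum(axis=(0, 2, 3))
        t2 = (gsc * xhat).sum(axis=(0, 2, 3))
        dx = (gsc - (t1[None, :, None, None] + xhat * t2[None, :, None, None]) / m) \
            / std[None, :, None, None]
        return dx

    def plan(self):
        return {"op": "batchnorm"}


class Dropout(Layer):
    def __init__(self, p: float = 0.25):
        self.p = p
        self._rng = np.random.default_rng(0)

    def set_rng(self, rng):
        self._rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self._rng.random(x.shape) >= self.p).astype(np.float32) \
            / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask

    def plan(self):
        return {"op": "dropout", "p": self.p}


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)

    def out_shape(self, shape):
        c, h, w = shape
        return (c * h * w, 1, 1)

    def plan(self):
        return {"op": "flatten"}


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g):
        n, c, h, w = self._shape
        return np.broadcast_to(g[:, :, None, None] / (h * w),
                               self._shape).astype(np.float32)

    def out_shape(self, shape):
        return (shape[0], 1, 1)

    def plan(self):
        return {"op": "global_avg_pool"}


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in)),
                       "dense.W")
        self.b = Param(np.zeros(n_out), "dense.b")

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, g):
        self.W.grad += g.T @ self._x
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value

    def out_shape(self, shape):
        return (self.W.value.shape[0], 1, 1)

    def plan(self):
        return {"op": "dense", "units": self.W.value.shape[0]}


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def set_rng(self, rng):
        for l in self.layers:
            l.set_rng(rng)

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g

    def out_shape(self, shape):
        for l in self.layers:
            shape = l.out_shape(shape)
        return shape

    def plan(self):
        return {"op": "sequential", "layers": [l.plan() for l in self.layers]}


class Residual(Layer):
    """Identity-shortcut block: out = x + body(x) (no post-add activation,
    so an all-zero body is an exact identity)."""

    def __init__(self, body: Sequential):
        self.body = body

    def parameters(self):
        return self.body.parameters()

    def set_rng(self, rng):
        self.body.set_rng(rng)

    def forward(self, x, train=False):
        return x + self.body.forward(x, train=train)

    def backward(self, g):
        return g + self.body.backward(g)

    def out_shape(self, shape):
        assert self.body.out_shape(shape) == shape, \
            "residual body must preserve shape"
        return shape

    def plan(self):
        return {"op": "residual", "body": self.body.plan()}


class InceptionModule(Layer):
    """Four parallel branches (1x1; 1x1->3x3; 1x1->5x5; pool->1x1)
    concatenated along channels, each conv followed by ReLU."""

    def __init__(self, cin: int, b1: int, b3r: int, b3: int, b5r: int,
                 b5: int, pp: int, rng: np.random.Generator):
        self.branches = [
            Sequential([Conv2D(cin, b1, 1, rng=rng), ReLU()]),
            Sequential([Conv2D(cin, b3r, 1, rng=rng), ReLU(),
                        Conv2D(b3r, b3, 3, rng=rng), ReLU()]),
            Sequential([Conv2D(cin, b5r, 1, rng=rng), ReLU(),
                        Conv2D(b5r, b5, 5, rng=rng), ReLU()]),
            Sequential([MaxPoolSame3(), Conv2D(cin, pp, 1, rng=rng), ReLU()]),
        ]
        self._widths = (b1, b3, b5, pp)

    @property
    def cout(self) -> int:
        return sum(self._widths)

    def parameters(self):
        return [p for b in self.branches for p in b.parameters()]

    def set_rng(self, rng):
        for b in self.branches:
            b.set_rng(rng)

    def forward(self, x, train=False):
        outs = [b.forward(x, train=train) for b in self.branches]
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1]
        return np.concatenate(outs, axis=1)

    def backward(self, g):
        parts = np.split(g, self._splits, axis=1)
        return sum(b.backward(np.ascontiguousarray(p))
                   for b, p in zip(self.branches, parts))

    def out_shape(self, shape):
        return (self.cout, shape[1], shape[2])

    def plan(self):
        return {"op": "inception", "widths": list(self._widths)}
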