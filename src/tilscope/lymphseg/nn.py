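"""Minimal CPU neural-net layers with hand-written backprop.

Just enough machinery for the encoder-decoder segmenter: 2-D convolution
(arbitrary stride/padding, im2col), 2x2 stride-2 transposed convolution,
2x2 max pooling, ReLU, residual blocks, and Adam. Arrays are NCHW float32.
Determinism: all randomness flows through explicit ``numpy`` generators and
no threading-order-dependent reductions are used.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("v", "g")

    def __init__(self, value):
        self.v = np.asarray(value, dtype=np.float32)
        self.g = np.zeros_like(self.v)


class Module:
    """Base class: children are registered in ``_modules`` declaration order."""

    def __init__(self):
        self._modules: list[tuple[str, "Module"]] = []
        self._params: list[tuple[str, Param]] = []

    def add(self, name, module):
        self._modules.append((name, module))
        return module

    def add_param(self, name, value):
        p = Param(value)
        self._params.append((name, p))
        return p

    def parameters(self):
        for _name, p in self._params:
            yield p
        for _name, m in self._modules:
            yield from m.parameters()

    def state_dict(self, prefix=""):
        out = {}
        for name, p in self._params:
            out[prefix + name] = p.v
        for name, m in self._modules:
            out.update(m.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state, prefix=""):
        for name, p in self._params:
            p.v = np.asarray(state[prefix + name], dtype=np.float32).copy()
        for name, m in self._modules:
            m.load_state_dict(state, prefix + name + ".")

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args):
        return self.forward(*args)


def he_normal(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def xavier_uniform(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride=1, pad=None, rng=None, init="he"):
        super().__init__()
        if pad is None:
            pad = k // 2
        self.k, self.stride, self.pad = k, stride, pad
        fan_in = cin * k * k
        fan_out = cout * k * k
        if init == "he":
            w = he_normal(rng, (cout, cin, k, k), fan_in)
        else:
            w = xavier_uniform(rng, (cout, cin, k, k), fan_in, fan_out)
        self.W = self.add_param("W", w)
        self.b = self.add_param("b", np.zeros(cout, dtype=np.float32))

    def forward(self, x):
        k, s, p = self.k, self.stride, self.pad
        N, C, H, Wd = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        Ho, Wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N * Ho * Wo, C * k * k
        )
        Wm = self.W.v.reshape(self.W.v.shape[0], -1)
        y = cols @ Wm.T + self.b.v
        self._cache = (x.shape, xp.shape, cols, Ho, Wo)
        return np.ascontiguousarray(
            y.reshape(N, Ho, Wo, -1).transpose(0, 3, 1, 2)
        )

    def backward(self, dy):
        x_shape, xp_shape, cols, Ho, Wo = self._cache
        k, s, p = self.k, self.stride, self.pad
        N, C, H, Wd = x_shape
        O = dy.shape[1]
        dym = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, O)
        Wm = self.W.v.reshape(O, -1)
        self.W.g += (dym.T @ cols).reshape(self.W.v.shape)
        self.b.g += dym.sum(axis=0)
        dcols = (dym @ Wm).reshape(N, Ho, Wo, C, k, k)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + Ho * s : s, kj : kj + Wo * s : s] += (
                    dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
                )
        if p:
            dxp = dxp[:, :, p : p + H, p : p + Wd]
        self._cache = None
        return dxp


class ConvTranspose2x2(Module):
    """2x2 transposed convolution with stride 2 (exact upsampling-by-2)."""

    def __init__(self, cin, cout, rng=None, init="xavier"):
        super().__init__()
        fan_in, fan_out = cin, cout * 4
        if init == "he":
            w = he_normal(rng, (cin, cout, 2, 2), fan_in)
        else:
            w = xavier_uniform(rng, (cin, cout, 2, 2), fan_in, fan_out)
        self.W = self.add_param("W", w)
        self.b = self.add_param("b", np.zeros(cout, dtype=np.float32))

    def forward(self, x):
        N, C, H, Wd = x.shape
        y = np.einsum("nchw,cokl->nohkwl", x, self.W.v, optimize=True)
        y = y.reshape(N, -1, H * 2, Wd * 2) + self.b.v[None, :, None, None]
        self._cache = x
        return y

    def backward(self, dy):
        x = self._cache
        N, C, H, Wd = x.shape
        O = dy.shape[1]
        dyr = dy.reshape(N, O, H, 2, Wd, 2)
        self.W.g += np.einsum("nchw,nohkwl->cokl", x, dyr, optimize=True)
        self.b.g += dy.sum(axis=(0, 2, 3))
        dx = np.einsum("nohkwl,cokl->nchw", dyr, self.W.v, optimize=True)
        self._cache = None
        return dx


class MaxPool2(Module):
    """2x2 stride-2 max pooling; spatial dims must be even."""

    def forward(self, x):
        N, C, H, W = x.shape
        assert H % 2 == 0 and W % 2 == 0, "MaxPool2 requires even dims"
        xv = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xv = np.ascontiguousarray(xv).reshape(N, C, H // 2, W // 2, 4)
        idx = xv.argmax(axis=-1)
        y = np.take_along_axis(xv, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, idx)
        return y

    def backward(self, dy):
        (N, C, H, W), idx = self._cache
        dxv = np.zeros((N, C, H // 2, W // 2, 4), dtype=np.float32)
        np.put_along_axis(dxv, idx[..., None], dy[..., None], axis=-1)
        dx = dxv.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._cache = None
        return np.ascontiguousarray(dx).reshape(N, C, H, W)


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        dy = dy * self._mask
        self._mask = None
        return dy


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        for i, m in enumerate(modules):
            self.add(str(i), m)

    def forward(self, x):
        for _name, m in self._modules:
            x = m(x)
        return x

    def backward(self, dy):
        for _name, m in reversed(self._modules):
            dy = m.backward(dy)
        return dy


class BasicBlock(Module):
    """Residual block: two 3x3 convs with an (optionally projected) shortcut."""

    def __init__(self, cin, cout, stride=1, rng=None):
        super().__init__()
        self.conv1 = self.add("conv1", Conv2d(cin, cout, 3, stride=stride, rng=rng))
        self.relu1 = self.add("relu1", ReLU())
        self.conv2 = self.add("conv2", Conv2d(cout, cout, 3, rng=rng))
        self.proj = None
        if stride != 1 or cin != cout:
            self.proj = self.add(
                "proj", Conv2d(cin, cout, 1, stride=stride, pad=0, rng=rng)
            )
        self.relu2 = self.add("relu2", ReLU())

    def forward(self, x):
        main = self.conv2(self.relu1(self.conv1(x)))
        short = self.proj(x) if self.proj is not None else x
        return self.relu2(main + short)

    def backward(self, dy):
        dsum = self.relu2.backward(dy)
        dmain = self.conv1.backward(self.relu1.backward(self.conv2.backward(dsum)))
        dshort = self.proj.backward(dsum) if self.proj is not None else dsum
        return dmain + dshort


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.v) for p in self.params]
        self.s = [np.zeros_like(p.v) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.g[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, s in zip(self.params, self.m, self.s):
            m *= self.b1
            m += (1 - self.b1) * p.g
            s *= self.b2
            s += (1 - self.b2) * p.g**2
            p.v -= self.lr * (m / b1t) / (np.sqrt(s / b2t) + self.eps)


def bce_with_logits(logits, targets):
    """Mean binary cross-entropy on logits; returns (loss, dlogits)."""
    z = logits.astype(np.float64)
    y = targets
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    n = z.size
    grad = (sigmoid(z) - y) / n
    return float(loss.mean()), grad.astype(np.float32)


def sigmoid(z):
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
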