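"""Neural-network layers, parameter containers and the Adam optimizer.

Layers follow the usual Module convention: parameters are discovered by
attribute traversal, `train()` / `eval()` toggle batch-norm statistics,
and every layer is deterministic given the `numpy.random.Generator`
passed at construction.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concatenate, conv2d, grid_sample, stack

__all__ = [
    "Module",
    "Parameter",
    "Conv2d",
    "Linear",
    "BatchNorm2d",
    "LayerNorm",
    "ReLU",
    "Sequential",
    "DeformConv2d",
    "MultiHeadSelfAttention",
    "Adam",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    training: bool = True

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def modules(self):
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, flag: bool = True):
        for m in self.modules():
            m.training = flag
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        """Flat dict of parameter / buffer arrays, keyed by attribute path."""
        out = {}

        def visit(obj, prefix):
            for k, v in obj.__dict__.items():
                if k.startswith("_"):
                    continue  # private bookkeeping, not learnable state
                key = f"{prefix}{k}"
                if isinstance(v, Parameter):
                    out[key] = v.data
                elif isinstance(v, np.ndarray):
                    out[key] = v
                elif isinstance(v, Module):
                    visit(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{key}.{i}.")
                        elif isinstance(item, Parameter):
                            out[f"{key}.{i}"] = item.data
        visit(self, "")
        return out

    def load_state_dict(self, state):
        def visit(obj, prefix):
            for k, v in obj.__dict__.items():
                if k.startswith("_"):
                    continue
                key = f"{prefix}{k}"
                if isinstance(v, Parameter):
                    v.data = np.asarray(state[key], dtype=np.float64).reshape(v.shape)
                elif isinstance(v, np.ndarray):
                    setattr(obj, k, np.asarray(state[key], dtype=np.float64).reshape(v.shape))
                elif isinstance(v, Module):
                    visit(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{key}.{i}.")
                        elif isinstance(item, Parameter):
                            item.data = np.asarray(state[f"{key}.{i}"], dtype=np.float64).reshape(item.shape)
        visit(self, "")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int):
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, cin, cout, k=3, stride=1, pad=None, bias=True, *, rng):
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        self.weight = Parameter(_he_init(rng, (cout, cin, k, k), cin * k * k))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, cin, cout, bias=True, *, rng):
        self.weight = Parameter(_he_init(rng, (cin, cout), cin))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
            )
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xn = (x - mu) / ((var + self.eps) ** 0.5)
        return xn * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class LayerNorm(Module):
    """Normalization over the trailing feature axis."""

    def __init__(self, c, eps=1e-5):
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class DeformConv2d(Module):
    """Deformable 3x3 convolution (v1): a plain conv predicts a 2-D offset
    for each kernel tap, the input is bilinearly sampled at the displaced
    tap positions and combined with the kernel weights.

    Offset-predictor weights start at zero so the layer is initially an
    ordinary convolution.
    """

    def __init__(self, cin, cout, k=3, *, rng):
        self.k = k
        self.weight = Parameter(_he_init(rng, (cout, cin, k, k), cin * k * k))
        self.bias = Parameter(np.zeros(cout))
        self.offset_conv = Conv2d(cin, 2 * k * k, k=k, rng=rng)
        self.offset_conv.weight.data[:] = 0.0

    def forward(self, x):
        b, cin, h, w = x.shape
        k = self.k
        off = self.offset_conv(x)  # (B, 2*k*k, H, W)
        jj, ii = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        base = np.stack([jj.ravel(), ii.ravel()], axis=-1)[None]  # (1, HW, 2)
        cout = self.weight.shape[0]
        acc = None
        for t in range(k * k):
            di, dj = t // k - k // 2, t % k - k // 2
            doff = off[:, 2 * t : 2 * t + 2].reshape(b, 2, h * w).transpose(0, 2, 1)
            coords = doff + (base + np.array([dj, di], dtype=float))
            samp = grid_sample(x, coords)  # (B, Cin, HW)
            wt = self.weight[:, :, t // k, t % k]  # (Cout, Cin), differentiable
            term = wt @ samp.reshape(b, cin, h * w)
            acc = term if acc is None else acc + term
        acc = acc + self.bias.reshape(1, cout, 1)
        return acc.reshape(b, cout, h, w)


class MultiHeadSelfAttention(Module):
    """MHSA over the second-to-last axis (tokens), features on the last.

    Query and key may be built from tokens plus an additive positional /
    type embedding supplied at call time. `raw_qk=True` skips the Q/K
    linear projections, using token+embedding directly.
    """

    def __init__(self, c, n_heads=4, raw_qk=False, *, rng):
        if c % n_heads:
            raise ValueError(f"feature dim {c} not divisible by n_heads {n_heads}")
        self.c = c
        self.n_heads = n_heads
        self.raw_qk = raw_qk
        if not raw_qk:
            self.wq = Linear(c, c, rng=rng)
            self.wk = Linear(c, c, rng=rng)
        self.wv = Linear(c, c, rng=rng)
        self.wo = Linear(c, c, rng=rng)

    def _split(self, x):
        # (..., P, C) -> (..., heads, P, dh)
        shape = x.shape
        p = shape[-2]
        dh = self.c // self.n_heads
        x = x.reshape(shape[:-1] + (self.n_heads, dh))
        perm = tuple(range(len(shape) - 2)) + (len(shape) - 1, len(shape) - 2, len(shape))
        return x.transpose(perm), p, dh

    def forward(self, tokens, qk_extra=None, return_attn=False):
        qk_in = tokens if qk_extra is None else tokens + qk_extra
        q = qk_in if self.raw_qk else self.wq(qk_in)
        k = qk_in if self.raw_qk else self.wk(qk_in)
        v = self.wv(tokens)
        qh, p, dh = self._split(q)
        kh, _, _ = self._split(k)
        vh, _, _ = self._split(v)
        nd = len(qh.shape)
        kt = kh.transpose(tuple(range(nd - 2)) + (nd - 1, nd - 2))
        attn = ((qh @ kt) / math.sqrt(dh)).softmax(axis=-1)
        out = attn @ vh  # (..., heads, P, dh)
        perm = tuple(range(nd - 3)) + (nd - 2, nd - 3, nd - 1)
        out = out.transpose(perm).reshape(tokens.shape[:-1] + (self.c,))
        out = self.wo(out)
        if return_attn:
            return out, attn
        return out


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
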