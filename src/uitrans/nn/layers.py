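"""Neural-network building blocks on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int,
                    a: float = 0.01) -> np.ndarray:
    gain = np.sqrt(2.0 / (1.0 + a ** 2))
    bound = gain * np.sqrt(3.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02,
                 clip: float = 2.0) -> np.ndarray:
    x = rng.normal(0.0, std, size=shape)
    x = np.clip(x, -clip * std, clip * std)
    return x.astype(np.float32)


class Module:
    """Tiny module base: parameter discovery by attribute recursion."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params, seen):
        for value in self.__dict__.values():
            self._collect_value(value, params, seen)

    @staticmethod
    def _collect_value(value, params, seen):
        if isinstance(value, Parameter):
            if id(value) not in seen:
                seen.add(id(value))
                params.append(value)
        elif isinstance(value, Module):
            value._collect(params, seen)
        elif isinstance(value, (list, tuple)):
            for v in value:
                Module._collect_value(v, params, seen)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model expects {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(
                    f"parameter shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = a.astype(np.float32)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, rng, in_features: int, out_features: int,
                 init: str = "trunc_normal"):
        if init == "trunc_normal":
            w = trunc_normal(rng, (in_features, out_features))
        else:
            w = kaiming_uniform(rng, (in_features, out_features), in_features)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return ag.matmul(x, self.weight) + self.bias


class Conv3d(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, kernel=3,
                 stride=1, padding=None):
        kernel = (kernel,) * 3 if isinstance(kernel, int) else tuple(kernel)
        if padding is None:
            padding = tuple(k // 2 for k in kernel)
        fan_in = in_ch * int(np.prod(kernel))
        self.weight = Parameter(
            kaiming_uniform(rng, (out_ch, in_ch, *kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv3d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding)


class LayerNorm(Module):
    """Normalization over the last axis with learned affine."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = ag.mean(x, axis=-1, keepdims=True)
        centered = x - mu
        var = ag.mean(centered * centered, axis=-1, keepdims=True)
        inv = ag.power(var + self.eps, -0.5)
        return centered * inv * self.gamma + self.beta


class MLP(Module):
    def __init__(self, rng, dim: int, hidden: int):
        self.fc1 = Linear(rng, dim, hidden)
        self.fc2 = Linear(rng, hidden, dim)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(ag.gelu(self.fc1(x)))


class MultiheadSelfAttention(Module):
    """Scaled dot-product attention over a token sequence.

    Keys/values may come from a coarser token sequence ``kv`` (pooled
    tokens) while queries stay at full resolution; with ``kv=None`` this
    is plain self-attention. The most recent attention weights, shape
    (N, heads, T_q, T_kv), are kept in ``last_attention`` for
    diagnostics; each row is a softmax distribution over key tokens.
    """

    def __init__(self, rng, dim: int, n_heads: int):
        if dim % n_heads != 0:
            raise ValueError(
                f"embedding dim {dim} not divisible by n_heads {n_heads}")
        self.dim = dim
        self.n_heads = n_heads
        self.q = Linear(rng, dim, dim)
        self.kv = Linear(rng, dim, 2 * dim)
        self.proj = Linear(rng, dim, dim)
        self.last_attention: np.ndarray | None = None

    def _heads(self, x: Tensor) -> Tensor:
        N, T, E = x.shape
        x = ag.reshape(x, (N, T, self.n_heads, E // self.n_heads))
        return ag.transpose(x, (0, 2, 1, 3))  # (N,h,T,d)

    def forward(self, x: Tensor, kv: Tensor | None = None) -> Tensor:
        if kv is None:
            kv = x
        N, T, E = x.shape
        h = self.n_heads
        d = E // h
        # scale q before the score matmul (cheaper than scaling T_q x T_kv scores)
        q = self._heads(self.q(x) * (1.0 / np.sqrt(d)))
        kv_proj = self.kv(kv)  # (N,Tk,2E)
        Tk = kv.shape[1]
        kv_proj = ag.reshape(kv_proj, (N, Tk, 2, h, d))
        kv_proj = ag.transpose(kv_proj, (2, 0, 3, 1, 4))  # (2,N,h,Tk,d)
        k = ag.index_axis0(kv_proj, 0)
        v = ag.index_axis0(kv_proj, 1)
        scores = ag.matmul(q, ag.transpose(k, (0, 1, 3, 2)))
        attn = ag.softmax(scores, axis=-1)
        self.last_attention = attn.data
        out = ag.matmul(attn, v)  # (N,h,T,d)
        out = ag.transpose(out, (0, 2, 1, 3))
        out = ag.reshape(out, (N, T, E))
        return self.proj(out)


class Adam:
    """ADAM optimizer (Kingma & Ba) on raw parameter arrays."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
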