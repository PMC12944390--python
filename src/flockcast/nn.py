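"""Neural-network building blocks on top of the autodiff core.

Layers follow the conventions of mainstream deep-learning frameworks:
fan-in uniform initialization, pre-norm residual wiring for the Transformer
encoder, decoupled weight decay in AdamW.  All randomness (initialization,
dropout masks, batch shuffling) flows through explicitly passed
``numpy.random.Generator`` instances so runs are bit-reproducible.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from ._autodiff import Parameter, Tensor, sigmoid, softmax, tanh

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerEncoderLayer",
    "LSTMCell",
    "AdamW",
    "gelu",
    "dropout",
    "clip_grad_norm",
]


def gelu(x: Tensor) -> Tensor:
    """Exact GELU: x * Phi(x) via the error function."""
    from ._autodiff import erf

    return x * 0.5 * (erf(x * (1.0 / math.sqrt(2.0))) + 1.0)


def dropout(x: Tensor, p: float, rng: np.random.Generator | None, training: bool) -> Tensor:
    if not training or p <= 0.0 or rng is None:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


class Module:
    """Base class with recursive parameter registration and train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for mod in self._modules.values():
            yield from mod.modules()

    def train(self, mode: bool = True) -> "Module":
        for mod in self.modules():
            object.__setattr__(mod, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise ValueError(f"missing parameters in state dict: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: checkpoint {arr.shape} vs model {p.data.shape}"
                )
            p.data = arr.copy()

    def count_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        if zero_init:
            w = np.zeros((in_features, out_features))
            b = np.zeros(out_features)
        else:
            k = 1.0 / math.sqrt(in_features)
            w = rng.uniform(-k, k, size=(in_features, out_features))
            b = rng.uniform(-k, k, size=out_features)
        self.weight = Parameter(w)
        self.bias = Parameter(b)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.weight + self.bias


class MultiHeadSelfAttention(Module):
    """Full bidirectional (unmasked) multi-head self-attention."""

    def __init__(self, d_model: int, n_heads: int, dropout_p: float, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.dropout_p = dropout_p
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        B, L, D = x.shape
        H, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:  # (B, L, D) -> (B, H, L, dh)
            return t.reshape(B, L, H, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(dh))
        attn = softmax(scores, axis=-1)
        attn = dropout(attn, self.dropout_p, rng, self.training)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.wo(out)


class TransformerEncoderLayer(Module):
    """Pre-norm residual block: x + MHSA(LN(x)); x + FFN(LN(x)) with GELU."""

    def __init__(self, d_model: int, n_heads: int, ffn_dim: int, dropout_p: float,
                 rng: np.random.Generator):
        super().__init__()
        self.dropout_p = dropout_p
        self.norm1 = LayerNorm(d_model)
        self.attn = MultiHeadSelfAttention(d_model, n_heads, dropout_p, rng)
        self.norm2 = LayerNorm(d_model)
        self.ffn1 = Linear(d_model, ffn_dim, rng)
        self.ffn2 = Linear(ffn_dim, d_model, rng)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        x = x + self.attn(self.norm1(x), rng)
        h = gelu(self.ffn1(self.norm2(x)))
        h = dropout(h, self.dropout_p, rng, self.training)
        return x + self.ffn2(h)


class LSTMCell(Module):
    """Standard LSTM cell; gate order (input, forget, cell, output)."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.hidden_size = hidden_size
        self.lin = Linear(input_size + hidden_size, 4 * hidden_size, rng)

    def __call__(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        from ._autodiff import concatenate

        z = self.lin(concatenate([x, h], axis=-1))
        n = self.hidden_size
        i = sigmoid(z[..., 0 * n:1 * n])
        f = sigmoid(z[..., 1 * n:2 * n])
        g = tanh(z[..., 2 * n:3 * n])
        o = sigmoid(z[..., 3 * n:4 * n])
        c_new = f * c + i * g
        h_new = o * tanh(c_new)
        return h_new, c_new


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr: float, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            if self.weight_decay:
                p.data -= lr * self.weight_decay * p.data
            p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale gradients in place so the global L2 norm is at most max_norm."""
    params = [p for p in params if p.grad is not None]
    total = math.sqrt(sum(float(np.sum(p.grad ** 2)) for p in params))
    if total > max_norm and total > 0.0:
        scale = max_norm / total
        for p in params:
            p.grad = p.grad * scale
    return total
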