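"""Neural-network building blocks used by the risk model.

Layers follow the usual Module pattern: parameters are :class:`Tensor` leaves
with ``requires_grad=True``, sub-modules are discovered by attribute scan, and
``train()`` / ``eval()`` toggle stochastic layers (dropout).  Initialisation is
driven by a single ``numpy.random.Generator`` so that model construction is
fully reproducible from one seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    def __init__(self):
        self.training = True
        self._buffers: dict[str, np.ndarray] = {}

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=np.float64)

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, val in self._buffers.items():
            yield f"{prefix}{name}", val
        for name, val in vars(self).items():
            if name == "_buffers":
                continue
            full = f"{prefix}{name}"
            if isinstance(val, Module):
                yield from val.named_buffers(full + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")
            elif isinstance(val, dict):
                for k, item in val.items():
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{k}.")

    # -- parameter / module discovery ---------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item
            elif isinstance(val, dict):
                for k, item in val.items():
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{k}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()
            elif isinstance(val, dict):
                for item in val.values():
                    if isinstance(item, Module):
                        yield from item.modules()

    # -- mode ----------------------------------------------------------------
    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- (de)serialisation ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            out[f"buffer::{name}"] = buf.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        own_bufs = {f"buffer::{n}" for n, _ in self.named_buffers()}
        if set(own) | own_bufs != set(state):
            missing = (set(own) | own_bufs) ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)[:5]} ...")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()
        # restore buffers in place on their owning modules
        def visit(mod: "Module", prefix: str):
            for name in list(mod._buffers):
                key = f"buffer::{prefix}{name}"
                mod._buffers[name] = np.asarray(state[key], dtype=np.float64).copy()
            for name, val in vars(mod).items():
                if name == "_buffers":
                    continue
                full = f"{prefix}{name}"
                if isinstance(val, Module):
                    visit(val, full + ".")
                elif isinstance(val, (list, tuple)):
                    for i, item in enumerate(val):
                        if isinstance(item, Module):
                            visit(item, f"{full}.{i}.")
                elif isinstance(val, dict):
                    for k, item in val.items():
                        if isinstance(item, Module):
                            visit(item, f"{full}.{k}.")
        visit(self, "")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_kaiming(rng, in_dim, (in_dim, out_dim)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.weight) + self.bias


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int = 1):
        super().__init__()
        self.stride, self.pad = stride, pad
        self.weight = Tensor(_kaiming(rng, cin * k * k, (cout, cin, k, k)), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class LayerNorm(Module):
    def __init__(self, dim: int):
        super().__init__()
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.gain, self.bias)


class BatchNorm1d(Module):
    """Per-feature standardisation over the batch with running statistics.

    Used on the longitudinal contrast channel: within-patient feature
    differences have tiny raw scale, and standardising them per feature is
    what makes slow changes visible to the heads at O(1) scale.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-8):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(dim))
        self.register_buffer("running_var", np.ones(dim))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=0)
            var = x.data.var(axis=0)
            m = self.momentum
            self._buffers["running_mean"] = (1 - m) * self._buffers["running_mean"] + m * mu
            self._buffers["running_var"] = (1 - m) * self._buffers["running_var"] + m * var
        else:
            mu = self._buffers["running_mean"]
            var = self._buffers["running_var"]
        # normalisation constants are treated as data (no gradient through
        # the batch statistics); at these widths the approximation is the
        # standard "frozen-statistics" simplification
        inv = 1.0 / np.sqrt(var + self.eps)
        return (x + (-mu)) * inv * self.gain + self.bias


class Dropout(Module):
    """Inverted dropout; draws masks from a generator owned by the top model."""

    def __init__(self, p: float):
        super().__init__()
        self.p = float(p)
        self.rng: np.random.Generator | None = None

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        if self.rng is None:
            raise RuntimeError("dropout used in training mode without a seeded rng")
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return ad.mul(x, mask)


class MLP2(Module):
    """Two fully connected layers with dropout between them (ReLU after the first)."""

    def __init__(self, in_dim: int, hidden: int, out_dim: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(in_dim, hidden, rng)
        self.drop = Dropout(dropout)
        self.fc2 = Linear(hidden, out_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.drop(ad.relu(self.fc1(x))))


class MultiheadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.dim, self.heads, self.hd = dim, heads, dim // heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor, key_padding_mask: np.ndarray) -> Tensor:
        """``x``: (B, T, D); ``key_padding_mask``: (B, T) bool, True = valid."""
        b, t, d = x.shape
        qkv = self.qkv(x)  # (B, T, 3D)
        qkv = ad.reshape(qkv, (b, t, 3, self.heads, self.hd))
        qkv = ad.transpose(qkv, (2, 0, 3, 1, 4))  # (3, B, H, T, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))) * (1.0 / np.sqrt(self.hd))
        bias = np.where(key_padding_mask[:, None, None, :], 0.0, -1e30)
        attn = ad.softmax(scores + Tensor(bias), axis=-1)
        out = ad.matmul(attn, v)  # (B, H, T, hd)
        out = ad.reshape(ad.transpose(out, (0, 2, 1, 3)), (b, t, d))
        return self.proj(out)


class TransformerEncoderLayer(Module):
    """Pre-norm encoder layer: LN -> MHSA -> residual, LN -> GELU MLP -> residual."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 ff_mult: int = 2, dropout: float = 0.0):
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = MultiheadSelfAttention(dim, heads, rng)
        self.ln2 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_mult * dim, rng)
        self.ff2 = Linear(ff_mult * dim, dim, rng)
        self.drop = Dropout(dropout)

    def forward(self, x: Tensor, key_padding_mask: np.ndarray) -> Tensor:
        x = x + self.attn(self.ln1(x), key_padding_mask)
        x = x + self.ff2(self.drop(ad.gelu(self.ff1(self.ln2(x)))))
        return x


class Adam:
    """Adam with optional decoupled weight decay (AdamW-style)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def seed_dropout(module: Module, rng: np.random.Generator) -> None:
    """Give every Dropout layer in ``module`` the shared training generator."""
    for m in module.modules():
        if isinstance(m, Dropout):
            m.rng = rng
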