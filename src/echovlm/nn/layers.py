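"""Small neural-network layers built on the autodiff engine.

Everything is float32, NHWC for images, (B, L, width) for token streams.
A Module is just a container with a flat name->Tensor parameter registry so
optimizers and checkpoints can treat models as dictionaries of arrays.
"""
from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, embedding, take_rows

DTYPE = np.float32


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}

    def register(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value.astype(DTYPE), requires_grad=True)
        self._params[name] = t
        return t

    def add_child(self, name: str, child: "Module") -> "Module":
        self._children[name] = child
        return child

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for cname, child in self._children.items():
            out.update(child.parameters(prefix + cname + "."))
        return out

    def zero_grad(self):
        for p in self.parameters().values():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, v in params.items():
            if state[k].shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            v.data = state[k].astype(DTYPE).copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 gain: float = 1.0):
        super().__init__()
        scale = gain / np.sqrt(n_in)
        self.w = self.register("w", rng.uniform(-scale, scale, (n_in, n_out)))
        self.b = self.register("b", np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm(Module):
    def __init__(self, width: int, eps: float = 1e-5):
        super().__init__()
        self.g = self.register("g", np.ones(width))
        self.b = self.register("b", np.zeros(width))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = (var + self.eps).powf(-0.5)
        return xc * inv * self.g + self.b


class Embedding(Module):
    def __init__(self, n_vocab: int, width: int, rng: np.random.Generator):
        super().__init__()
        self.w = self.register("w", rng.normal(0, 0.02, (n_vocab, width)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding(self.w, ids)


class CausalSelfAttention(Module):
    def __init__(self, width: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if width % heads:
            raise ValueError("width must be divisible by heads")
        self.heads = heads
        self.hd = width // heads
        self.qkv = self.add_child("qkv", Linear(width, 3 * width, rng))
        self.proj = self.add_child("proj", Linear(width, width, rng))

    def __call__(self, x: Tensor) -> Tensor:
        B, L, W = x.shape
        qkv = self.qkv(x)  # (B, L, 3W)
        qkv = qkv.reshape(B, L, 3, self.heads, self.hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (B, H, L, hd)
        att = (q @ k.transpose(0, 1, 3, 2)) * float(1.0 / np.sqrt(self.hd))
        mask = np.triu(np.full((L, L), -1e9, dtype=DTYPE), k=1)
        att = att + Tensor(mask)
        att = att.softmax(axis=-1)
        out = att @ v  # (B, H, L, hd)
        out = out.transpose(0, 2, 1, 3).reshape(B, L, W)
        return self.proj(out)


class TransformerBlock(Module):
    def __init__(self, width: int, heads: int, rng: np.random.Generator):
        super().__init__()
        self.ln1 = self.add_child("ln1", LayerNorm(width))
        self.attn = self.add_child("attn", CausalSelfAttention(width, heads, rng))
        self.ln2 = self.add_child("ln2", LayerNorm(width))
        self.fc1 = self.add_child("fc1", Linear(width, 4 * width, rng))
        self.fc2 = self.add_child("fc2", Linear(4 * width, width, rng))

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        x = x + self.fc2(self.fc1(self.ln2(x)).gelu())
        return x


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator):
        super().__init__()
        fan_in = k * k * cin
        self.w = self.register("w", rng.normal(0, np.sqrt(2.0 / fan_in), (k, k, cin, cout)))
        self.b = self.register("b", np.zeros(cout))
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


def l2_normalize(x: Tensor, eps: float = 1e-8) -> Tensor:
    n = ((x * x).sum(axis=-1, keepdims=True) + eps).powf(-0.5)
    return x * n


__all__ = [
    "Module", "Linear", "LayerNorm", "Embedding", "CausalSelfAttention",
    "TransformerBlock", "Conv2d", "l2_normalize", "take_rows", "Tensor", "DTYPE",
]
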