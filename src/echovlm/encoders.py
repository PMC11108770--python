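"""Dual encoder: image tower and decoder-only transformer text tower
projecting into a shared unit-norm embedding space.

The desk-scale default is a 4-block convnet image tower and a 4-layer,
128-wide causal transformer text tower with a 128-dimensional joint space.
A heavier ``convnext_like`` tower (patchify stem, residual stages) is
offered for fidelity to production-scale configurations; the contract is
identical. All embeddings are divided by their Euclidean norm, so every
similarity is a cosine in [-1, 1].

Number-slot values from the template tokenizer are injected out-of-band:
the NUMBER token's embedding is shifted by (value / 100) times a learned
direction, so numeric magnitude reaches the transformer without per-digit
tokens.
"""
from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, asdict

import numpy as np

from .nn import (Tensor, no_grad, Module, Linear, LayerNorm, Embedding,
                 TransformerBlock, Conv2d, l2_normalize, take_rows, DTYPE)
from .nn.autodiff import avg_pool
from .tokenizer import TemplateVocabulary, TokenSequence, tokenize, PAD_ID, NUM_ID

logger = logging.getLogger(__name__)

FRAME_SHAPE = (224, 224, 3)
_PIX_MEAN, _PIX_SD = 0.3, 0.3

# angular frequencies (per unit value) spanning coarse-to-fine structure on
# the clinically relevant 0-200 numeric range
VALUE_FREQS = np.array([0.5, 1.0, 2.0, 4.0, 8.0]) * 2 * np.pi / 200.0


def value_features(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """(..., 2F) sin/cos Fourier features of slot values, zero off-slot."""
    ang = values[..., None] * VALUE_FREQS
    feats = np.concatenate([np.sin(ang), np.cos(ang)], axis=-1)
    return (feats * mask[..., None]).astype(DTYPE)


@dataclass(frozen=True)
class EncoderConfig:
    image_arch: str = "small_convnet"  # or "convnext_like"
    embed_dim: int = 128
    text_context_length: int = 77  # base variant; long-context default is 256
    text_layers: int = 4
    text_width: int = 128
    text_heads: int = 4
    temperature_init: float = 0.07

    def __post_init__(self):
        if self.embed_dim < 8:
            raise ValueError("embed_dim must be >= 8")
        if self.image_arch not in ("small_convnet", "convnext_like"):
            raise ValueError(f"unknown image_arch {self.image_arch!r}")
        if self.temperature_init <= 0:
            raise ValueError("temperature_init must be positive")


@dataclass(frozen=True)
class JointEmbedding:
    """A unit-norm vector in the shared space, tagged by its source tower."""
    vector: np.ndarray
    source: str  # "image" | "text"

    def __post_init__(self):
        n = float(np.linalg.norm(self.vector))
        if abs(n - 1.0) > 1e-5:
            raise ValueError(f"embedding norm {n} not within 1e-5 of 1")


class SmallConvNet(Module):
    """Average-pooling stem (224 -> 56) followed by 4 conv blocks, global
    average pool and a linear projection. The pooling stem keeps the cost of
    the full-resolution input negligible without losing the rendered
    anatomy, which spans tens of pixels."""

    def __init__(self, embed_dim: int, rng: np.random.Generator):
        super().__init__()
        self.c1 = self.add_child("c1", Conv2d(3, 32, 3, stride=2, pad=1, rng=rng))
        self.c2 = self.add_child("c2", Conv2d(32, 64, 3, stride=2, pad=1, rng=rng))
        self.c3 = self.add_child("c3", Conv2d(64, 96, 3, stride=2, pad=1, rng=rng))
        self.c4 = self.add_child("c4", Conv2d(96, 96, 3, stride=1, pad=1, rng=rng))
        self.ln = self.add_child("ln", LayerNorm(96))
        # high-gain projection: pooled features of visually similar frames are
        # strongly correlated at init, and a wider projection spreads the
        # unit-norm embeddings enough for the contrastive signal to bite
        self.proj = self.add_child("proj", Linear(96, embed_dim, rng, gain=4.0))

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] == 224:  # pre-pooled (56 x 56) input is also accepted
            x = avg_pool(x, 4)
        x = self.c1(x).relu()  # 28
        x = self.c2(x).relu()  # 14
        x = self.c3(x).relu()  # 7
        x = self.c4(x).relu()
        x = x.mean(axis=(1, 2))  # global pool -> (B, 96)
        return self.proj(self.ln(x))


class _ResBlock(Module):
    def __init__(self, c: int, rng: np.random.Generator):
        super().__init__()
        self.conv = self.add_child("conv", Conv2d(c, c, 3, stride=1, pad=1, rng=rng))
        self.ln = self.add_child("ln", LayerNorm(c))
        self.fc1 = self.add_child("fc1", Linear(c, 4 * c, rng))
        self.fc2 = self.add_child("fc2", Linear(4 * c, c, rng))

    def __call__(self, x: Tensor) -> Tensor:
        h = self.ln(self.conv(x))
        h = self.fc2(self.fc1(h).gelu())
        return x + h


class ConvNeXtLike(Module):
    """Patchify stem plus residual stages; a scaled-down homage to modern
    convnet designs, not a faithful reproduction."""

    def __init__(self, embed_dim: int, rng: np.random.Generator):
        super().__init__()
        self.stem = self.add_child("stem", Conv2d(3, 32, 4, stride=4, pad=0, rng=rng))
        self.b1 = self.add_child("b1", _ResBlock(32, rng))
        self.d1 = self.add_child("d1", Conv2d(32, 64, 2, stride=2, pad=0, rng=rng))
        self.b2 = self.add_child("b2", _ResBlock(64, rng))
        self.d2 = self.add_child("d2", Conv2d(64, 96, 2, stride=2, pad=0, rng=rng))
        self.b3 = self.add_child("b3", _ResBlock(96, rng))
        self.d3 = self.add_child("d3", Conv2d(96, 128, 2, stride=2, pad=0, rng=rng))
        self.b4 = self.add_child("b4", _ResBlock(128, rng))
        self.ln = self.add_child("ln", LayerNorm(128))
        self.proj = self.add_child("proj", Linear(128, embed_dim, rng, gain=4.0))

    def __call__(self, x: Tensor) -> Tensor:
        x = self.stem(x)
        x = self.d1(self.b1(x))
        x = self.d2(self.b2(x))
        x = self.d3(self.b3(x))
        x = self.b4(x)
        x = x.mean(axis=(1, 2))
        return self.proj(self.ln(x))


class TextTransformer(Module):
    """Decoder-only (causal) transformer; the embedding is read at the final
    real token position and projected to the joint space."""

    def __init__(self, cfg: EncoderConfig, n_vocab: int, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.tok = self.add_child("tok", Embedding(n_vocab, cfg.text_width, rng))
        self.pos = self.add_child("pos", Embedding(cfg.text_context_length,
                                                   cfg.text_width, rng))
        # numeric slot values enter as multi-frequency Fourier features so
        # that nearby values embed nearby and distant values are separable
        # from the start; a single learned direction scaled by value/100
        # turned out to be invisible after layer normalization
        self.value_proj = self.register("value_proj",
                                        rng.normal(0, 0.04, (2 * len(VALUE_FREQS),
                                                             cfg.text_width)))
        self.blocks = [self.add_child(f"blk{i}", TransformerBlock(
            cfg.text_width, cfg.text_heads, rng)) for i in range(cfg.text_layers)]
        self.ln_f = self.add_child("ln_f", LayerNorm(cfg.text_width))
        self.proj = self.add_child("proj", Linear(cfg.text_width, cfg.embed_dim,
                                                  rng, gain=4.0))

    def __call__(self, ids: np.ndarray, values: np.ndarray,
                 last_idx: np.ndarray) -> Tensor:
        B, L = ids.shape
        has_value = (ids == NUM_ID)
        x = self.tok(ids) + self.pos(np.arange(L)) \
            + Tensor(value_features(values, has_value)) @ self.value_proj
        for blk in self.blocks:
            x = blk(x)
        x = self.ln_f(x)
        pooled = take_rows(x, last_idx)
        return self.proj(pooled)


def pack_token_batch(seqs: list[TokenSequence], context_length: int):
    """Pad a list of token sequences to arrays (ids, values, last_idx).

    Sequences longer than the context are truncated to the first
    ``context_length`` tokens with a logged warning.
    """
    prepped = []
    for s in seqs:
        if s.length == 0:
            raise ValueError("cannot encode an empty token sequence")
        if s.length > context_length:
            logger.warning("token sequence length %d exceeds context %d; truncating",
                           s.length, context_length)
            s = s.truncate(context_length)
        prepped.append(s)
    L = max(s.length for s in prepped)
    ids = np.full((len(prepped), L), PAD_ID, dtype=np.int64)
    values = np.zeros((len(prepped), L), dtype=np.float32)
    last_idx = np.zeros(len(prepped), dtype=np.int64)
    for i, s in enumerate(prepped):
        ids[i, :s.length] = s.tokens
        last_idx[i] = s.length - 1
        for pos, stype, val in s.slot_values:
            if stype == "NUMBER":
                values[i, pos] = val
    return ids, values, last_idx


def normalize_frames(frames: np.ndarray) -> np.ndarray:
    """uint8/float frames (B, 224, 224, 3) -> standardized float32."""
    scale = 1.0 / (255.0 * _PIX_SD)
    return frames.astype(np.float32) * scale - (_PIX_MEAN / _PIX_SD)


def pooled_normalized_frames(frames: np.ndarray, k: int = 4) -> np.ndarray:
    """Fused 4x4 average pool + standardization for uint8 frame batches.

    The pooling stem is linear and the normalization affine, so pooling
    before normalizing is exactly equivalent to the model's internal
    ``avg_pool``; summing the uint8 input with a float32 accumulator avoids
    materializing a full-resolution float copy.
    """
    B, H, W, C = frames.shape
    s = frames.reshape(B, H // k, k, W // k, k, C).sum(axis=(2, 4), dtype=np.float32)
    scale = 1.0 / (k * k * 255.0 * _PIX_SD)
    return s * scale - (_PIX_MEAN / _PIX_SD)


class DualEncoder(Module):
    """Image and text towers plus the learnable contrastive temperature."""

    def __init__(self, config: EncoderConfig, vocab: TemplateVocabulary,
                 seed: int = 0):
        super().__init__()
        self.config = config
        self.vocab = vocab
        rng = np.random.default_rng(seed)
        tower = SmallConvNet if config.image_arch == "small_convnet" else ConvNeXtLike
        self.image_tower = self.add_child("image", tower(config.embed_dim, rng))
        self.text_tower = self.add_child("text", TextTransformer(
            config, vocab.max_token_id(), rng))
        # log of the logit scale, initialized to ln(1/temperature_init)
        self.log_scale = self.register("log_scale",
                                       np.array([np.log(1.0 / config.temperature_init)]))

    # ---- differentiable forward passes (training / saliency) -------------
    def image_forward(self, x: Tensor) -> Tensor:
        """Differentiable image tower on standardized input; unit-norm output."""
        return l2_normalize(self.image_tower(x))

    def text_forward(self, ids, values, last_idx) -> Tensor:
        return l2_normalize(self.text_tower(ids, values, last_idx))

    def logit_scale(self) -> Tensor:
        """exp(log_scale) clamped to at most 100."""
        self.log_scale.data = np.minimum(self.log_scale.data, np.log(100.0))
        return self.log_scale.exp()

    # ---- inference API ----------------------------------------------------
    def encode_image(self, frames: np.ndarray) -> np.ndarray:
        """Encode one frame (224, 224, 3) or a batch (N, 224, 224, 3) to
        unit-norm embeddings. Deterministic."""
        arr = np.asarray(frames)
        single = arr.ndim == 3
        if single:
            arr = arr[None]
        if arr.shape[1:] != FRAME_SHAPE:
            raise ValueError(f"expected frames of shape {FRAME_SHAPE}, got {arr.shape[1:]}")
        with no_grad():
            if (self.config.image_arch == "small_convnet"
                    and arr.dtype == np.uint8):
                x = Tensor(pooled_normalized_frames(arr))
            else:
                x = Tensor(normalize_frames(arr))
            out = self.image_forward(x).data
        return out[0] if single else out

    def encode_text(self, seqs: TokenSequence | list[TokenSequence]) -> np.ndarray:
        """Encode token sequences to unit-norm embeddings."""
        single = isinstance(seqs, TokenSequence)
        batch = [seqs] if single else list(seqs)
        ids, values, last_idx = pack_token_batch(batch, self.config.text_context_length)
        with no_grad():
            out = self.text_forward(ids, values, last_idx).data
        return out[0] if single else out

    def embed_text(self, texts: str | list[str]) -> np.ndarray:
        """Tokenize raw text with the model's vocabulary and encode it."""
        single = isinstance(texts, str)
        batch = [texts] if single else list(texts)
        embs = self.encode_text([tokenize(t, self.vocab) for t in batch])
        return embs[0] if single else embs

    # ---- checkpointing ----------------------------------------------------
    def save(self, path):
        buf = io.BytesIO()
        np.savez(buf,
                 __config__=np.frombuffer(
                     json.dumps(asdict(self.config)).encode(), dtype=np.uint8),
                 __vocab__=np.frombuffer(self.vocab.to_json().encode(), dtype=np.uint8),
                 __vocab_hash__=np.frombuffer(
                     self.vocab.content_hash().encode(), dtype=np.uint8),
                 **self.state_dict())
        with open(path, "wb") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path, vocab: TemplateVocabulary | None = None) -> "DualEncoder":
        with np.load(path) as z:
            cfg = EncoderConfig(**json.loads(bytes(z["__config__"]).decode()))
            stored_vocab = TemplateVocabulary.from_json(bytes(z["__vocab__"]).decode())
            stored_hash = bytes(z["__vocab_hash__"]).decode()
            state = {k: z[k] for k in z.files if not k.startswith("__")}
        if stored_vocab.content_hash() != stored_hash:
            raise ValueError("checkpoint vocabulary hash mismatch (corrupt file)")
        if vocab is not None and vocab.content_hash() != stored_hash:
            raise ValueError("checkpoint was trained with a different vocabulary; "
                             "refusing to load")
        model = cls(cfg, stored_vocab)
        model.load_state_dict(state)
        return model


def similarity_matrix(image_embs: np.ndarray, text_embs: np.ndarray) -> np.ndarray:
    """Cosine-similarity matrix between two sets of unit-norm embeddings;
    entry (i, j) is the dot product of image i and text j."""
    a = np.atleast_2d(np.asarray(image_embs, dtype=np.float64))
    b = np.atleast_2d(np.asarray(text_embs, dtype=np.float64))
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"embedding dims differ: {a.shape[1]} vs {b.shape[1]}")
    return a @ b.T


__all__ = ["EncoderConfig", "JointEmbedding", "DualEncoder", "similarity_matrix",
           "pack_token_batch", "normalize_frames", "SmallConvNet", "ConvNeXtLike",
           "TextTransformer", "FRAME_SHAPE"]
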