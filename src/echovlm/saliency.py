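"""Prompt-conditioned saliency by integrated gradients.

The attribution objective is the cosine similarity between the image
embedding of a frame and the (fixed) text embedding of a prompt; integrating
the gradient of that objective along the straight path from a baseline frame
to the input frame distributes the similarity change over pixels. By the
completeness property the attributions sum to f(input) - f(baseline) up to
the Riemann-sum discretization error, which is reported rather than hidden.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .encoders import DualEncoder, normalize_frames
from .nn import Tensor, l2_normalize

FRAME_HW = (224, 224)


@dataclass
class SaliencyMap:
    attribution: np.ndarray  # (224, 224), channel-summed
    prompt: str
    completeness_gap: float

    def __post_init__(self):
        if not np.isfinite(self.attribution).all():
            raise ValueError("attribution contains non-finite values")


class _CosineObjective:
    """f(x) = cos(image_embedding(x), prompt_embedding); differentiable."""

    def __init__(self, model, prompt_text: str):
        self.model = model
        if hasattr(model, "embed_text"):
            self.t = np.asarray(model.embed_text(prompt_text), dtype=np.float64)
        else:
            raise ValueError("model cannot embed text prompts")
        self.t_f32 = self.t.astype(np.float32)

    def value_and_grad(self, frame_f32: np.ndarray):
        x = Tensor(frame_f32[None], requires_grad=True)
        emb = self._image_embedding(x)
        f = (emb * Tensor(self.t_f32[None])).sum()
        f.backward()
        if x.grad is None:
            raise RuntimeError("model is not differentiable with respect to "
                               "its input pixels")
        return float(f.data), x.grad[0]

    def value(self, frame_f32: np.ndarray) -> float:
        x = Tensor(frame_f32[None])
        emb = self._image_embedding(x)
        return float((emb.data[0] * self.t_f32).sum())

    def _image_embedding(self, x: Tensor) -> Tensor:
        if hasattr(self.model, "image_forward"):
            return self.model.image_forward(x)
        return l2_normalize(self.model(x))


def _baseline_frame(frame: np.ndarray, baseline: str | np.ndarray) -> np.ndarray:
    if isinstance(baseline, np.ndarray):
        return baseline.astype(np.float32)
    if baseline == "black":
        return np.zeros_like(frame, dtype=np.float32)
    if baseline == "blur":
        return gaussian_filter(frame.astype(np.float32), sigma=(8, 8, 0))
    raise ValueError(f"unknown baseline {baseline!r}")


def prompt_attribution(frame: np.ndarray, prompt_text: str, model,
                       steps: int = 50,
                       baseline: str | np.ndarray = "black") -> SaliencyMap:
    """Integrated-gradients saliency for one (frame, prompt) pair.

    The path runs from the baseline (default: black, matching the dark
    out-of-sector background) to the frame; gradients are evaluated at
    ``steps`` midpoint Riemann nodes, summed over color channels into a
    single 2-D map. ``model`` must expose a differentiable image forward
    pass and a text-prompt embedder (a trained dual encoder does).
    """
    if steps < 2:
        raise ValueError("steps must be >= 2")
    frame_raw = np.asarray(frame)
    if frame_raw.shape[:2] != FRAME_HW:
        raise ValueError(f"expected a {FRAME_HW} frame")
    obj = _CosineObjective(model, prompt_text)

    x1 = normalize_frames(frame_raw[None])[0]
    x0raw = _baseline_frame(frame_raw, baseline)
    x0 = normalize_frames(x0raw[None])[0]
    delta = x1 - x0

    grad_sum = np.zeros_like(x1, dtype=np.float64)
    for k in range(steps):
        alpha = (k + 0.5) / steps
        _, g = obj.value_and_grad((x0 + alpha * delta).astype(np.float32))
        grad_sum += g.astype(np.float64)
    attr3 = delta.astype(np.float64) * (grad_sum / steps)
    attribution = attr3.sum(axis=-1)

    f1 = obj.value(x1)
    f0 = obj.value(x0)
    gap = abs(float(attribution.sum()) - (f1 - f0))
    return SaliencyMap(attribution=attribution, prompt=prompt_text,
                       completeness_gap=gap)


def render_overlay(frame: np.ndarray, smap: SaliencyMap,
                   floor_percentile: float = 90.0,
                   alpha: float = 0.5) -> np.ndarray:
    """Overlay the attribution on the frame as a red (most important) to
    green (less important) ramp; pixels below the percentile floor of
    absolute attribution are left uncolored."""
    a = np.abs(smap.attribution)
    if not np.isfinite(a).all():
        raise ValueError("attribution must be finite")
    out = np.asarray(frame, dtype=np.float64).copy()
    if a.max() == 0.0:
        return out.astype(np.uint8)
    floor = np.percentile(a, floor_percentile)
    mask = a >= floor
    # rank-normalize within the colored set: 0 = least, 1 = most important
    vals = a[mask]
    from scipy.stats import rankdata
    t = (rankdata(vals, method="average") - 1) / max(len(vals) - 1, 1)
    color = np.zeros((len(vals), 3))
    color[:, 0] = 255.0 * t        # red ramps up with importance
    color[:, 1] = 255.0 * (1 - t)  # green fades out
    out[mask] = (1 - alpha) * out[mask] + alpha * color
    return np.clip(out, 0, 255).astype(np.uint8)


__all__ = ["SaliencyMap", "prompt_attribution", "render_overlay"]
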