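"""Cross-modal retrieval evaluation.

Candidates are ranked by cosine similarity to the query embedding; the rank
of the true match is recorded in both directions (image-to-text and
text-to-image). The mean cross-modal retrieval rank (MCMRR) is the average
of the two directional mean ranks. Ranks are 1-based; ties receive the
midrank (the average position of the tied block), which is unbiased under
exchangeability.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoders import similarity_matrix


@dataclass
class RetrievalResult:
    image_to_text_ranks: np.ndarray
    text_to_image_ranks: np.ndarray
    mcmrr: float
    top_k_hit: dict[int, float] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.image_to_text_ranks)


def _midrank_of_true(sims: np.ndarray, true_index: int) -> float:
    s = sims[true_index]
    greater = int(np.sum(sims > s))
    ties = int(np.sum(sims == s)) - 1  # excluding the true candidate itself
    return 1.0 + greater + ties / 2.0


def rank_candidates(query: np.ndarray, candidates: np.ndarray,
                    true_index: int) -> float:
    """1-based midrank of the true candidate among all candidates, ranked by
    cosine similarity to the query (best possible rank: 1)."""
    candidates = np.asarray(candidates, dtype=np.float64)
    if candidates.ndim != 2 or len(candidates) == 0:
        raise ValueError("candidates must be a nonempty (N, D) array")
    if not 0 <= true_index < len(candidates):
        raise IndexError(f"true_index {true_index} out of range")
    sims = candidates @ np.asarray(query, dtype=np.float64)
    return _midrank_of_true(sims, true_index)


def evaluate_retrieval(image_embs: np.ndarray, text_embs: np.ndarray,
                       pairing: np.ndarray | None = None,
                       ks: tuple[int, ...] = (1, 5, 10)) -> RetrievalResult:
    """Rank every image against all texts and vice versa over one shared
    candidate pool. ``pairing[i]`` is the index of the text matching image i
    and must be a bijection (default: identity)."""
    image_embs = np.asarray(image_embs, dtype=np.float64)
    text_embs = np.asarray(text_embs, dtype=np.float64)
    n = len(image_embs)
    if len(text_embs) != n:
        raise ValueError("image and text sets must have equal size")
    if pairing is None:
        pairing = np.arange(n)
    pairing = np.asarray(pairing)
    if sorted(pairing.tolist()) != list(range(n)):
        raise ValueError("pairing must be a bijection onto 0..N-1")
    sims = similarity_matrix(image_embs, text_embs)
    i2t = np.array([_midrank_of_true(sims[i], pairing[i]) for i in range(n)])
    inverse = np.empty(n, dtype=int)
    inverse[pairing] = np.arange(n)
    t2i = np.array([_midrank_of_true(sims[:, j], inverse[j]) for j in range(n)])
    mcmrr = float((i2t.mean() + t2i.mean()) / 2.0)
    all_ranks = np.concatenate([i2t, t2i])
    top_k = {int(k): float(np.mean(all_ranks <= k)) for k in ks}
    return RetrievalResult(image_to_text_ranks=i2t, text_to_image_ranks=t2i,
                           mcmrr=mcmrr, top_k_hit=top_k)


__all__ = ["RetrievalResult", "rank_candidates", "evaluate_retrieval"]
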